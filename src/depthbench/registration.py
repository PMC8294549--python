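"""Rigid registration between a depth-camera frame and the marker-based reference frame.

A marker-less depth-camera motion tracking system (DCMTS) and a marker-based
reference system (MMTS) each report 3-D coordinates in their own frame.  Before
any tracking error can be measured, the device frame ``D`` must be mapped onto
the reference frame ``M`` with a proper rigid transform (rotation + translation,
no scaling, no reflection).  The correspondences come from a planar alignment
board carrying a labeled grid of reflective markers that both systems see
simultaneously.

Conventions used throughout the package:

* coordinates are in **cm**; x is the lateral axis, y vertical, z the camera
  depth axis;
* transforms use the **row-vector** convention ``p' = p @ R + t`` (the
  column-vector equivalent is ``p'ᵀ = Rᵀ pᵀ + tᵀ``);
* point sets correspond **by label**, never by list order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FRAME_REFERENCE",
    "FRAME_DEVICE",
    "FRAME_DEVICE_ALIGNED",
    "AXIS_CONVENTION",
    "RegistrationError",
    "InsufficientCorrespondencesError",
    "DegenerateConfigurationError",
    "MarkerSet",
    "RigidTransform",
    "AlignmentResult",
    "estimate_rigid_transform",
    "apply_transform",
    "invert_transform",
    "residual_error",
]

logger = logging.getLogger(__name__)

#: Reference (marker-based system) frame tag.
FRAME_REFERENCE = "M"
#: Device (depth camera) frame tag.
FRAME_DEVICE = "D"
#: Device coordinates after transformation into the reference frame.
FRAME_DEVICE_ALIGNED = "D->M"

_FRAMES = (FRAME_REFERENCE, FRAME_DEVICE, FRAME_DEVICE_ALIGNED)
_FRAME_ALIASES = {"D→M": FRAME_DEVICE_ALIGNED}

#: Physical meaning of each coordinate axis.
AXIS_CONVENTION = {"x": "lateral", "y": "vertical", "z": "depth"}

# Relative threshold on the singular values of the centered reference points:
# collinear or coincident configurations leave the rotation under-determined.
_DEGENERACY_RTOL = 1e-8


class RegistrationError(ValueError):
    """Base class for registration failures."""


class InsufficientCorrespondencesError(RegistrationError):
    """Fewer than three matched labels between the two marker sets."""


class DegenerateConfigurationError(RegistrationError):
    """Matched reference points are collinear or coincident."""


@dataclass(frozen=True)
class MarkerSet:
    """An ordered set of labeled 3-D points (cm) tagged with a coordinate frame.

    Used both for alignment-board markers and for body landmarks.  Labels are
    unique within a set; two sets *correspond* through their shared labels.

    Parameters
    ----------
    frame:
        ``"M"`` (reference), ``"D"`` (device) or ``"D->M"`` (device after
        alignment; the unicode arrow form is accepted and normalised).
    labels:
        Marker labels, one per point.
    points:
        ``(n, 3)`` array of coordinates in cm.
    """

    frame: str
    labels: tuple[str, ...]
    points: np.ndarray

    def __post_init__(self) -> None:
        frame = _FRAME_ALIASES.get(self.frame, self.frame)
        if frame not in _FRAMES:
            raise ValueError(f"unknown frame {self.frame!r}; expected one of {_FRAMES}")
        labels = tuple(str(lab) for lab in self.labels)
        pts = np.array(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must have shape (n, 3), got {pts.shape}")
        if len(labels) != pts.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for {pts.shape[0]} points"
            )
        if len(set(labels)) != len(labels):
            seen: set[str] = set()
            dup = next(lab for lab in labels if lab in seen or seen.add(lab))
            raise ValueError(f"duplicate label {dup!r} in marker set")
        if not np.all(np.isfinite(pts)):
            raise ValueError("marker coordinates must be finite")
        pts.setflags(write=False)
        object.__setattr__(self, "frame", frame)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_records(
        cls, frame: str, records: Iterable[tuple[str, float, float, float]]
    ) -> "MarkerSet":
        """Build a set from an iterable of ``(label, x, y, z)`` rows."""
        recs = list(records)
        labels = tuple(r[0] for r in recs)
        pts = np.array([r[1:4] for r in recs], dtype=float).reshape(len(recs), 3)
        return cls(frame, labels, pts)

    def __len__(self) -> int:
        return len(self.labels)

    def coordinates(self, label: str) -> np.ndarray:
        """Return the (x, y, z) of one labeled point."""
        try:
            return self.points[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"label {label!r} not in marker set") from None

    def subset(self, labels: Sequence[str]) -> "MarkerSet":
        """A new set restricted to ``labels`` (in the given order)."""
        idx = [self.labels.index(lab) for lab in labels]
        return MarkerSet(self.frame, tuple(labels), self.points[idx])

    def common_labels(self, other: "MarkerSet") -> tuple[str, ...]:
        """Labels shared with ``other``, in this set's order."""
        theirs = set(other.labels)
        return tuple(lab for lab in self.labels if lab in theirs)

    def with_frame(self, frame: str) -> "MarkerSet":
        return MarkerSet(frame, self.labels, self.points)


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform mapping device coordinates to reference coordinates.

    Applied in the row-vector convention ``p' = p @ rotation + translation``.
    ``rotation`` is a 3x3 proper orthogonal matrix (RᵀR = I, det = +1);
    ``translation`` is in cm.
    """

    rotation: np.ndarray
    translation: np.ndarray

    #: validation tolerance on orthonormality / determinant
    _TOL = 1e-6

    def __post_init__(self) -> None:
        R = np.array(self.rotation, dtype=float)
        t = np.array(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if not np.allclose(R.T @ R, np.eye(3), atol=self._TOL):
            raise ValueError("rotation matrix is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=self._TOL):
            raise ValueError("rotation matrix is not proper (det != +1)")
        R.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply ``p' = p @ R + t`` to an ``(n, 3)`` or ``(3,)`` array."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation + self.translation

    def inverse(self) -> "RigidTransform":
        """The transform undoing this one: ``(Rᵀ, -t @ Rᵀ)``."""
        Rt = self.rotation.T
        return RigidTransform(Rt, -self.translation @ Rt)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """The transform equivalent to applying ``self`` then ``other``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.translation @ other.rotation + other.translation,
        )

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians (0..pi)."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


@dataclass(frozen=True)
class AlignmentResult:
    """A fitted rigid transform plus its per-marker residuals.

    ``residual_error`` is the mean Euclidean distance (cm) between the
    transformed device markers and their reference counterparts — the
    alignment-quality number Er_R reported for each coordinate-system
    alignment step.
    """

    transform: RigidTransform
    per_marker_residual: Mapping[str, float]
    residual_error: float
    n_markers_used: int
    labels_excluded: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_markers_used < 3:
            raise ValueError("an alignment uses at least 3 markers")
        resids = np.array(list(self.per_marker_residual.values()), dtype=float)
        if np.any(resids < 0):
            raise ValueError("residuals must be non-negative")
        if not np.isclose(self.residual_error, resids.mean(), atol=1e-9):
            raise ValueError("residual_error must equal the mean per-marker residual")


def _matched_arrays(
    device_set: MarkerSet, reference_set: MarkerSet
) -> tuple[tuple[str, ...], np.ndarray, np.ndarray, tuple[str, ...]]:
    """Match by label; return (labels, device pts, reference pts, excluded)."""
    common = device_set.common_labels(reference_set)
    matched = set(common)
    excluded = tuple(
        lab
        for lab in (*device_set.labels, *(l for l in reference_set.labels if l not in set(device_set.labels)))
        if lab not in matched
    )
    D = device_set.subset(common).points if common else np.empty((0, 3))
    M = reference_set.subset(common).points if common else np.empty((0, 3))
    return common, D, M, excluded


def estimate_rigid_transform(
    device_set: MarkerSet, reference_set: MarkerSet
) -> AlignmentResult:
    """Least-squares proper rigid transform from device onto reference markers.

    Solves ``min_R,t  Σ_i ‖ d_i @ R + t − m_i ‖²`` over proper rotations via
    the SVD of the cross-covariance of the centered matched points (Kabsch /
    absolute-orientation closed form), with a determinant sign correction so a
    reflection can never be returned even for mirrored input.

    Raises
    ------
    InsufficientCorrespondencesError
        Fewer than 3 shared labels.
    DegenerateConfigurationError
        Matched reference points collinear or coincident (rotation
        under-determined).  Planar configurations — such as the alignment
        board — are fine.
    """
    common, D, M, excluded = _matched_arrays(device_set, reference_set)
    if len(common) < 3:
        raise InsufficientCorrespondencesError(
            f"insufficient correspondences: {len(common)} matched labels, need >= 3"
        )
    Mc = M - M.mean(axis=0)
    sing = np.linalg.svd(Mc, compute_uv=False)
    if sing[0] == 0.0 or sing[1] < _DEGENERACY_RTOL * sing[0]:
        raise DegenerateConfigurationError(
            "degenerate configuration: matched reference points are collinear or coincident"
        )
    Dc = D - D.mean(axis=0)
    H = Dc.T @ Mc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    t = M.mean(axis=0) - D.mean(axis=0) @ R
    transform = RigidTransform(R, t)
    resid = np.linalg.norm(D @ R + t - M, axis=1)
    return AlignmentResult(
        transform=transform,
        per_marker_residual=dict(zip(common, resid.tolist())),
        residual_error=float(resid.mean()),
        n_markers_used=len(common),
        labels_excluded=excluded,
    )


def apply_transform(points: MarkerSet, transform: RigidTransform) -> MarkerSet:
    """Map a device-frame marker set into the reference frame (``D`` → ``D->M``)."""
    if points.frame != FRAME_DEVICE:
        raise ValueError(
            f"apply_transform expects a device-frame ('D') set, got {points.frame!r}"
        )
    return MarkerSet(FRAME_DEVICE_ALIGNED, points.labels, transform.apply(points.points))


def invert_transform(transform: RigidTransform) -> RigidTransform:
    """Inverse transform; composing with the original gives the identity."""
    return transform.inverse()


def residual_error(
    device_set: MarkerSet, reference_set: MarkerSet, transform: RigidTransform
) -> float:
    """Mean Euclidean distance (cm) between transformed device and reference markers.

    Evaluated over the label intersection.  Equals
    ``AlignmentResult.residual_error`` when called with the fitted transform.
    """
    common, D, M, _ = _matched_arrays(device_set, reference_set)
    if not common:
        raise RegistrationError("no matched labels between the two marker sets")
    return float(np.linalg.norm(transform.apply(D) - M, axis=1).mean())
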