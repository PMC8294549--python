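"""Landmark tracking-error metrics and the end-to-end benchmarking pipeline.

Once the device frame has been registered onto the reference frame, the
tracking error of a body landmark is the Euclidean distance ``Er`` between the
device-measured (transformed) position and the reference position, together
with the per-axis absolute differences |Δx|, |Δy|, |Δz|.  Errors are pooled
across subjects and repeated trials and summarised per landmark and overall.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .registration import (
    FRAME_DEVICE,
    FRAME_DEVICE_ALIGNED,
    AlignmentResult,
    MarkerSet,
    estimate_rigid_transform,
)

__all__ = [
    "SYSTEM_REFERENCE",
    "SYSTEM_DEVICE",
    "LandmarkObservation",
    "ErrorRecord",
    "BoardPair",
    "BenchmarkSession",
    "BenchmarkReport",
    "landmark_errors",
    "aggregate_report",
    "run_benchmark",
    "records_to_frame",
    "records_from_frame",
]

logger = logging.getLogger(__name__)

SYSTEM_REFERENCE = "reference"
SYSTEM_DEVICE = "device"


@dataclass(frozen=True)
class LandmarkObservation:
    """One 3-D observation of a named anatomical landmark.

    Exactly one observation may exist per (landmark, subject, trial, system);
    device observations additionally carry the camera ("front"/"back") that
    produced them.
    """

    landmark: str
    subject: str
    trial: int
    system: str
    point: tuple[float, float, float]
    camera: str | None = None

    def __post_init__(self) -> None:
        if self.system not in (SYSTEM_REFERENCE, SYSTEM_DEVICE):
            raise ValueError(f"system must be 'reference' or 'device', got {self.system!r}")
        pt = tuple(float(v) for v in self.point)
        if len(pt) != 3 or not all(math.isfinite(v) for v in pt):
            raise ValueError(f"point must be 3 finite coordinates, got {self.point!r}")
        object.__setattr__(self, "point", pt)
        object.__setattr__(self, "trial", int(self.trial))

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.landmark, self.subject, self.trial)


@dataclass(frozen=True)
class ErrorRecord:
    """Tracking error of one landmark in one (subject, trial).

    ``er`` is the 3-D Euclidean distance (cm); ``ax_x/ax_y/ax_z`` the per-axis
    absolute differences, so er² = ax_x² + ax_y² + ax_z².
    """

    landmark: str
    subject: str
    trial: int
    er: float
    ax_x: float
    ax_y: float
    ax_z: float
    camera: str | None = None

    @classmethod
    def from_points(
        cls,
        landmark: str,
        subject: str,
        trial: int,
        reference_point: Sequence[float],
        device_point: Sequence[float],
        camera: str | None = None,
    ) -> "ErrorRecord":
        d = np.asarray(reference_point, float) - np.asarray(device_point, float)
        ax = np.abs(d)
        return cls(
            landmark=landmark,
            subject=subject,
            trial=int(trial),
            er=float(np.linalg.norm(d)),
            ax_x=float(ax[0]),
            ax_y=float(ax[1]),
            ax_z=float(ax[2]),
            camera=camera,
        )


class BoardPair(NamedTuple):
    """Alignment-board capture of one camera: device set + reference set."""

    device: MarkerSet
    reference: MarkerSet


@dataclass
class BenchmarkSession:
    """Everything one benchmark run needs.

    ``boards`` maps camera name → :class:`BoardPair`; ``observations`` holds
    both systems' landmark observations; ``camera_map`` assigns every
    catalogued landmark to exactly one device camera.
    """

    boards: Mapping[str, BoardPair]
    observations: list[LandmarkObservation]
    camera_map: Mapping[str, str]


@dataclass
class BenchmarkReport:
    """Aggregated benchmark result.

    ``per_landmark`` is a DataFrame indexed by landmark with columns
    ``{er,x,y,z}_mean``, ``{er,x,y,z}_sd`` and ``n``.  ``overall_mean_er`` is
    the mean over all records; ``overall_sd_er`` the SD across the per-landmark
    mean values (the dispersion the per-landmark figures show).
    ``frac_below_threshold`` is the fraction of error values under
    ``threshold`` cm, computed over per-axis values (``threshold_basis='axis'``,
    the default) or over 3-D ``er`` values (``'er'``).
    """

    per_landmark: pd.DataFrame
    overall_mean_er: float
    overall_sd_er: float
    axis_mean: dict[str, float]
    axis_sd: dict[str, float]
    min_landmark_mean_er: float
    max_landmark_mean_er: float
    threshold: float
    threshold_basis: str
    frac_below_threshold: float
    n_records: int
    alignment_residuals: dict[str, float] = field(default_factory=dict)

    def summary_dict(self) -> dict:
        """JSON-serialisable summary (per-landmark table excluded)."""
        return {
            "overall_mean_er_cm": self.overall_mean_er,
            "overall_sd_er_cm": self.overall_sd_er,
            "axis_mean_cm": dict(self.axis_mean),
            "axis_sd_cm": dict(self.axis_sd),
            "min_landmark_mean_er_cm": self.min_landmark_mean_er,
            "max_landmark_mean_er_cm": self.max_landmark_mean_er,
            "threshold_cm": self.threshold,
            "threshold_basis": self.threshold_basis,
            "frac_below_threshold": self.frac_below_threshold,
            "n_records": self.n_records,
            "alignment_residuals_cm": dict(self.alignment_residuals),
        }


def landmark_errors(
    reference_obs: Iterable[LandmarkObservation],
    device_obs_transformed: Iterable[LandmarkObservation],
) -> list[ErrorRecord]:
    """Per-landmark error records from matched reference/device observations.

    Matching is on (landmark, subject, trial).  Keys present in only one of the
    two sets are excluded with a logged warning, never imputed.  Device
    observations must already be in the reference frame.
    """
    ref = {}
    for o in reference_obs:
        if o.system != SYSTEM_REFERENCE:
            raise ValueError(f"expected reference observations, got system={o.system!r}")
        if o.key in ref:
            raise ValueError(f"duplicate reference observation for {o.key}")
        ref[o.key] = o
    dev = {}
    for o in device_obs_transformed:
        if o.system != SYSTEM_DEVICE:
            raise ValueError(f"expected device observations, got system={o.system!r}")
        if o.key in dev:
            raise ValueError(f"duplicate device observation for {o.key}")
        dev[o.key] = o

    unmatched = sorted(set(ref) ^ set(dev))
    if unmatched:
        logger.warning(
            "%d unmatched landmark observation key(s) excluded: %s",
            len(unmatched),
            unmatched[:10],
        )
    records = [
        ErrorRecord.from_points(
            *key, ref[key].point, dev[key].point, camera=dev[key].camera
        )
        for key in ref
        if key in dev
    ]
    return records


def aggregate_report(
    records: Sequence[ErrorRecord],
    threshold: float = 2.0,
    threshold_basis: str = "axis",
    alignment_residuals: Mapping[str, float] | None = None,
) -> BenchmarkReport:
    """Aggregate error records into a :class:`BenchmarkReport`.

    Every (subject, trial) record carries equal weight; per-landmark means are
    taken across subjects and trials jointly.
    """
    if not records:
        raise ValueError("cannot aggregate an empty record list")
    if threshold_basis not in ("axis", "er"):
        raise ValueError("threshold_basis must be 'axis' or 'er'")
    df = records_to_frame(records)
    agg = df.groupby("landmark")[["er", "ax_x", "ax_y", "ax_z"]].agg(["mean", "std", "size"])
    per_landmark = pd.DataFrame(
        {
            "er_mean": agg[("er", "mean")],
            "er_sd": agg[("er", "std")],
            "x_mean": agg[("ax_x", "mean")],
            "x_sd": agg[("ax_x", "std")],
            "y_mean": agg[("ax_y", "mean")],
            "y_sd": agg[("ax_y", "std")],
            "z_mean": agg[("ax_z", "mean")],
            "z_sd": agg[("ax_z", "std")],
            "n": agg[("er", "size")].astype(int),
        }
    )
    if threshold_basis == "axis":
        vals = df[["ax_x", "ax_y", "ax_z"]].to_numpy().ravel()
    else:
        vals = df["er"].to_numpy()
    lm_means = per_landmark["er_mean"]
    return BenchmarkReport(
        per_landmark=per_landmark,
        overall_mean_er=float(df["er"].mean()),
        overall_sd_er=float(lm_means.std(ddof=1)) if len(lm_means) > 1 else 0.0,
        axis_mean={a: float(df[f"ax_{a}"].mean()) for a in "xyz"},
        axis_sd={
            a: float(per_landmark[f"{a}_mean"].std(ddof=1)) if len(per_landmark) > 1 else 0.0
            for a in "xyz"
        },
        min_landmark_mean_er=float(lm_means.min()),
        max_landmark_mean_er=float(lm_means.max()),
        threshold=float(threshold),
        threshold_basis=threshold_basis,
        frac_below_threshold=float(np.mean(vals < threshold)),
        n_records=len(df),
        alignment_residuals=dict(alignment_residuals or {}),
    )


def run_benchmark(
    session: BenchmarkSession,
    threshold: float = 2.0,
    threshold_basis: str = "axis",
    residual_warning: float = 2.0,
    return_details: bool = False,
):
    """Run the full benchmark: align each camera, transform, pool, aggregate.

    One rigid transform is fitted per camera from its alignment-board pair;
    each camera's device landmark observations are mapped through *its own*
    transform, error records are pooled across cameras, and the aggregate
    report is returned.  Deterministic given its inputs.

    With ``return_details=True`` returns
    ``(report, records, alignments)`` instead of just the report.
    """
    cameras = sorted(set(session.camera_map.values()))
    missing = [c for c in cameras if c not in session.boards]
    if missing:
        raise ValueError(f"missing board capture for camera(s): {missing}")

    alignments: dict[str, AlignmentResult] = {}
    for cam in cameras:
        pair = session.boards[cam]
        res = estimate_rigid_transform(pair.device, pair.reference)
        if res.residual_error > residual_warning:
            logger.warning(
                "alignment residual for camera %r is %.2f cm (warning threshold %.2f cm)",
                cam,
                res.residual_error,
                residual_warning,
            )
        alignments[cam] = res

    reference_obs = [o for o in session.observations if o.system == SYSTEM_REFERENCE]
    device_obs = []
    for o in session.observations:
        if o.system != SYSTEM_DEVICE:
            continue
        cam = session.camera_map.get(o.landmark)
        if cam is None:
            raise ValueError(f"landmark {o.landmark!r} has no camera assignment")
        transform = alignments[cam].transform
        device_obs.append(
            LandmarkObservation(
                o.landmark,
                o.subject,
                o.trial,
                SYSTEM_DEVICE,
                tuple(transform.apply(np.asarray(o.point))),
                camera=cam,
            )
        )
    records = landmark_errors(reference_obs, device_obs)
    report = aggregate_report(
        records,
        threshold=threshold,
        threshold_basis=threshold_basis,
        alignment_residuals={c: a.residual_error for c, a in alignments.items()},
    )
    if return_details:
        return report, records, alignments
    return report


def records_to_frame(records: Sequence[ErrorRecord]) -> pd.DataFrame:
    """Error records as a tidy DataFrame (one row per record)."""
    return pd.DataFrame(
        {
            "landmark": [r.landmark for r in records],
            "subject": [r.subject for r in records],
            "trial": [r.trial for r in records],
            "camera": [r.camera for r in records],
            "er": [r.er for r in records],
            "ax_x": [r.ax_x for r in records],
            "ax_y": [r.ax_y for r in records],
            "ax_z": [r.ax_z for r in records],
        }
    )


def records_from_frame(df: pd.DataFrame) -> list[ErrorRecord]:
    """Inverse of :func:`records_to_frame`."""
    required = {"landmark", "subject", "trial", "er", "ax_x", "ax_y", "ax_z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"error-record table is missing columns: {sorted(missing)}")
    return [
        ErrorRecord(
            landmark=str(row.landmark),
            subject=str(row.subject),
            trial=int(row.trial),
            er=float(row.er),
            ax_x=float(row.ax_x),
            ax_y=float(row.ax_y),
            ax_z=float(row.ax_z),
            camera=(str(row.camera) if "camera" in df.columns and pd.notna(row.camera) else None),
        )
        for row in df.itertuples()
    ]
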