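"""File formats: marker/landmark CSV tables, session directories, XLSX workbooks.

All coordinates are stored with an explicit unit declaration (``cm``, ``mm`` or
``m``); the in-memory canonical unit is cm.  CSV files may start with comment
lines of the form ``# key=value`` declaring ``frame`` and ``units``; parse
errors name the offending column, label or line number.

A *session directory* is the on-disk form of a :class:`~depthbench.metrics.BenchmarkSession`:

.. code-block:: text

    session/
      board_<camera>_device.csv      # label,x,y,z  (frame D)
      board_<camera>_reference.csv   # label,x,y,z  (frame M)
      landmarks.csv                  # landmark,subject,trial,system,camera,x,y,z
      session.json                   # cameras, camera_map, units, seed, config hash

The same content can live in a single XLSX workbook whose sheet names and
column meanings are described by a small *descriptor* mapping (YAML/JSON),
so externally produced workbooks can be ingested by editing the descriptor
rather than the code.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .metrics import (
    SYSTEM_DEVICE,
    SYSTEM_REFERENCE,
    BenchmarkSession,
    BoardPair,
    ErrorRecord,
    LandmarkObservation,
    records_from_frame,
    records_to_frame,
)
from .registration import FRAME_DEVICE, FRAME_REFERENCE, MarkerSet

__all__ = [
    "UNIT_TO_CM",
    "MarkerTableError",
    "WorkbookError",
    "SessionConfig",
    "read_marker_table",
    "write_marker_table",
    "read_landmark_table",
    "write_landmark_table",
    "read_error_records",
    "write_error_records",
    "write_session_dir",
    "read_session_dir",
    "write_session_workbook",
    "read_session_workbook",
    "default_workbook_descriptor",
    "load_config",
    "config_hash",
]

UNIT_TO_CM = {"cm": 1.0, "mm": 0.1, "m": 100.0}

_LANDMARK_COLUMNS = ["landmark", "subject", "trial", "system", "camera", "x", "y", "z"]


class MarkerTableError(ValueError):
    """A marker/landmark CSV could not be parsed."""


class WorkbookError(ValueError):
    """A session workbook did not match its descriptor."""


def _unit_factor(units: str) -> float:
    if units not in UNIT_TO_CM:
        raise MarkerTableError(f"unknown units {units!r}; expected one of {sorted(UNIT_TO_CM)}")
    return UNIT_TO_CM[units]


def _split_comments(path: Path) -> tuple[dict[str, str], list[str], int]:
    """Leading ``# key=value`` comments, remaining lines, line-number offset."""
    meta: dict[str, str] = {}
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines) and lines[i].lstrip().startswith("#"):
        body = lines[i].lstrip().lstrip("#").strip()
        if "=" in body:
            key, _, val = body.partition("=")
            meta[key.strip()] = val.strip()
        i += 1
    return meta, lines[i:], i


def read_marker_table(
    path: str | Path, units: str | None = None, frame: str | None = None
) -> MarkerSet:
    """Read a ``label,x,y,z`` CSV into a cm :class:`MarkerSet`.

    ``units``/``frame`` arguments override any ``# units=`` / ``# frame=``
    comment in the file; units default to cm, frame to the reference frame.
    Row order is preserved.
    """
    path = Path(path)
    meta, lines, offset = _split_comments(path)
    units = units or meta.get("units", "cm")
    frame = frame or meta.get("frame", FRAME_REFERENCE)
    factor = _unit_factor(units)

    reader = csv.DictReader(lines)
    if reader.fieldnames is None:
        raise MarkerTableError(f"{path.name}: empty file")
    header = [h.strip() for h in reader.fieldnames]
    missing = [c for c in ("label", "x", "y", "z") if c not in header]
    if missing:
        raise MarkerTableError(f"{path.name}: missing column(s) {missing}")

    labels: list[str] = []
    pts: list[tuple[float, float, float]] = []
    seen: set[str] = set()
    for rownum, row in enumerate(reader, start=offset + 2):
        row = {k.strip(): (v.strip() if isinstance(v, str) else v) for k, v in row.items()}
        label = row["label"]
        if label in seen:
            raise MarkerTableError(f"{path.name}: duplicate label {label!r} at line {rownum}")
        seen.add(label)
        try:
            xyz = tuple(float(row[c]) * factor for c in ("x", "y", "z"))
        except (TypeError, ValueError):
            raise MarkerTableError(
                f"{path.name}: non-numeric coordinate at line {rownum} (label {label!r})"
            ) from None
        labels.append(label)
        pts.append(xyz)
    return MarkerSet(frame, tuple(labels), np.array(pts, dtype=float).reshape(len(pts), 3))


def write_marker_table(
    path: str | Path,
    marker_set: MarkerSet,
    units: str = "cm",
    extra_comments: Mapping[str, str] | None = None,
) -> None:
    """Write a marker set as ``label,x,y,z`` CSV with frame/units comments."""
    path = Path(path)
    factor = _unit_factor(units)
    lines = [f"# frame={marker_set.frame}", f"# units={units}"]
    for key, val in (extra_comments or {}).items():
        lines.append(f"# {key}={val}")
    lines.append("label,x,y,z")
    for label, p in zip(marker_set.labels, marker_set.points):
        x, y, z = (float(v) / factor for v in p)
        lines.append(f"{label},{x!r},{y!r},{z!r}")
    path.write_text("\n".join(lines) + "\n")


def read_landmark_table(path: str | Path, units: str | None = None) -> list[LandmarkObservation]:
    """Read ``landmark,subject,trial,system,camera,x,y,z`` rows (cm-canonical)."""
    path = Path(path)
    meta, lines, offset = _split_comments(path)
    factor = _unit_factor(units or meta.get("units", "cm"))
    df = pd.read_csv(pd.io.common.StringIO("\n".join(lines)), float_precision="round_trip")
    missing = [c for c in _LANDMARK_COLUMNS if c not in df.columns and c != "camera"]
    if missing:
        raise MarkerTableError(f"{path.name}: missing column(s) {missing}")
    obs = []
    for idx, row in enumerate(df.itertuples(), start=offset + 2):
        try:
            point = (float(row.x) * factor, float(row.y) * factor, float(row.z) * factor)
        except (TypeError, ValueError):
            raise MarkerTableError(f"{path.name}: non-numeric coordinate at line {idx}") from None
        camera = getattr(row, "camera", None)
        obs.append(
            LandmarkObservation(
                landmark=str(row.landmark),
                subject=str(row.subject),
                trial=int(row.trial),
                system=str(row.system),
                point=point,
                camera=None if camera is None or pd.isna(camera) else str(camera),
            )
        )
    return obs


def write_landmark_table(
    path: str | Path,
    observations: Sequence[LandmarkObservation],
    units: str = "cm",
    extra_comments: Mapping[str, str] | None = None,
) -> None:
    """Write landmark observations as CSV (inverse of :func:`read_landmark_table`)."""
    path = Path(path)
    factor = _unit_factor(units)
    lines = [f"# units={units}"]
    for key, val in (extra_comments or {}).items():
        lines.append(f"# {key}={val}")
    lines.append(",".join(_LANDMARK_COLUMNS))
    for o in observations:
        x, y, z = (v / factor for v in o.point)
        lines.append(
            f"{o.landmark},{o.subject},{o.trial},{o.system},{o.camera or ''},{x!r},{y!r},{z!r}"
        )
    path.write_text("\n".join(lines) + "\n")


def write_error_records(path: str | Path, records: Sequence[ErrorRecord]) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_error_records(path: str | Path) -> list[ErrorRecord]:
    return records_from_frame(pd.read_csv(path, comment="#", float_precision="round_trip"))


# ---------------------------------------------------------------------------
# session directory


def write_session_dir(
    directory: str | Path, session: BenchmarkSession, meta: Mapping[str, Any] | None = None
) -> None:
    """Write a session (boards + landmarks + metadata JSON) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cam, pair in sorted(session.boards.items()):
        write_marker_table(directory / f"board_{cam}_device.csv", pair.device)
        write_marker_table(directory / f"board_{cam}_reference.csv", pair.reference)
    write_landmark_table(directory / "landmarks.csv", session.observations)
    payload = {
        "cameras": sorted(session.boards),
        "camera_map": dict(sorted(session.camera_map.items())),
        "units": "cm",
        **(dict(meta) if meta else {}),
    }
    (directory / "session.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_session_dir(directory: str | Path) -> tuple[BenchmarkSession, dict[str, Any]]:
    """Read a session directory back; returns ``(session, metadata)``."""
    directory = Path(directory)
    meta_path = directory / "session.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"{directory} is not a session directory (no session.json)")
    meta = json.loads(meta_path.read_text())
    boards = {}
    for cam in meta["cameras"]:
        boards[cam] = BoardPair(
            device=read_marker_table(directory / f"board_{cam}_device.csv"),
            reference=read_marker_table(directory / f"board_{cam}_reference.csv"),
        )
    observations = read_landmark_table(directory / "landmarks.csv")
    return (
        BenchmarkSession(boards=boards, observations=observations, camera_map=meta["camera_map"]),
        meta,
    )


# ---------------------------------------------------------------------------
# XLSX workbook


def default_workbook_descriptor(cameras: Sequence[str] = ("front", "back")) -> dict:
    """Descriptor for the workbook layout this package writes itself."""
    return {
        "units": "cm",
        "boards": {
            cam: {
                "device": f"board_{cam}_device",
                "reference": f"board_{cam}_reference",
            }
            for cam in cameras
        },
        "landmarks": {
            "sheet": "landmarks",
            "columns": {c: c for c in _LANDMARK_COLUMNS},
        },
        "camera_map": {"sheet": "camera_map", "columns": {"landmark": "landmark", "camera": "camera"}},
    }


def write_session_workbook(
    path: str | Path, session: BenchmarkSession, descriptor: Mapping[str, Any] | None = None
) -> None:
    """Export a session to one XLSX workbook (layout per the descriptor)."""
    desc = descriptor or default_workbook_descriptor(sorted(session.boards))
    factor = _unit_factor(desc.get("units", "cm"))
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for cam, sheets in desc["boards"].items():
            pair = session.boards[cam]
            for role, ms in (("device", pair.device), ("reference", pair.reference)):
                pd.DataFrame(
                    {
                        "label": ms.labels,
                        "x": ms.points[:, 0] / factor,
                        "y": ms.points[:, 1] / factor,
                        "z": ms.points[:, 2] / factor,
                    }
                ).to_excel(writer, sheet_name=sheets[role], index=False)
        lm = desc["landmarks"]
        cols = lm["columns"]
        obs = session.observations
        pd.DataFrame(
            {
                cols["landmark"]: [o.landmark for o in obs],
                cols["subject"]: [o.subject for o in obs],
                cols["trial"]: [o.trial for o in obs],
                cols["system"]: [o.system for o in obs],
                cols["camera"]: [o.camera or "" for o in obs],
                cols["x"]: [o.point[0] / factor for o in obs],
                cols["y"]: [o.point[1] / factor for o in obs],
                cols["z"]: [o.point[2] / factor for o in obs],
            }
        ).to_excel(writer, sheet_name=lm["sheet"], index=False)
        cm = desc["camera_map"]
        pd.DataFrame(
            sorted(session.camera_map.items()), columns=[cm["columns"]["landmark"], cm["columns"]["camera"]]
        ).to_excel(writer, sheet_name=cm["sheet"], index=False)


def read_session_workbook(
    path: str | Path, descriptor: Mapping[str, Any] | str | Path | None = None
) -> BenchmarkSession:
    """Read a session from an XLSX workbook described by ``descriptor``.

    ``descriptor`` may be a mapping, a YAML/JSON file path, or None for the
    package's own layout.  Missing sheets or columns raise
    :class:`WorkbookError` naming the offender.
    """
    path = Path(path)
    if isinstance(descriptor, (str, Path)):
        descriptor = load_config(descriptor)
    xls = pd.ExcelFile(path, engine="openpyxl")
    desc = descriptor or default_workbook_descriptor(
        sorted(k.split("_")[1] for k in xls.sheet_names if k.startswith("board_") and k.endswith("_device"))
    )
    factor = _unit_factor(desc.get("units", "cm"))

    def sheet(name: str) -> pd.DataFrame:
        if name not in xls.sheet_names:
            raise WorkbookError(f"{path.name}: missing sheet {name!r}")
        return xls.parse(name)

    def col(df: pd.DataFrame, sheet_name: str, name: str) -> pd.Series:
        if name not in df.columns:
            raise WorkbookError(f"{path.name}: sheet {sheet_name!r} is missing column {name!r}")
        return df[name]

    boards = {}
    for cam, sheets in desc["boards"].items():
        pair = {}
        for role, frame in (("device", FRAME_DEVICE), ("reference", FRAME_REFERENCE)):
            df = sheet(sheets[role])
            pts = np.column_stack(
                [col(df, sheets[role], c).to_numpy(dtype=float) * factor for c in ("x", "y", "z")]
            )
            pair[role] = MarkerSet(frame, tuple(col(df, sheets[role], "label").astype(str)), pts)
        boards[cam] = BoardPair(device=pair["device"], reference=pair["reference"])

    lm = desc["landmarks"]
    cols = lm["columns"]
    df = sheet(lm["sheet"])
    observations = []
    for i in range(len(df)):
        camera = ""
        if cols.get("camera") in df.columns:
            raw = df[cols["camera"]].iloc[i]
            camera = "" if pd.isna(raw) else str(raw)
        observations.append(
            LandmarkObservation(
                landmark=str(col(df, lm["sheet"], cols["landmark"]).iloc[i]),
                subject=str(col(df, lm["sheet"], cols["subject"]).iloc[i]),
                trial=int(col(df, lm["sheet"], cols["trial"]).iloc[i]),
                system=str(col(df, lm["sheet"], cols["system"]).iloc[i]),
                point=tuple(
                    float(col(df, lm["sheet"], cols[c]).iloc[i]) * factor for c in ("x", "y", "z")
                ),
                camera=camera or None,
            )
        )

    cmdesc = desc["camera_map"]
    df = sheet(cmdesc["sheet"])
    camera_map = dict(
        zip(
            col(df, cmdesc["sheet"], cmdesc["columns"]["landmark"]).astype(str),
            col(df, cmdesc["sheet"], cmdesc["columns"]["camera"]).astype(str),
        )
    )
    return BenchmarkSession(boards=boards, observations=observations, camera_map=camera_map)


# ---------------------------------------------------------------------------
# config


@dataclass
class SessionConfig:
    """A benchmark run description loaded from YAML/JSON.

    Paths are resolved relative to the config file's directory and must exist
    at load time.
    """

    boards: dict[str, dict[str, Path]]
    landmarks: Path
    camera_map: dict[str, str]
    units: str = "cm"
    threshold_cm: float = 2.0
    threshold_basis: str = "axis"
    icc_form: str = "absolute_agreement"
    output_dir: Path | None = None
    seed: int | None = None
    log_level: str = "INFO"
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_file(cls, path: str | Path) -> "SessionConfig":
        path = Path(path)
        data = load_config(path)
        base = path.parent

        def resolve(p: str) -> Path:
            q = (base / p).resolve() if not Path(p).is_absolute() else Path(p)
            if not q.exists():
                raise FileNotFoundError(f"config references missing path: {p}")
            return q

        units = data.get("units", "cm")
        if units not in UNIT_TO_CM:
            raise ValueError(f"config units must be one of {sorted(UNIT_TO_CM)}, got {units!r}")
        boards = {
            cam: {role: resolve(p) for role, p in pair.items()}
            for cam, pair in data["boards"].items()
        }
        camera_map = data["camera_map"]
        if isinstance(camera_map, str):
            df = pd.read_csv(resolve(camera_map))
            camera_map = dict(zip(df["landmark"].astype(str), df["camera"].astype(str)))
        return cls(
            boards=boards,
            landmarks=resolve(data["landmarks"]),
            camera_map=dict(camera_map),
            units=units,
            threshold_cm=float(data.get("threshold_cm", 2.0)),
            threshold_basis=data.get("threshold_basis", "axis"),
            icc_form=data.get("icc_form", "absolute_agreement"),
            output_dir=Path(data["output_dir"]) if "output_dir" in data else None,
            seed=data.get("seed"),
            log_level=data.get("log_level", "INFO"),
            raw=data,
        )

    def load_session(self) -> BenchmarkSession:
        boards = {
            cam: BoardPair(
                device=read_marker_table(paths["device"], units=self.units, frame=FRAME_DEVICE),
                reference=read_marker_table(paths["reference"], units=self.units, frame=FRAME_REFERENCE),
            )
            for cam, paths in self.boards.items()
        }
        observations = read_landmark_table(self.landmarks, units=self.units)
        return BenchmarkSession(boards=boards, observations=observations, camera_map=self.camera_map)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON mapping."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path.name}: expected a mapping at top level")
    return data


def config_hash(obj: Any) -> str:
    """Short deterministic digest of a JSON-serialisable config object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
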