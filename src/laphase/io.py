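"""CSV interchange: writers, readers and schema validation.

All tables are UTF-8 CSV with a header row and '.' decimal separator.
Floats are serialized at fixed precision so repeated runs with the same
seed are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from laphase.curves import EventFrames, TimeVolumeCurve
from laphase.errors import SchemaError
from laphase.synthetic import BiplaneFrame, GroundTruthPatient
from laphase.volumetry import EmptyingFractions, PhasicVolumes

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6f"

COHORT_COLUMNS = [
    "patient_id", "group", "bsa_m2", "lvedp_mmhg", "heart_rate",
    "true_lav_min", "true_lav_ac", "true_lav_max",
    "n_frames", "frame_mv_open", "frame_ac_onset", "frame_mv_close",
]
CURVES_COLUMNS = ["patient_id", "frame", "time_ms", "volume_ml_m2"]
BIPLANE_COLUMNS = [
    "patient_id", "observer_id", "frame", "a1_cm2", "a2_cm2", "l_cm",
]
PHASIC_COLUMNS = [
    "patient_id", "observer_id", "method", "flags",
    "lav_min", "lav_ac", "lav_max",
    "laef_total", "laef_passive", "laef_contractile",
]

#: fraction of invalid rows above which validation aborts
MAX_INVALID_FRACTION = 0.10


def write_table(df: pd.DataFrame, path: Path) -> None:
    """Deterministic CSV serialization (fixed float precision, LF endings)."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


_write = write_table


def write_cohort(patients: list[GroundTruthPatient], path: Path) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "group": p.group,
            "bsa_m2": p.bsa,
            "lvedp_mmhg": p.lvedp,
            "heart_rate": p.heart_rate,
            "true_lav_min": p.true_lav_min,
            "true_lav_ac": p.true_lav_ac,
            "true_lav_max": p.true_lav_max,
            "n_frames": p.n_frames,
            "frame_mv_open": p.event_frames.mv_open,
            "frame_ac_onset": p.event_frames.ac_onset,
            "frame_mv_close": p.event_frames.mv_close,
        }
        for p in patients
    ]
    _write(pd.DataFrame(rows, columns=COHORT_COLUMNS), Path(path))


def write_curves(curves: list[TimeVolumeCurve], path: Path) -> None:
    """Long-format curve table: one row per (patient, frame)."""
    parts = []
    for c in curves:
        parts.append(
            pd.DataFrame(
                {
                    "patient_id": c.patient_id,
                    "frame": np.arange(c.n_frames),
                    "time_ms": c.times,
                    "volume_ml_m2": c.volumes,
                }
            )
        )
    _write(pd.concat(parts, ignore_index=True)[CURVES_COLUMNS], Path(path))


def write_biplane(frames: list[BiplaneFrame], path: Path) -> None:
    rows = [
        {
            "patient_id": f.patient_id,
            "observer_id": f.observer_id,
            "frame": f.frame_index,
            "a1_cm2": f.a1,
            "a2_cm2": f.a2,
            "l_cm": f.length_l,
        }
        for f in frames
    ]
    _write(pd.DataFrame(rows, columns=BIPLANE_COLUMNS), Path(path))


def write_phasic(
    records: list[tuple[PhasicVolumes, EmptyingFractions | None]],
    path: Path,
    observer_id: str = "obs1",
) -> None:
    rows = []
    for pv, ef in records:
        rows.append(
            {
                "patient_id": pv.patient_id,
                "observer_id": observer_id,
                "method": pv.method,
                "flags": ";".join(sorted(pv.flags)),
                "lav_min": pv.lav_min,
                "lav_ac": pv.lav_ac,
                "lav_max": pv.lav_max,
                "laef_total": ef.laef_total if ef else np.nan,
                "laef_passive": ef.laef_passive if ef else np.nan,
                "laef_contractile": ef.laef_contractile if ef else np.nan,
            }
        )
    _write(pd.DataFrame(rows, columns=PHASIC_COLUMNS), Path(path))


@dataclass
class ValidationReport:
    path: str
    n_rows: int
    invalid_rows: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_valid(self) -> int:
        return self.n_rows - len(self.invalid_rows)

    def raise_if_excessive(self) -> None:
        if self.n_rows and len(self.invalid_rows) > MAX_INVALID_FRACTION * self.n_rows:
            detail = "; ".join(
                f"line {ln}: {msg}" for ln, msg in self.invalid_rows[:5]
            )
            raise SchemaError(
                f"{self.path}: {len(self.invalid_rows)}/{self.n_rows} rows "
                f"invalid (> {MAX_INVALID_FRACTION:.0%}); first failures: {detail}"
            )


def _require_columns(df: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _row_checks(
    df: pd.DataFrame, checks: dict[str, tuple], report: ValidationReport
) -> pd.DataFrame:
    """Apply per-column (lo, hi, label) range checks; collect bad rows.

    Line numbers are 1-based file lines (header is line 1).
    """
    bad = pd.Series(False, index=df.index)
    for col, (lo, hi, label) in checks.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        mask = ~((vals > lo) & (vals <= hi))
        for i in df.index[mask]:
            report.invalid_rows.append((int(i) + 2, f"{col} {label}"))
        bad |= mask
    return df[~bad]


def validate_cohort(path: Path) -> tuple[pd.DataFrame, ValidationReport]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, COHORT_COLUMNS, str(path))
    report = ValidationReport(str(path), len(df))
    df = _row_checks(
        df,
        {
            "lvedp_mmhg": (0.0, 60.0, "must be in (0, 60]"),
            "bsa_m2": (0.5, 3.5, "must be in (0.5, 3.5]"),
            "true_lav_min": (0.0, np.inf, "must be > 0"),
            "true_lav_ac": (0.0, np.inf, "must be > 0"),
            "true_lav_max": (0.0, np.inf, "must be > 0"),
        },
        report,
    )
    report.raise_if_excessive()
    if report.invalid_rows:
        logger.warning(
            "%s: excluded %d invalid rows", path, len(report.invalid_rows)
        )
    return df, report


def validate_curves(path: Path) -> tuple[pd.DataFrame, ValidationReport]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, CURVES_COLUMNS, str(path))
    report = ValidationReport(str(path), len(df))
    df = _row_checks(
        df,
        {
            "volume_ml_m2": (0.0, np.inf, "must be > 0"),
            "time_ms": (-1e-9, np.inf, "must be >= 0"),
        },
        report,
    )
    report.raise_if_excessive()
    return df, report


def validate_biplane(path: Path) -> tuple[pd.DataFrame, ValidationReport]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, BIPLANE_COLUMNS, str(path))
    report = ValidationReport(str(path), len(df))
    df = _row_checks(
        df,
        {
            "a1_cm2": (0.0, np.inf, "must be > 0"),
            "a2_cm2": (0.0, np.inf, "must be > 0"),
            "l_cm": (0.0, np.inf, "must be > 0"),
        },
        report,
    )
    report.raise_if_excessive()
    return df, report


def validate_phasic(path: Path) -> tuple[pd.DataFrame, ValidationReport]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, PHASIC_COLUMNS, str(path))
    report = ValidationReport(str(path), len(df))
    df = _row_checks(
        df,
        {
            "lav_min": (0.0, np.inf, "must be > 0"),
            "lav_ac": (0.0, np.inf, "must be > 0"),
            "lav_max": (0.0, np.inf, "must be > 0"),
        },
        report,
    )
    report.raise_if_excessive()
    return df, report


def curves_from_frame(df: pd.DataFrame) -> list[TimeVolumeCurve]:
    """Reassemble TimeVolumeCurve objects from a long-format curve table."""
    curves = []
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("frame")
        times = grp["time_ms"].to_numpy(dtype=float)
        volumes = grp["volume_ml_m2"].to_numpy(dtype=float)
        n = len(times)
        dt = times[1] - times[0] if n > 1 else 30.0
        curves.append(
            TimeVolumeCurve(
                patient_id=str(pid),
                times=times,
                volumes=volumes,
                rr_interval=float(times[-1] + dt),
            )
        )
    return curves


def events_from_cohort_row(row: pd.Series) -> EventFrames:
    return EventFrames(
        mv_open=int(row["frame_mv_open"]),
        ac_onset=int(row["frame_ac_onset"]),
        mv_close=int(row["frame_mv_close"]),
    )
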