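"""End-to-end study pipeline: simulate -> quantify -> evaluate -> agree.

One global seed deterministically derives per-stage seeds, so a full run
with a fixed seed is byte-identical across invocations.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from laphase import io as lio
from laphase.agreement import bland_altman, replicate_study
from laphase.curves import TimeVolumeCurve
from laphase.diagnostics import (
    GREATER,
    LESS,
    dichotomize_lvedp,
    evaluate_index,
    group_compare,
)
from laphase.errors import ConfigError
from laphase.phase_extraction import extract_multi_phase, extract_single_phase
from laphase.synthetic import (
    CohortConfig,
    build_curve,
    project_biplane,
    sample_cohort,
)
from laphase.volumetry import (
    MULTI_PHASE,
    SINGLE_PHASE,
    PhasicVolumes,
    emptying_fractions,
    volumes_from_biplane,
)

logger = logging.getLogger(__name__)

#: analysis indices: (name, phasic column, ROC direction)
VOLUME_INDICES = [
    ("LAV_min", "lav_min", GREATER),
    ("LAV_max", "lav_max", GREATER),
    ("LAV_ac", "lav_ac", GREATER),
]
LAEF_INDICES = [
    ("LAEF_Passive", "laef_passive", LESS),
    ("LAEF_Contractile", "laef_contractile", LESS),
    ("LAEF_Total", "laef_total", LESS),
]
ALL_INDICES = VOLUME_INDICES + LAEF_INDICES


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    method: str = "both"  # single | multi | both
    smooth_window: int = 3
    flat_tol: float = 0.05
    lvedp_threshold: float = 12.0
    welch: bool = False
    n_replicates: int = 2
    replicate_cases: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.method not in ("single", "multi", "both"):
            raise ConfigError(f"unknown extraction method {self.method!r}")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ConfigError("smooth_window must be a positive odd integer")
        if not 0 < self.lvedp_threshold < 60:
            raise ConfigError("lvedp_threshold must be in (0, 60)")
        self.cohort.validate()


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(3)
    names = ("cohort", "observer_noise", "replicates")
    return {n: int(k.generate_state(1)[0]) for n, k in zip(names, kids)}


def quantify_patient(
    measured: TimeVolumeCurve,
    events,
    method: str,
    smooth_window: int,
    flat_tol: float,
    noisy: bool,
) -> list[PhasicVolumes]:
    out = []
    window = smooth_window if noisy else 1
    if method in ("single", "both"):
        out.append(extract_single_phase(measured, events))
    if method in ("multi", "both"):
        out.append(
            extract_multi_phase(measured, smooth_window=window, flat_tol=flat_tol)
        )
    return out


def phasic_records(
    pvs: list[PhasicVolumes],
) -> list[tuple[PhasicVolumes, object | None]]:
    """Attach emptying fractions to usable triples; leave flagged ones bare."""
    records = []
    for pv in pvs:
        records.append((pv, emptying_fractions(pv) if pv.usable else None))
    return records


def _phasic_table(records, observer_id="obs1") -> pd.DataFrame:
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
    return pd.DataFrame(rows, columns=lio.PHASIC_COLUMNS)


def evaluate_tables(
    phasic: pd.DataFrame,
    cohort: pd.DataFrame,
    threshold: float = 12.0,
    method: str = SINGLE_PHASE,
    welch: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Group-comparison and ROC tables for one extraction method.

    Flagged records and records with missing LVEDP are excluded; exclusion
    counts are returned alongside the tables.
    """
    sub = phasic[(phasic["method"] == method)].copy()
    n_input = len(sub)
    sub = sub[sub["flags"].fillna("") == ""]
    n_flagged = n_input - len(sub)
    merged = sub.merge(
        cohort[["patient_id", "lvedp_mmhg"]], on="patient_id", how="inner"
    )
    merged = merged[merged["lvedp_mmhg"].notna()]
    n_missing = len(sub) - len(merged)
    labels = np.array(
        [
            dichotomize_lvedp(v, threshold) == "elevated"
            for v in merged["lvedp_mmhg"]
        ]
    )
    if labels.sum() == 0 or (~labels).sum() == 0:
        raise ConfigError(
            "cohort has a single LVEDP class; diagnostics undefined"
        )

    t2_rows, t3_rows = [], []
    for name, col, direction in ALL_INDICES:
        values = merged[col].to_numpy(dtype=float)
        # LAEF reported as percent in the comparison table
        scale = 100.0 if col.startswith("laef") else 1.0
        gc = group_compare(values * scale, labels, index_name=name, welch=welch)
        t2_rows.append(dataclasses.asdict(gc))
        rep = evaluate_index(name, values, labels, direction)
        t3_rows.append(dataclasses.asdict(rep))
    gc = group_compare(
        merged["lvedp_mmhg"].to_numpy(dtype=float), labels,
        index_name="LVEDP", welch=welch,
    )
    t2_rows.append(dataclasses.asdict(gc))

    counts = {
        "n_input": n_input,
        "n_flagged": n_flagged,
        "n_missing_lvedp": n_missing,
        "n_analyzed": len(merged),
    }
    if n_flagged or n_missing:
        logger.warning(
            "evaluation exclusions: %d flagged, %d missing LVEDP "
            "(%d analyzed of %d)",
            n_flagged, n_missing, len(merged), n_input,
        )
    return pd.DataFrame(t2_rows), pd.DataFrame(t3_rows), counts


def _fmt_pct0(x: float) -> str:
    return f"{100 * x:.0f}%"


def write_summary(
    path: Path,
    table2: pd.DataFrame,
    table3: pd.DataFrame,
    agreement: pd.DataFrame,
    counts: dict,
) -> None:
    """Plain-text study summary in results-narrative order."""
    lines = ["Phasic LA quantitation study summary", "=" * 38, ""]
    lvedp = table2[table2["index_name"] == "LVEDP"].iloc[0]
    lines.append(
        f"Analyzed {counts['n_analyzed']} patients: "
        f"{int(lvedp['n_elevated'])} with elevated LVEDP (>12 mmHg), "
        f"{int(lvedp['n_normal'])} with normal LVEDP "
        f"({counts['n_flagged']} flagged records and "
        f"{counts['n_missing_lvedp']} missing-LVEDP records excluded)."
    )
    lines.append("")
    lines.append("Group comparison (mean +/- SD, elevated vs normal):")
    for _, r in table2.iterrows():
        unit = "%" if r["index_name"].startswith("LAEF") else (
            " mmHg" if r["index_name"] == "LVEDP" else " mL/m^2"
        )
        lines.append(
            f"  {r['index_name']:<17} {r['mean_elevated']:.0f} +/- "
            f"{r['sd_elevated']:.0f}{unit} vs {r['mean_normal']:.0f} +/- "
            f"{r['sd_normal']:.0f}{unit} (p = {r['p_value']:.3f})"
        )
    lines.append("")
    lines.append("ROC analysis vs elevated LVEDP:")
    for _, r in table3.iterrows():
        if pd.isna(r["cutoff"]):
            crit = "cutoff undefined"
        else:
            sym = ">=" if r["direction"] == GREATER else "<="
            if r["index_name"].startswith("LAEF"):
                crit = (
                    f"{sym} {100 * r['cutoff']:.0f}%, sensitivity "
                    f"{_fmt_pct0(r['sensitivity'])}, specificity "
                    f"{_fmt_pct0(r['specificity'])}"
                )
            else:
                crit = (
                    f"{sym} {r['cutoff']:.0f} mL/m^2, sensitivity "
                    f"{_fmt_pct0(r['sensitivity'])}, specificity "
                    f"{_fmt_pct0(r['specificity'])}"
                )
        lines.append(
            f"  {r['index_name']:<17} AUC {r['auc']:.3f} "
            f"(p = {r['auc_p']:.3f}), {crit}"
        )
    if len(agreement):
        lines.append("")
        lines.append("Method agreement and observer variability:")
        for _, r in agreement.iterrows():
            if not pd.isna(r["mean_diff"]):
                lines.append(
                    f"  {r['comparison']:<28} mean diff "
                    f"{r['mean_diff']:+.1f} +/- {r['sd_diff']:.1f} mL/m^2"
                )
            else:
                lines.append(
                    f"  {r['comparison']:<28} CCC {r['ccc']:.2f}"
                )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig, out_dir: Path) -> dict:
    """Run the full study and write the report bundle to ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    logger.info("stage simulate: sampling cohort")
    cohort_cfg = dataclasses.replace(config.cohort, seed=seeds["cohort"])
    patients = sample_cohort(cohort_cfg)
    lio.write_cohort(patients, out / "cohort.csv")

    curves = [build_curve(p) for p in patients]
    lio.write_curves(curves, out / "curves.csv")

    logger.info("stage simulate: projecting biplane measurements")
    noise_rng = np.random.default_rng(seeds["observer_noise"])
    all_frames = []
    measured_curves: dict[str, TimeVolumeCurve] = {}
    for p, c in zip(patients, curves):
        frames = project_biplane(
            c, bsa=p.bsa, noise_sd_rel=cohort_cfg.noise_sd_rel,
            observer_id="obs1", seed=noise_rng,
        )
        all_frames.extend(frames)
        vols = volumes_from_biplane(
            [f.a1 for f in frames], [f.a2 for f in frames],
            [f.length_l for f in frames], p.bsa,
        )
        measured_curves[p.patient_id] = TimeVolumeCurve(
            patient_id=p.patient_id, times=c.times, volumes=vols,
            rr_interval=c.rr_interval, event_frames=c.event_frames,
        )
    lio.write_biplane(all_frames, out / "biplane.csv")

    logger.info("stage quantify: extracting phasic volumes")
    records = []
    noisy = cohort_cfg.noise_sd_rel > 0
    for p in patients:
        pvs = quantify_patient(
            measured_curves[p.patient_id], p.event_frames, config.method,
            config.smooth_window, config.flat_tol, noisy,
        )
        records.extend(phasic_records(pvs))
    phasic = _phasic_table(records)
    lio.write_table(phasic, out / "phasic.csv")

    logger.info("stage evaluate: diagnostics vs dichotomized LVEDP")
    cohort_df = pd.read_csv(out / "cohort.csv")
    eval_method = SINGLE_PHASE if config.method in ("single", "both") else MULTI_PHASE
    table2, table3, counts = evaluate_tables(
        phasic, cohort_df, threshold=config.lvedp_threshold,
        method=eval_method, welch=config.welch,
    )
    lio.write_table(table2, out / "table2.csv")
    lio.write_table(table3, out / "table3.csv")

    logger.info("stage agree: method comparison and observer variability")
    agree_rows = []
    if config.method == "both":
        sp = phasic[(phasic["method"] == SINGLE_PHASE) & (phasic["flags"].fillna("") == "")]
        mp = phasic[(phasic["method"] == MULTI_PHASE) & (phasic["flags"].fillna("") == "")]
        paired = sp.merge(mp, on="patient_id", suffixes=("_sp", "_mp"))
        for name, col, _ in VOLUME_INDICES:
            res = bland_altman(
                paired[f"{col}_sp"], paired[f"{col}_mp"],
                comparison_name=f"single_vs_multi:{name}",
            )
            agree_rows.append(
                {
                    "comparison": res.comparison_name,
                    "mean_diff": res.mean_diff, "sd_diff": res.sd_diff,
                    "loa_low": res.loa_low, "loa_high": res.loa_high,
                    "ccc": np.nan, "n": res.n_pairs,
                }
            )
    ccc = replicate_study(
        patients, n_replicates=config.n_replicates,
        noise_sd_rel=cohort_cfg.noise_sd_rel, seed=seeds["replicates"],
        n_cases=config.replicate_cases, smooth_window=config.smooth_window,
    )
    for (method, idx), res in sorted(ccc.items()):
        agree_rows.append(
            {
                "comparison": f"replicates:{method}:{idx}",
                "mean_diff": np.nan, "sd_diff": np.nan,
                "loa_low": np.nan, "loa_high": np.nan,
                "ccc": res.ccc, "n": res.n_pairs,
            }
        )
    agreement = pd.DataFrame(
        agree_rows,
        columns=["comparison", "mean_diff", "sd_diff", "loa_low",
                 "loa_high", "ccc", "n"],
    )
    lio.write_table(agreement, out / "agreement.csv")

    write_summary(out / "summary.txt", table2, table3, agreement, counts)
    logger.info("pipeline complete: outputs in %s", out)
    return {
        "patients": patients,
        "table2": table2,
        "table3": table3,
        "agreement": agreement,
        "counts": counts,
    }
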