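"""Method-comparison and observer-variability statistics.

Bland-Altman differences use the convention first-argument minus
second-argument (single-phase minus multi-phase in the pipeline), reported
as mean +/- SD of differences with conventional 1.96-SD limits of
agreement. Concordance is Lin's coefficient with population (n) moment
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from laphase.curves import TimeVolumeCurve
from laphase.errors import DomainError
from laphase.phase_extraction import extract_multi_phase, extract_single_phase
from laphase.synthetic import GroundTruthPatient, build_curve, project_biplane
from laphase.volumetry import MULTI_PHASE, SINGLE_PHASE, volumes_from_biplane

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementResult:
    comparison_name: str
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int


@dataclass(frozen=True)
class ConcordanceResult:
    comparison_name: str
    ccc: float
    n_pairs: int


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("paired vectors must be equal-length and 1-D")
    return x, y


def bland_altman(x, y, comparison_name: str = "") -> AgreementResult:
    """Mean and SD of paired differences d = x - y with 1.96-SD limits."""
    x, y = _paired(x, y)
    if len(x) < 2:
        raise DomainError("Bland-Altman needs n >= 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        comparison_name=comparison_name,
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - LOA_MULTIPLIER * sd,
        loa_high=mean + LOA_MULTIPLIER * sd,
        n_pairs=len(x),
    )


def lin_ccc(x, y, comparison_name: str = "") -> ConcordanceResult:
    """Lin's concordance correlation coefficient.

    2*cov(x,y) / (var x + var y + (mean x - mean y)^2), with population (n)
    variance normalization as in Lin's original definition.
    """
    x, y = _paired(x, y)
    if len(x) < 3:
        raise DomainError("CCC needs n >= 3 pairs")
    vx, vy = float(np.var(x)), float(np.var(y))
    if vx == 0.0 or vy == 0.0:
        raise DomainError("CCC undefined for zero-variance input")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    ccc = 2.0 * sxy / (vx + vy + (float(x.mean()) - float(y.mean())) ** 2)
    return ConcordanceResult(
        comparison_name=comparison_name, ccc=ccc, n_pairs=len(x)
    )


_INDEX_ATTRS = {"lav_min": "lav_min", "lav_ac": "lav_ac", "lav_max": "lav_max"}


def replicate_study(
    cohort: list[GroundTruthPatient],
    n_replicates: int = 2,
    noise_sd_rel: float = 0.03,
    seed: int = 0,
    n_cases: int = 5,
    smooth_window: int = 3,
) -> dict[tuple[str, str], ConcordanceResult]:
    """Observer-variability study on randomly selected cases.

    Draws ``n_cases`` patients, regenerates ``n_replicates`` independent
    observer measurement replicates of each via biplane projection with
    multiplicative noise, quantifies every replicate with both extraction
    methods, and returns Lin's CCC per (method, volume index) computed
    between replicate pairs. Deterministic under ``seed``.
    """
    if n_replicates < 2:
        raise DomainError("replicate study needs n_replicates >= 2")
    if len(cohort) < 3:
        raise DomainError("replicate study needs at least 3 cases")
    rng = np.random.default_rng(seed)
    n_cases = min(n_cases, len(cohort))
    chosen = rng.choice(len(cohort), size=n_cases, replace=False)

    # values[method][index][replicate] -> list over cases
    values: dict[str, dict[str, list[list[float]]]] = {
        m: {idx: [[] for _ in range(n_replicates)] for idx in _INDEX_ATTRS}
        for m in (SINGLE_PHASE, MULTI_PHASE)
    }
    for ci in chosen:
        patient = cohort[int(ci)]
        truth_curve = build_curve(patient)
        for rep in range(n_replicates):
            frames = project_biplane(
                truth_curve,
                bsa=patient.bsa,
                noise_sd_rel=noise_sd_rel,
                observer_id=f"obs{rep + 1}",
                seed=rng,
            )
            vols = volumes_from_biplane(
                [f.a1 for f in frames],
                [f.a2 for f in frames],
                [f.length_l for f in frames],
                patient.bsa,
            )
            measured = TimeVolumeCurve(
                patient_id=patient.patient_id,
                times=truth_curve.times,
                volumes=vols,
                rr_interval=truth_curve.rr_interval,
                event_frames=truth_curve.event_frames,
            )
            window = smooth_window if noise_sd_rel > 0 else 1
            sp = extract_single_phase(measured, truth_curve.event_frames)
            mp = extract_multi_phase(measured, smooth_window=window)
            for pv in (sp, mp):
                for idx, attr in _INDEX_ATTRS.items():
                    values[pv.method][idx][rep].append(getattr(pv, attr))

    out: dict[tuple[str, str], ConcordanceResult] = {}
    for method, per_index in values.items():
        for idx, reps in per_index.items():
            cccs = [
                lin_ccc(reps[a], reps[b]).ccc
                for a in range(n_replicates)
                for b in range(a + 1, n_replicates)
            ]
            out[(method, idx)] = ConcordanceResult(
                comparison_name=f"{method}:{idx}",
                ccc=float(np.mean(cccs)),
                n_pairs=n_cases,
            )
    return out
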