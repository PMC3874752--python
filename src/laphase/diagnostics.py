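"""Diagnostic evaluation of LA indices against elevated filling pressure.

Dichotomizes LVEDP at 12 mmHg (elevated strictly above), compares groups
with Student's t (pooled variance by default, Welch by flag), correlates
indices with LVEDP (Pearson), and runs per-index empirical ROC analysis:
Mann-Whitney AUC with half-weight ties, DeLong variance for the two-sided
test against 0.5, and a Youden-optimal operating cutoff.

Directionality: volumes discriminate upward (elevated group larger, rule
"value >= cutoff"), emptying fractions downward (rule "value <= cutoff").
No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from laphase.errors import DomainError

LVEDP_THRESHOLD = 12.0

GREATER = "greater"  # positive class scores high; rule "score >= cutoff"
LESS = "less"        # positive class scores low; rule "score <= cutoff"


def dichotomize_lvedp(
    lvedp: float, threshold: float = LVEDP_THRESHOLD
) -> str:
    """Label a pressure: 'elevated' iff strictly above threshold."""
    if lvedp <= 0 or not np.isfinite(lvedp):
        raise DomainError(f"LVEDP must be positive and finite, got {lvedp}")
    return "elevated" if lvedp > threshold else "normal"


@dataclass(frozen=True)
class DiagnosticReport:
    index_name: str
    auc: float
    auc_p: float
    cutoff: float | None
    direction: str
    sensitivity: float | None
    specificity: float | None
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class GroupComparison:
    index_name: str
    mean_elevated: float
    sd_elevated: float
    n_elevated: int
    mean_normal: float
    sd_normal: float
    n_normal: int
    p_value: float


def _split(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DomainError("scores and labels must be equal-length 1-D arrays")
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise DomainError("need at least one patient in each class")
    return pos, neg


def _oriented(scores: np.ndarray, direction: str) -> np.ndarray:
    if direction == GREATER:
        return np.asarray(scores, dtype=float)
    if direction == LESS:
        return -np.asarray(scores, dtype=float)
    raise DomainError(f"direction must be '{GREATER}' or '{LESS}'")


def _placement_values(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components: per-case placement probabilities."""
    v10 = np.empty(len(pos))
    for i, x in enumerate(pos):
        v10[i] = (np.sum(x > neg) + 0.5 * np.sum(x == neg)) / len(neg)
    v01 = np.empty(len(neg))
    for j, y in enumerate(neg):
        v01[j] = (np.sum(pos > y) + 0.5 * np.sum(pos == y)) / len(pos)
    return v10, v01


def empirical_auc(
    scores, labels, direction: str = GREATER
) -> tuple[float, float]:
    """Empirical (Mann-Whitney) AUC and a two-sided DeLong p versus 0.5.

    Ties count one half. ``direction`` orients scores so that AUC > 0.5
    means the index discriminates toward the positive (elevated) class.
    """
    pos, neg = _split(_oriented(np.asarray(scores), direction),
                      np.asarray(labels))
    v10, v01 = _placement_values(pos, neg)
    auc = float(v10.mean())
    var = 0.0
    if len(pos) > 1:
        var += float(np.var(v10, ddof=1)) / len(pos)
    if len(neg) > 1:
        var += float(np.var(v01, ddof=1)) / len(neg)
    if var <= 0.0:
        p = 1.0 if auc == 0.5 else 0.0
    else:
        z = (auc - 0.5) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return auc, p


def optimal_cutoff(
    scores, labels, direction: str = GREATER
) -> tuple[float | None, float | None, float | None]:
    """Youden-optimal cutoff with its sensitivity and specificity.

    Candidate thresholds are midpoints between consecutive distinct observed
    values. Rule semantics follow ``direction``: positive call is
    "score >= cutoff" for volumes, "score <= cutoff" for fractions. Ties in
    Youden's J break toward higher specificity, then toward the more
    conservative (extreme) cutoff. Returns (None, None, None) when no
    threshold beats J = 0 (degenerate, non-discriminating input).
    """
    raw = np.asarray(scores, dtype=float)
    oriented = _oriented(raw, direction)
    pos, neg = _split(oriented, np.asarray(labels))

    distinct = np.unique(oriented)
    if len(distinct) < 2:
        return None, None, None
    candidates = (distinct[:-1] + distinct[1:]) / 2.0

    best = None  # (j, spec, cand, sens)
    for c in candidates:
        sens = float(np.mean(pos >= c))
        spec = float(np.mean(neg < c))
        j = sens + spec - 1.0
        key = (j, spec, c)
        if best is None or key > (best[0], best[1], best[2]):
            best = (j, spec, c, sens)
    j, spec, c, sens = best
    if j <= 0.0:
        return None, None, None
    cutoff = float(c) if direction == GREATER else float(-c)
    return cutoff, sens, spec


def group_compare(
    values, labels, index_name: str = "", welch: bool = False
) -> GroupComparison:
    """Per-group mean +/- SD and a two-sided Student's t-test p-value.

    Pooled-variance t by default; set ``welch=True`` for unequal variances.
    """
    elev, norm = _split(np.asarray(values), np.asarray(labels))
    if len(elev) < 2 or len(norm) < 2:
        raise DomainError("each group needs n >= 2 for a defined SD")
    t, p = stats.ttest_ind(elev, norm, equal_var=not welch)
    return GroupComparison(
        index_name=index_name,
        mean_elevated=float(elev.mean()),
        sd_elevated=float(elev.std(ddof=1)),
        n_elevated=len(elev),
        mean_normal=float(norm.mean()),
        sd_normal=float(norm.std(ddof=1)),
        n_normal=len(norm),
        p_value=float(p),
    )


def pearson_r(values, lvedp) -> tuple[float, float]:
    """Product-moment correlation and two-sided p via the t-transform."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(lvedp, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise DomainError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise DomainError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise DomainError("table must hold nonnegative integer counts")
        t = t.astype(int)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


def evaluate_index(
    index_name: str, values, labels, direction: str
) -> DiagnosticReport:
    """Full ROC report (AUC, p, Youden cutoff, sens/spec) for one index."""
    labels = np.asarray(labels, dtype=bool)
    auc, p = empirical_auc(values, labels, direction)
    cutoff, sens, spec = optimal_cutoff(values, labels, direction)
    return DiagnosticReport(
        index_name=index_name,
        auc=auc,
        auc_p=p,
        cutoff=cutoff,
        direction=direction,
        sensitivity=sens,
        specificity=spec,
        n_pos=int(labels.sum()),
        n_neg=int((~labels).sum()),
    )
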