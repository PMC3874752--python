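"""Phasic volume extraction from cine time-volume data.

Two routes are implemented and compared:

* single-phase — read the curve at externally supplied valve-event frames
  (in practice these come from visual cine review);
* multi-phase — locate the landmarks on the time-volume curve itself, with
  no knowledge of the ground-truth event frames.

Multi-phase search windows (fractions of the RR interval, cyclic from the
R-wave trigger): lav_max is the maximum over ventricular systole (first
50%); lav_min the minimum over the end-diastolic window (last 15% plus frame
0); lav_ac the last local maximum at or before the steepest late-diastolic
fall. Ties break toward the earliest frame for determinism.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from laphase.curves import EventFrames, TimeVolumeCurve
from laphase.errors import DomainError
from laphase.volumetry import MULTI_PHASE, SINGLE_PHASE, PhasicVolumes

logger = logging.getLogger(__name__)

#: Curves whose total range is below this fraction of the mean volume are
#: considered flat: phase identification is unreliable when LA volume change
#: is limited, so such records are flagged rather than quantified.
FLATNESS_TOL = 0.05

FLAG_ORDERING = "ordering_violation"
FLAG_FLAT = "flat_curve"
FLAG_NO_KICK = "no_atrial_kick"

MIN_FRAMES = 20


def extract_single_phase(
    curve: TimeVolumeCurve, events: EventFrames
) -> PhasicVolumes:
    """Read (lav_max, lav_ac, lav_min) at the valve-event frames.

    A triple violating lav_min <= lav_ac <= lav_max (possible under heavy
    measurement noise) is returned flagged for exclusion, with a warning.
    """
    n = curve.n_frames
    # events are indexed relative to the R-wave trigger
    shifted = events.shifted(-curve.trigger_frame, n) if curve.trigger_frame else events
    shifted.validate(n)
    v = curve.unrolled_volumes()
    lav_max = float(v[shifted.mv_open])
    lav_ac = float(v[shifted.ac_onset])
    lav_min = float(v[shifted.mv_close])
    flags: frozenset[str] = frozenset()
    if not lav_min <= lav_ac <= lav_max:
        flags = frozenset({FLAG_ORDERING})
        logger.warning(
            "%s: single-phase triple (%.2f, %.2f, %.2f) violates ordering; "
            "record flagged",
            curve.patient_id, lav_min, lav_ac, lav_max,
        )
    return PhasicVolumes(
        patient_id=curve.patient_id,
        lav_max=lav_max,
        lav_ac=lav_ac,
        lav_min=lav_min,
        method=SINGLE_PHASE,
        flags=flags,
    )


def _smooth(v: np.ndarray, window: int) -> np.ndarray:
    """Centered cyclic moving average; window must be odd, 1 = no-op."""
    if window <= 1:
        return v
    if window % 2 == 0:
        raise DomainError(f"smoothing window must be odd, got {window}")
    half = window // 2
    padded = np.concatenate([v[-half:], v, v[:half]])
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def _is_local_max(v: np.ndarray, i: int) -> bool:
    return 0 < i < len(v) - 1 and v[i] >= v[i - 1] and v[i] >= v[i + 1]


def _steepest_fall_frame(v: np.ndarray) -> int | None:
    """Frame of steepest negative slope within the final diastolic third."""
    n = len(v)
    start = math.ceil(2 * n / 3)
    slopes = np.diff(v[start:])
    if slopes.size == 0 or slopes.min() >= 0:
        return None
    return start + int(np.argmin(slopes))


def _ac_frame(v: np.ndarray, raw: np.ndarray, half: int = 0) -> int | None:
    """Atrial-contraction onset: volume peak preceding the late fall.

    Primary: last local maximum at or before the steepest negative slope in
    the final third. Fallback when late diastole has no negative slope: last
    local maximum strictly between the global maximum and the global
    minimum. None when no atrial kick is detectable. A candidate found on a
    smoothed curve is refined to the raw argmax within the smoothing
    half-width, so smoothing cannot displace the landmark on clean data.
    """
    n = len(v)
    cand = None
    steepest = _steepest_fall_frame(v)
    if steepest is not None:
        start = math.ceil(2 * n / 3)
        for i in range(steepest, start - 1, -1):
            if _is_local_max(v, i):
                cand = i
                break
    if cand is None:
        # fallback: a mid/late-diastolic bump between the global extrema
        g_max = int(np.argmax(v))
        g_min = g_max + int(np.argmin(v[g_max:])) if g_max < n - 1 else g_max
        for i in range(g_min - 1, g_max, -1):
            if _is_local_max(v, i):
                cand = i
                break
    if cand is None or half == 0:
        return cand
    lo = max(cand - half, 0)
    hi = min(cand + half + 1, n)
    return lo + int(np.argmax(raw[lo:hi]))


def detect_ac_onset(
    curve: TimeVolumeCurve,
    smooth_window: int = 1,
    flat_tol: float = FLATNESS_TOL,
) -> int:
    """Locate the atrial-contraction-onset frame on the curve alone.

    Returns the index relative to the curve's stored frame order. Raises
    ``DomainError`` for flat curves or curves with no detectable atrial kick.
    """
    v = curve.unrolled_volumes()
    if _is_flat(v, flat_tol):
        raise DomainError(f"{curve.patient_id}: curve is flat")
    frame = _ac_frame(_smooth(v, smooth_window), v, half=smooth_window // 2)
    if frame is None:
        raise DomainError(f"{curve.patient_id}: no atrial kick detectable")
    return (frame + curve.trigger_frame) % curve.n_frames


def _is_flat(v: np.ndarray, tol: float = FLATNESS_TOL) -> bool:
    return float(v.max() - v.min()) < tol * float(v.mean())


def extract_multi_phase(
    curve: TimeVolumeCurve,
    smooth_window: int = 1,
    flat_tol: float = FLATNESS_TOL,
) -> PhasicVolumes:
    """Extract the phasic triple from curve landmarks alone.

    Smoothing (odd window, cyclic moving average) is applied only for
    landmark localization; reported values are read from the raw curve.
    A flat curve yields the degenerate triple (V, V, V) with a flatness
    flag; an undetectable atrial kick collapses lav_ac onto lav_min with a
    no-kick flag.
    """
    if curve.n_frames < MIN_FRAMES:
        raise DomainError(
            f"{curve.patient_id}: need >= {MIN_FRAMES} frames, "
            f"got {curve.n_frames}"
        )
    v = curve.unrolled_volumes()
    n = len(v)
    if _is_flat(v, flat_tol):
        mean = float(v.mean())
        return PhasicVolumes(
            patient_id=curve.patient_id,
            lav_max=mean, lav_ac=mean, lav_min=mean,
            method=MULTI_PHASE,
            flags=frozenset({FLAG_FLAT}),
        )
    vs = _smooth(v, smooth_window)
    flags: set[str] = set()

    # lav_max: maximum during ventricular systole (first half of RR)
    sys_end = n // 2 + 1
    max_frame = int(np.argmax(vs[:sys_end]))

    # lav_min: minimum over the end-diastolic window (last 15% + frame 0)
    ed_start = math.ceil(0.85 * n)
    ed_idx = np.concatenate([[0], np.arange(ed_start, n)])
    min_frame = int(ed_idx[np.argmin(vs[ed_idx])])

    # landmark frames come from the (possibly smoothed) curve; values are
    # read from the raw curve at those frames, which keeps noisy extraction
    # close to bias-free (no selection over raw noise maxima)
    ac_frame = _ac_frame(vs, v, half=0)
    if ac_frame is None:
        flags.add(FLAG_NO_KICK)
        ac_frame = min_frame

    lav_max = float(v[max_frame])
    lav_min = float(v[min_frame])
    lav_ac = float(v[ac_frame])
    if not lav_min <= lav_ac <= lav_max:
        flags.add(FLAG_ORDERING)
        logger.warning(
            "%s: multi-phase triple (%.2f, %.2f, %.2f) violates ordering; "
            "record flagged",
            curve.patient_id, lav_min, lav_ac, lav_max,
        )
    return PhasicVolumes(
        patient_id=curve.patient_id,
        lav_max=lav_max,
        lav_ac=lav_ac,
        lav_min=lav_min,
        method=MULTI_PHASE,
        flags=frozenset(flags),
    )
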