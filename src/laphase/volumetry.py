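"""Biplane area-length LA volumetry and emptying-fraction indices.

The chamber volume estimate is 0.85 * A1 * A2 / L, with A1 and A2 the
planimetered LA areas in the 2- and 4-chamber long-axis views (cm^2) and L
the LA length perpendicular to the mitral annulus center in the 4-chamber
view (cm). Emptying fractions are ratios of a phasic volume triple and are
identical whether computed on absolute or BSA-indexed volumes (BSA cancels),
so they are computed on indexed values throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from laphase.errors import DomainError, OrderingError

#: Indexed volumes below this floor (mL/m^2) are treated as implausible.
MIN_PLAUSIBLE_VOLUME = 1.0

SINGLE_PHASE = "single_phase"
MULTI_PHASE = "multi_phase"


def biplane_volume(a1: float, a2: float, length_l: float) -> float:
    """Absolute LA volume (mL) from biplane areas (cm^2) and length (cm)."""
    if a1 <= 0 or a2 <= 0 or length_l <= 0:
        raise DomainError(
            f"biplane inputs must be positive: a1={a1}, a2={a2}, L={length_l}"
        )
    return 0.85 * a1 * a2 / length_l


def index_volume(volume_ml: float, bsa: float) -> float:
    """Normalize an absolute volume (mL) to body surface area (m^2)."""
    if bsa <= 0:
        raise DomainError(f"BSA must be positive, got {bsa}")
    return volume_ml / bsa


@dataclass(frozen=True)
class PhasicVolumes:
    """The (LAV_max, LAV_ac, LAV_min) triple for one patient, in mL/m^2.

    ``method`` tags how the triple was obtained (single_phase/multi_phase).
    ``flags`` carries QC markers (e.g. ``ordering_violation``, ``flat_curve``,
    ``no_atrial_kick``); flagged records are excluded from downstream stats.
    """

    patient_id: str
    lav_max: float
    lav_ac: float
    lav_min: float
    method: str
    flags: frozenset[str] = frozenset()

    @property
    def ordering_valid(self) -> bool:
        return self.lav_min <= self.lav_ac <= self.lav_max

    @property
    def usable(self) -> bool:
        return not self.flags and self.ordering_valid

    def validate(self) -> None:
        if min(self.lav_min, self.lav_ac, self.lav_max) < MIN_PLAUSIBLE_VOLUME:
            raise DomainError(
                f"{self.patient_id}: implausible volume below "
                f"{MIN_PLAUSIBLE_VOLUME} mL/m^2 in "
                f"({self.lav_min}, {self.lav_ac}, {self.lav_max})"
            )
        if self.lav_min > self.lav_ac:
            raise OrderingError(
                f"{self.patient_id}: lav_min={self.lav_min} > "
                f"lav_ac={self.lav_ac}"
            )
        if self.lav_ac > self.lav_max:
            raise OrderingError(
                f"{self.patient_id}: lav_ac={self.lav_ac} > "
                f"lav_max={self.lav_max}"
            )


@dataclass(frozen=True)
class EmptyingFractions:
    """Total/passive/contractile LA emptying fractions, stored in [0, 1).

    Rendered as percentages only in reports, never internally.
    """

    patient_id: str
    laef_total: float
    laef_passive: float
    laef_contractile: float


def emptying_fractions(pv: PhasicVolumes) -> EmptyingFractions:
    """Compute (max-min)/max, (max-ac)/max and (ac-min)/max.

    The additivity identity passive + contractile == total holds to floating
    rounding because all three share the same denominator.
    """
    pv.validate()
    return EmptyingFractions(
        patient_id=pv.patient_id,
        laef_total=(pv.lav_max - pv.lav_min) / pv.lav_max,
        laef_passive=(pv.lav_max - pv.lav_ac) / pv.lav_max,
        laef_contractile=(pv.lav_ac - pv.lav_min) / pv.lav_max,
    )


def volumes_from_biplane(
    a1: np.ndarray, a2: np.ndarray, length_l: np.ndarray, bsa: float
) -> np.ndarray:
    """Vectorized biplane volume per frame, indexed to BSA (mL/m^2)."""
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    length_l = np.asarray(length_l, dtype=float)
    if np.any(a1 <= 0) or np.any(a2 <= 0) or np.any(length_l <= 0):
        raise DomainError("biplane measurements must all be positive")
    if bsa <= 0:
        raise DomainError(f"BSA must be positive, got {bsa}")
    return 0.85 * a1 * a2 / length_l / bsa
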