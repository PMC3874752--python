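"""Core cine-curve domain types.

Frame convention: 0-based, frame 0 at the R-wave trigger (LV end diastole),
times in milliseconds from the trigger. Curves are cyclic over one RR
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from laphase.errors import DomainError


@dataclass(frozen=True)
class EventFrames:
    """Valve-event frame indices used by single-phase quantitation.

    ``mv_open``: frame just before mitral valve opening (LA maximal);
    ``ac_onset``: frame immediately prior to atrial contraction;
    ``mv_close``: frame at mitral valve closure (LA minimal).
    """

    mv_open: int
    ac_onset: int
    mv_close: int

    def validate(self, n_frames: int) -> None:
        idx = (self.mv_open, self.ac_onset, self.mv_close)
        if not all(0 <= i < n_frames for i in idx):
            raise DomainError(
                f"event frames {idx} outside [0, {n_frames})"
            )
        if not (self.mv_open < self.ac_onset < self.mv_close):
            raise DomainError(
                f"event frames must be in cyclic order from frame 0: "
                f"mv_open={self.mv_open} < ac_onset={self.ac_onset} "
                f"< mv_close={self.mv_close} fails"
            )

    def shifted(self, k: int, n_frames: int) -> "EventFrames":
        """Re-index events after rotating the frame origin by ``k``."""
        return EventFrames(
            (self.mv_open + k) % n_frames,
            (self.ac_onset + k) % n_frames,
            (self.mv_close + k) % n_frames,
        )


@dataclass(frozen=True)
class TimeVolumeCurve:
    """Frame-sampled LA volume (mL/m^2) over one cardiac cycle.

    ``trigger_frame`` records where the R-wave trigger sits after any
    rotation of the frame origin; it is 0 for freshly generated curves.
    """

    patient_id: str
    times: np.ndarray
    volumes: np.ndarray
    rr_interval: float
    event_frames: EventFrames | None = None
    trigger_frame: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        volumes = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "volumes", volumes)
        if times.shape != volumes.shape or times.ndim != 1:
            raise DomainError("times and volumes must be equal-length 1-D arrays")
        if len(times) < 3:
            raise DomainError("curve needs at least 3 frames")
        if np.any(np.diff(times) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(volumes <= 0):
            raise DomainError("all volumes must be positive")
        if self.rr_interval <= times[-1]:
            raise DomainError("rr_interval must exceed the last sample time")

    @property
    def n_frames(self) -> int:
        return len(self.volumes)

    def rotated(self, k: int) -> "TimeVolumeCurve":
        """Rotate the frame origin so old frame ``-k`` becomes frame 0.

        Volumes are rolled by ``k``; event frames are re-indexed and
        ``trigger_frame`` tracks the displaced R-wave so extraction can
        unroll the cycle. Times keep the uniform sampling grid.
        """
        n = self.n_frames
        k = k % n
        events = (
            self.event_frames.shifted(k, n) if self.event_frames else None
        )
        return replace(
            self,
            volumes=np.roll(self.volumes, k),
            event_frames=events,
            trigger_frame=(self.trigger_frame + k) % n,
        )

    def unrolled_volumes(self) -> np.ndarray:
        """Volumes re-anchored so index 0 is the R-wave trigger."""
        return np.roll(self.volumes, -self.trigger_frame)
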