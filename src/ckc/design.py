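"""Stimulus designs for proprioceptive multi-finger stimulation.

A :class:`StimulusDesign` describes when and how fast each finger (D2-D5:
index, middle, ring, little) is moved by the pneumatic actuator.  Three
condition layouts are supported:

* ``simultaneous_constant`` — all fingers driven together at one frequency
  (default 3 Hz) in repeated bursts;
* ``separate`` — a single finger driven at a time (one design per finger);
* ``simultaneous_varied`` — all fingers driven continuously, each at its own
  frequency (defaults 2, 2.5, 3, 3.5 Hz for D2-D5).

The stimulation frequency is also the frequency at which coherence is read
out downstream, so designs can be validated against the spectral resolution
implied by the epoch length (0.25 Hz for 4000 ms epochs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence, Tuple

FINGERS: Tuple[str, ...] = ("D2", "D3", "D4", "D5")

#: Finger-specific drive frequencies (Hz) in the varied-frequency condition.
VARIED_FREQS: Mapping[str, float] = {"D2": 2.0, "D3": 2.5, "D4": 3.0, "D5": 3.5}


class Condition(str, Enum):
    SIMULTANEOUS_CONSTANT = "simultaneous_constant"
    SEPARATE = "separate"
    SIMULTANEOUS_VARIED = "simultaneous_varied"


class DesignError(ValueError):
    """Raised when a stimulus design violates its invariants."""


@dataclass(frozen=True)
class StimulusDesign:
    """Condition, per-finger drive frequencies and burst schedule.

    Parameters
    ----------
    condition
        One of the three condition layouts.
    fingers
        Ordered ids of the fingers that are actively driven.
    freq_per_finger
        Drive frequency in Hz for each active finger.
    burst_schedule
        ``(start_s, duration_s)`` active windows.  Stimulation (and epoch
        eligibility downstream) is restricted to these windows.
    total_duration
        Recording length in seconds.
    sample_rate
        Sampling rate in Hz (1 kHz by default, as for a whole-scalp MEG
        system with time-locked accelerometers).
    """

    condition: Condition
    fingers: Tuple[str, ...]
    freq_per_finger: Mapping[str, float]
    burst_schedule: Tuple[Tuple[float, float], ...]
    total_duration: float
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        if not self.fingers:
            raise DesignError("design has no active fingers")
        for f in self.fingers:
            if f not in self.freq_per_finger:
                raise DesignError(f"no frequency given for finger {f}")
            if self.freq_per_finger[f] <= 0:
                raise DesignError(f"non-positive frequency for finger {f}")
        freqs = [self.freq_per_finger[f] for f in self.fingers]
        cond = Condition(self.condition)
        if cond is Condition.SIMULTANEOUS_CONSTANT and len(set(freqs)) != 1:
            raise DesignError("simultaneous_constant requires equal frequencies")
        if cond is Condition.SIMULTANEOUS_VARIED and len(set(freqs)) != len(freqs):
            raise DesignError("simultaneous_varied requires pairwise distinct frequencies")
        if self.total_duration <= 0 or self.sample_rate <= 0:
            raise DesignError("total_duration and sample_rate must be positive")
        prev_end = -float("inf")
        for start, dur in self.burst_schedule:
            if dur <= 0 or start < 0:
                raise DesignError(f"invalid burst ({start}, {dur})")
            if start < prev_end:
                raise DesignError("bursts overlap")
            if start + dur > self.total_duration + 1e-9:
                raise DesignError("burst extends beyond total_duration")
            prev_end = start + dur

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sample_rate))

    def active_freqs(self) -> Mapping[str, float]:
        return {f: self.freq_per_finger[f] for f in self.fingers}


def assert_freqs_on_bins(design: StimulusDesign, epoch_length_ms: float = 4000.0,
                         tol: float = 1e-9) -> None:
    """Check every drive frequency lies on a spectral bin center.

    The coherence stage uses a bare DFT of ``epoch_length_ms`` epochs, giving
    a bin width of ``1000 / epoch_length_ms`` Hz (0.25 Hz at 4000 ms).  Drive
    frequencies off that grid cannot be read out exactly.
    """
    resolution = 1000.0 / epoch_length_ms
    for f, freq in design.active_freqs().items():
        ratio = freq / resolution
        if abs(ratio - round(ratio)) > tol:
            raise DesignError(
                f"finger {f}: {freq} Hz is not a multiple of the "
                f"{resolution} Hz spectral resolution"
            )


def _bursts(n: int = 3, burst_s: float = 60.0, gap_s: float = 5.0):
    return tuple((i * (burst_s + gap_s), burst_s) for i in range(n))


def simultaneous_constant_design(freq: float = 3.0, n_bursts: int = 3,
                                 burst_s: float = 60.0, gap_s: float = 5.0,
                                 sample_rate: float = 1000.0) -> StimulusDesign:
    """All four fingers together at one frequency, in bursts (default 3x60 s)."""
    sched = _bursts(n_bursts, burst_s, gap_s)
    total = sched[-1][0] + sched[-1][1]
    return StimulusDesign(Condition.SIMULTANEOUS_CONSTANT, FINGERS,
                          {f: freq for f in FINGERS}, sched, total, sample_rate)


def separate_design(finger: str, freq: float = 3.0, n_bursts: int = 3,
                    burst_s: float = 60.0, gap_s: float = 5.0,
                    sample_rate: float = 1000.0) -> StimulusDesign:
    """A single finger at one frequency, in bursts (default 3x60 s)."""
    sched = _bursts(n_bursts, burst_s, gap_s)
    total = sched[-1][0] + sched[-1][1]
    return StimulusDesign(Condition.SEPARATE, (finger,), {finger: freq},
                          sched, total, sample_rate)


def simultaneous_varied_design(freqs: Mapping[str, float] | None = None,
                               duration_s: float = 240.0,
                               sample_rate: float = 1000.0) -> StimulusDesign:
    """All four fingers continuously, each at its own frequency (default 4 min)."""
    freqs = dict(VARIED_FREQS if freqs is None else freqs)
    return StimulusDesign(Condition.SIMULTANEOUS_VARIED, FINGERS, freqs,
                          ((0.0, duration_s),), duration_s, sample_rate)
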