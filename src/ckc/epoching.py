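"""Epoch extraction, artifact rejection and reference normalization.

Continuous MEG and the paired kinematic reference (the Euclidean-norm
acceleration magnitude, band-passed 0.5-195 Hz) are split into 4000 ms
epochs with a 5 ms overlap.  Epochs with any gradiometer exceeding
2000 fT/cm or any magnetometer exceeding 4000 fT peak-to-peak are excluded;
each surviving reference epoch is normalized to unit Euclidean norm.  The
resulting :class:`EpochSet` carries the accepted-epoch count K on which the
coherence estimate and its significance threshold depend.

The epoch grid restarts at each stimulation burst (data are acquired in
1-min runs), and an epoch must lie entirely within one burst.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .forward import GRAD, MAG, SensorArray
from .simulate import KinematicSignal, SensorRecording


class EpochingError(ValueError):
    pass


@dataclass(frozen=True)
class EpochSpec:
    """Epoching and rejection parameters.

    Defaults: 4000 ms epochs with 5 ms overlap; peak-to-peak rejection at
    2000 fT/cm (gradiometers) and 4000 fT (magnetometers), strict inequality
    (an epoch exactly at threshold is kept); acceleration band 0.5-195 Hz.
    """

    epoch_length_ms: float = 4000.0
    overlap_ms: float = 5.0
    grad_reject: float = 2000.0
    mag_reject: float = 4000.0
    acc_band: tuple = (0.5, 195.0)

    def __post_init__(self):
        if not 0 <= self.overlap_ms < self.epoch_length_ms:
            raise EpochingError("need 0 <= overlap < epoch_length")
        if self.grad_reject <= 0 or self.mag_reject <= 0:
            raise EpochingError("rejection thresholds must be positive")
        if not 0 < self.acc_band[0] < self.acc_band[1]:
            raise EpochingError("invalid acceleration band")

    @property
    def step_ms(self) -> float:
        return self.epoch_length_ms - self.overlap_ms


@dataclass(frozen=True)
class EpochSet:
    """Paired, onset-aligned MEG and reference epochs.

    ``meg`` (K, channels, samples); ``ref`` (K, samples); ``starts`` epoch
    start samples.  ``provenance`` records rejected indices and whether the
    reference epochs were unit-normalized.
    """

    meg: np.ndarray
    ref: np.ndarray
    starts: np.ndarray
    sample_rate: float
    array: SensorArray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.meg.shape[0] != self.ref.shape[0] or self.meg.shape[2] != self.ref.shape[1]:
            raise EpochingError("MEG and reference epochs are not aligned")

    @property
    def k(self) -> int:
        return self.meg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.meg.shape[2]


def bandpass_acceleration(axes: np.ndarray, low: float, high: float,
                          sample_rate: float, order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis; removes DC."""
    nyq = sample_rate / 2.0
    if not 0 < low < high < nyq:
        raise EpochingError(f"band ({low}, {high}) Hz outside (0, {nyq}) Hz")
    axes = np.asarray(axes, dtype=float)
    axes = axes - axes.mean(axis=-1, keepdims=True)
    sos = butter(order, [low, high], btype="band", fs=sample_rate, output="sos")
    return sosfiltfilt(sos, axes, axis=-1)


def euclidean_norm_magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Pointwise Euclidean norm of the three orthogonal accelerometer axes."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise EpochingError("axis length mismatch")
    return np.sqrt(x ** 2 + y ** 2 + z ** 2)


def reference_signal(kin: KinematicSignal, spec: EpochSpec) -> np.ndarray:
    """Band-passed acceleration magnitude used as the coherence reference."""
    filt = bandpass_acceleration(kin.axes, spec.acc_band[0], spec.acc_band[1],
                                 kin.sample_rate)
    return euclidean_norm_magnitude(filt[0], filt[1], filt[2])


def _epoch_starts(n_samples: int, epoch_len: int, step: int,
                  bursts_samples) -> np.ndarray:
    starts = []
    for s0, s1 in bursts_samples:
        s1 = min(s1, n_samples)
        t = s0
        while t + epoch_len <= s1:
            starts.append(t)
            t += step
    return np.asarray(starts, dtype=int)


def segment_epochs(recording: SensorRecording, reference: np.ndarray,
                   spec: EpochSpec,
                   bursts_s: Sequence[tuple] | None = None) -> EpochSet:
    """Cut identical epoch windows from the MEG array and the reference.

    Epochs start at multiples of ``epoch_length - overlap`` from each burst
    start and must lie entirely within one burst (``bursts_s`` in seconds;
    the whole recording counts as a single burst when omitted).
    """
    fs = recording.sample_rate
    n = recording.n_samples
    if len(reference) != n:
        raise EpochingError("reference length does not match the recording")
    epoch_len = int(round(spec.epoch_length_ms * fs / 1000.0))
    step = int(round(spec.step_ms * fs / 1000.0))
    if n < epoch_len:
        raise EpochingError("recording shorter than one epoch")
    if bursts_s is None:
        bursts = [(0, n)]
    else:
        bursts = [(int(round(a * fs)), int(round((a + d) * fs))) for a, d in bursts_s]
    starts = _epoch_starts(n, epoch_len, step, bursts)
    if len(starts) == 0:
        raise EpochingError("no epoch fits inside the stimulation bursts")
    meg = np.stack([recording.data[:, t:t + epoch_len] for t in starts])
    ref = np.stack([reference[t:t + epoch_len] for t in starts])
    return EpochSet(meg=meg, ref=ref, starts=starts, sample_rate=fs,
                    array=recording.array,
                    provenance={"k_original": len(starts), "rejected": [],
                                "normalized": False})


def peak_to_peak(epochs: np.ndarray) -> np.ndarray:
    """Per-epoch, per-channel peak-to-peak amplitude (K, channels)."""
    return epochs.max(axis=-1) - epochs.min(axis=-1)


def reject_epochs(epochs: EpochSet, spec: EpochSpec) -> EpochSet:
    """Drop epochs whose p2p amplitude exceeds the per-kind thresholds.

    Strictly greater-than: at-threshold epochs are kept.  Raises with
    per-channel diagnostics if nothing survives.
    """
    p2p = peak_to_peak(epochs.meg)
    kinds = np.asarray(epochs.array.kind)
    thr = np.where(kinds == GRAD, spec.grad_reject, spec.mag_reject)
    bad = np.any(p2p > thr[None, :], axis=1)
    if bad.all():
        worst = p2p.max(axis=0)
        top = np.argsort(worst)[::-1][:5]
        detail = ", ".join(f"{epochs.array.names[i]}: {worst[i]:.0f}" for i in top)
        raise EpochingError(f"all {epochs.k} epochs rejected; max p2p per "
                            f"channel (top 5): {detail}")
    keep = ~bad
    prov = dict(epochs.provenance)
    prov["rejected"] = sorted(set(prov.get("rejected", []))
                              | set(np.nonzero(bad)[0].tolist()))
    return replace(epochs, meg=epochs.meg[keep], ref=epochs.ref[keep],
                   starts=epochs.starts[keep], provenance=prov)


def normalize_ref_epochs(epochs: EpochSet) -> EpochSet:
    """Divide each reference epoch by its Euclidean norm (unit norm after)."""
    norms = np.linalg.norm(epochs.ref, axis=1)
    zero = np.nonzero(norms == 0)[0]
    if zero.size:
        raise EpochingError(f"zero-norm reference epoch(s): {zero.tolist()}")
    prov = dict(epochs.provenance)
    prov["normalized"] = True
    return replace(epochs, ref=epochs.ref / norms[:, None], provenance=prov)


def make_epochs(recording: SensorRecording, kin: KinematicSignal,
                spec: EpochSpec,
                bursts_s: Sequence[tuple] | None = None) -> EpochSet:
    """Full epoching chain: reference, segmentation, rejection, normalization."""
    ref = reference_signal(kin, spec)
    es = segment_epochs(recording, ref, spec, bursts_s)
    es = reject_epochs(es, spec)
    return normalize_ref_epochs(es)


def match_trial_counts(a: EpochSet, b: EpochSet,
                       seed: int | None = None,
                       mode: str = "earliest") -> tuple:
    """Truncate the larger epoch set to the smaller K.

    Used to cap the trial count of a longer condition at the count accepted
    in the shorter one.  ``mode='earliest'`` keeps the first epochs;
    ``mode='random'`` keeps a seeded random subset.
    """
    if a.k == 0 or b.k == 0:
        raise EpochingError("cannot match empty epoch sets")
    if mode not in ("earliest", "random"):
        raise EpochingError(f"unknown mode {mode!r}")
    k = min(a.k, b.k)

    def cut(es: EpochSet) -> EpochSet:
        if es.k == k:
            return es
        if mode == "earliest":
            idx = np.arange(k)
        else:
            rng = np.random.default_rng(seed)
            idx = np.sort(rng.choice(es.k, size=k, replace=False))
        prov = dict(es.provenance)
        prov["matched_from_k"] = es.k
        return replace(es, meg=es.meg[idx], ref=es.ref[idx],
                       starts=es.starts[idx], provenance=prov)

    return cut(a), cut(b)
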