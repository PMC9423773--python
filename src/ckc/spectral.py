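"""Epoch-averaged spectra, corticokinematic coherence, and its significance.

For K paired epochs with DFTs X_k(f) (MEG channel) and Y_k(f) (kinematic
reference),

    Pxx(f) = (1/K) sum_k X_k X_k*        Pyy(f) = (1/K) sum_k Y_k Y_k*
    Pxy(f) = (1/K) sum_k X_k Y_k*        Coh(f) = |Pxy|^2 / (Pxx Pyy)

computed with a bare rectangular-window DFT of the full epoch (bin width
1/epoch_length; 0.25 Hz at 4000 ms), so the stimulation frequencies
2/2.5/3/3.5 Hz fall exactly on bin centres.  Peak CKC is the maximum
coherence at the stimulation frequency over a designated channel set
(gradiometers by default).  The multiple-comparison-corrected significance
threshold is

    coh_thr = 1 - (alpha / (N_sens * N_f)) ** (1 / (N_trials/d - 1))

with alpha = 0.05, N_f = 1 (only the movement frequency is tested) and d an
effective-trial divisor (1 by default, i.e. no overlap correction; epochs
overlapping by 5 ms out of 4000 are essentially independent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .design import StimulusDesign
from .epoching import EpochSet, EpochingError
from .forward import GRAD, SensorArray
from .simulate import SensorRecording, StimulusTrain

logger = logging.getLogger(__name__)


class SpectralError(ValueError):
    pass


@dataclass(frozen=True)
class SpectralEstimate:
    """Epoch-averaged auto- and cross-spectra."""

    freqs: np.ndarray       # (bins,) Hz
    pxx: np.ndarray         # (channels, bins), real >= 0
    pyy: np.ndarray         # (bins,), real >= 0
    pxy: np.ndarray         # (channels, bins), complex
    k: int
    array: SensorArray

    @property
    def bin_width(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class CoherenceResult:
    """Coherence per channel per frequency bin, with peak bookkeeping."""

    coh: np.ndarray         # (channels, bins) in [0, 1]; NaN where undefined
    freqs: np.ndarray
    k: int
    array: SensorArray
    stim_freq: float | None = None
    peak_value: float | None = None
    peak_channel: int | None = None
    peak_pair: int | None = None
    peak_pair_value: float | None = None
    threshold: float | None = None

    @property
    def significant(self) -> bool | None:
        if self.peak_value is None or self.threshold is None:
            return None
        return bool(self.peak_value > self.threshold)


def epoch_spectra(epochs: EpochSet) -> SpectralEstimate:
    """Rectangular-window DFT spectra averaged over epochs (requires K >= 2)."""
    if epochs.k < 2:
        raise SpectralError("coherence is undefined for fewer than 2 epochs")
    x = np.fft.rfft(epochs.meg, axis=-1)          # (K, C, bins)
    y = np.fft.rfft(epochs.ref, axis=-1)          # (K, bins)
    freqs = np.fft.rfftfreq(epochs.n_samples, 1.0 / epochs.sample_rate)
    pxx = np.mean(np.abs(x) ** 2, axis=0)
    pyy = np.mean(np.abs(y) ** 2, axis=0)
    pxy = np.mean(x * np.conj(y)[:, None, :], axis=0)
    return SpectralEstimate(freqs=freqs, pxx=pxx, pyy=pyy, pxy=pxy,
                            k=epochs.k, array=epochs.array)


def coherence(spec: SpectralEstimate) -> CoherenceResult:
    """Magnitude-squared coherence |Pxy|^2 / (Pxx Pyy) per channel and bin.

    Bins where either auto-spectrum vanishes are flagged NaN (undefined),
    not zero.
    """
    denom = spec.pxx * spec.pyy[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(spec.pxy) ** 2 / denom
    coh = np.where(denom > 0, coh, np.nan)
    # Cauchy-Schwarz bounds coherence by 1; clip float dust only.
    coh = np.where(np.isnan(coh), coh, np.clip(coh, 0.0, 1.0))
    return CoherenceResult(coh=coh, freqs=spec.freqs, k=spec.k, array=spec.array)


def _bin_index(freqs: np.ndarray, f: float, snap: bool, tol: float = 1e-6) -> int:
    i = int(np.argmin(np.abs(freqs - f)))
    if abs(freqs[i] - f) > tol:
        if not snap:
            raise SpectralError(
                f"{f} Hz is not on the {freqs[1] - freqs[0]:.6g} Hz bin grid "
                "(pass snap=True to use the nearest bin)")
        logger.warning("snapping %.4g Hz to nearest bin %.4g Hz", f, freqs[i])
    return i


def peak_ckc(result: CoherenceResult, stim_freq: float,
             channel_set: Sequence[int] | None = None,
             snap: bool = False) -> CoherenceResult:
    """Peak coherence at the stimulation frequency over ``channel_set``.

    Defaults to the gradiometers (the reporting convention: the strongest
    gradiometer and its planar partner).  Ties break to the lowest channel
    index.
    """
    if channel_set is None:
        channel_set = result.array.channel_set(GRAD)
    channel_set = np.asarray(channel_set, dtype=int)
    if channel_set.size == 0:
        raise SpectralError("empty channel set")
    bi = _bin_index(result.freqs, stim_freq, snap)
    vals = result.coh[channel_set, bi]
    if np.all(np.isnan(vals)):
        raise SpectralError("coherence undefined on the whole channel set")
    best = int(np.nanargmax(vals))  # argmax returns the first max: lowest index
    ch = int(channel_set[best])
    pair = int(result.array.pair_index[ch])
    pair_val = float(result.coh[pair, bi]) if pair >= 0 else None
    return replace(result, stim_freq=float(result.freqs[bi]),
                   peak_value=float(vals[best]), peak_channel=ch,
                   peak_pair=pair, peak_pair_value=pair_val)


def significance_threshold(n_trials: float, n_sens: int, n_f: int = 1,
                           alpha: float = 0.05, d: float = 1.0) -> float:
    """Multiple-comparison-corrected coherence significance threshold.

    ``1 - (alpha/(n_sens*n_f)) ** (1/(n_trials/d - 1))``; requires
    ``n_trials/d > 1``.
    """
    if not 0 < alpha < 1:
        raise SpectralError("alpha must be in (0, 1)")
    if n_sens < 1 or n_f < 1:
        raise SpectralError("n_sens and n_f must be >= 1")
    eff = n_trials / d
    if eff <= 1:
        raise SpectralError("effective trial count n_trials/d must exceed 1")
    return 1.0 - (alpha / (n_sens * n_f)) ** (1.0 / (eff - 1.0))


def attach_threshold(result: CoherenceResult, alpha: float = 0.05,
                     n_f: int = 1, d: float = 1.0,
                     n_sens: int | None = None) -> CoherenceResult:
    """Attach the significance threshold for the searched channel set."""
    if n_sens is None:
        n_sens = len(result.array.channel_set(GRAD))
    thr = significance_threshold(result.k, n_sens, n_f, alpha, d)
    return replace(result, threshold=thr)


def sum_recordings(recordings: Sequence[SensorRecording],
                   trains: Sequence[StimulusTrain] | None = None) -> SensorRecording:
    """Element-wise sum of onset-locked recordings (the *separate_sum* input).

    All recordings must share the channel set and length; when stimulus
    trains are given, their onset grids must coincide (the separate runs are
    onset-locked by construction when they use the same burst schedule and
    frequency).
    """
    if not recordings:
        raise SpectralError("no recordings to sum")
    first = recordings[0]
    for r in recordings[1:]:
        if r.data.shape != first.data.shape or r.array is not first.array and \
                r.array.n_channels != first.array.n_channels:
            raise SpectralError("recordings have mismatched channel sets or lengths")
    if trains is not None:
        base = np.concatenate([np.sort(o) for o in
                               (next(iter(trains[0].onsets.values())),)])
        for t in trains[1:]:
            o = np.sort(next(iter(t.onsets.values())))
            if len(o) != len(base) or np.any(o != base):
                raise SpectralError("stimulus-onset grids are misaligned; "
                                    "cannot onset-lock the sum")
    data = np.sum([r.data for r in recordings], axis=0)
    return SensorRecording(data=data, array=first.array,
                           sample_rate=first.sample_rate)


def topography_table(result: CoherenceResult,
                     stim_freq: float | None = None) -> pd.DataFrame:
    """Per-channel coherence at the stimulation frequency, with positions.

    One row per channel: name, kind, sensor position (m), coherence.  This
    is the export used for topographic visualization in external tools.
    """
    f = stim_freq if stim_freq is not None else result.stim_freq
    if f is None:
        raise SpectralError("no stimulation frequency given")
    bi = _bin_index(result.freqs, f, snap=False)
    arr = result.array
    return pd.DataFrame({
        "channel": list(arr.names),
        "kind": list(arr.kind),
        "x": arr.pos[:, 0], "y": arr.pos[:, 1], "z": arr.pos[:, 2],
        "coherence": result.coh[:, bi],
    })


def sensor_ckc(epochs: EpochSet, stim_freq: float, alpha: float = 0.05,
               n_f: int = 1, d: float = 1.0,
               channel_set: Sequence[int] | None = None) -> CoherenceResult:
    """Spectra -> coherence -> peak -> threshold, in one call."""
    res = coherence(epoch_spectra(epochs))
    res = peak_ckc(res, stim_freq, channel_set)
    return attach_threshold(res, alpha=alpha, n_f=n_f, d=d,
                            n_sens=len(channel_set) if channel_set is not None
                            else None)
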