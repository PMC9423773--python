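"""Synthetic MEG + accelerometer data with the structure the CKC analysis assumes.

The generative model is deliberately simple but captures what matters for
corticokinematic coherence (CKC), which is driven by phase locking between
finger kinematics and cortical activity:

* each active finger produces a strictly periodic onset train inside its
  stimulation bursts (the pneumatic actuator has millisecond timing accuracy);
* finger acceleration is the onset train convolved with a movement kernel,
  per axis, plus white accelerometer noise;
* each finger drives a cortical source: the onset train, jittered by a small
  onset jitter, convolved with an evoked-response kernel, scaled by a
  coupling gain (nAm) and projected through the toy lead field;
* concurrent stimulation of *other* fingers at *different* frequencies
  degrades the phase locking of a finger's cortical response.  This is
  modelled as extra onset jitter proportional to the cross-finger
  interference weight — the mechanism behind the expected drop of CKC in the
  varied-frequency condition.  Other fingers' drives are also mixed linearly
  into the source (additive afference), which in the constant-frequency
  condition adds coherently and strengthens CKC;
* sensors see the summed source projections plus 1/f background and white
  noise, with optional high-amplitude artifact transients to exercise
  epoch rejection.

All randomness descends from one root seed through named child streams
(noise, jitter, artifacts, acceleration), so toggling one component does not
shift the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .design import Condition, StimulusDesign
from .forward import GRAD, MAG, LeadField, SensorArray, SourceGrid


class SimulationError(ValueError):
    pass


class KernelOverlapWarning(UserWarning):
    """Kernel longer than the stimulus-onset asynchrony: pulses overlap."""


# ---------------------------------------------------------------------------
# kernels

def hann_pulse_kernel(width_ms: float, sample_rate: float = 1000.0) -> np.ndarray:
    """Smooth unimodal pulse of ``width_ms``, normalized to unit area."""
    n = max(int(round(width_ms * sample_rate / 1000.0)), 1)
    k = np.hanning(n + 2)[1:-1]
    return k / k.sum()


def biphasic_kernel(width_ms: float = 300.0, sample_rate: float = 1000.0) -> np.ndarray:
    """Biphasic evoked-response kernel (one windowed sine cycle, unit peak).

    Stands in for the cortical evoked waveform; CKC depends on phase locking,
    not on the exact waveform shape, but the kernel must carry energy at the
    drive frequency, so the default spans most of a 3 Hz movement cycle
    (sustained evoked fields do in practice).
    """
    n = max(int(round(width_ms * sample_rate / 1000.0)), 2)
    t = np.arange(n) / n
    k = np.sin(2 * np.pi * t) * np.hanning(n)
    return k / np.max(np.abs(k))


# ---------------------------------------------------------------------------
# stimulus trains

@dataclass(frozen=True)
class StimulusTrain:
    """Per-finger onset samples and the sample grid they live on."""

    onsets: Mapping[str, np.ndarray]  # finger -> onset sample indices
    n_samples: int
    sample_rate: float

    def drive(self, finger: str, kernel: np.ndarray | None = None) -> np.ndarray:
        """Continuous drive waveform: onset impulses convolved with ``kernel``.

        With ``kernel=None`` the drive is the bare unit-impulse train.
        """
        x = np.zeros(self.n_samples)
        x[self.onsets[finger]] = 1.0
        if kernel is None:
            return x
        return fftconvolve(x, kernel)[: self.n_samples]


def make_stimulus_train(design: StimulusDesign) -> StimulusTrain:
    """Periodic onset trains inside the active bursts, on the sample grid.

    The inter-onset interval is the drive period quantized to the nearest
    sample (333 ms at 3 Hz / 1 kHz).  A frequency whose period is more than
    one sample away from any representable grid period is rejected.
    """
    fs = design.sample_rate
    onsets: dict[str, np.ndarray] = {}
    for f in design.fingers:
        freq = design.freq_per_finger[f]
        period = fs / freq
        p = int(round(period))
        if p < 2 or abs(period - p) > 1.0:
            raise SimulationError(
                f"finger {f}: {freq} Hz is not representable on the "
                f"{fs} Hz sample grid within 1 sample")
        idx = []
        for start_s, dur_s in design.burst_schedule:
            s0 = int(round(start_s * fs))
            n_in = int(np.floor((dur_s * fs - 1) / p)) + 1
            idx.append(s0 + p * np.arange(n_in))
        onsets[f] = (np.concatenate(idx) if idx
                     else np.empty(0, dtype=int)).astype(int)
    return StimulusTrain(onsets=onsets, n_samples=design.n_samples,
                         sample_rate=fs)


# ---------------------------------------------------------------------------
# kinematics

@dataclass(frozen=True)
class KinematicSignal:
    """Three-axis accelerometer trace of one finger."""

    finger: str
    axes: np.ndarray  # (3, n_samples)
    sample_rate: float

    def __post_init__(self):
        axes = np.asarray(self.axes, dtype=float)
        if axes.ndim != 2 or axes.shape[0] != 3:
            raise SimulationError("axes must be (3, n_samples)")
        if not np.all(np.isfinite(axes)):
            raise SimulationError("non-finite acceleration values")
        object.__setattr__(self, "axes", axes)

    @property
    def n_samples(self) -> int:
        return self.axes.shape[1]


def synth_acceleration(train: StimulusTrain, finger: str,
                       kernel: np.ndarray | None = None,
                       axis_gains: Sequence[float] = (9.0, 3.0, 1.5),
                       noise_sd: float = 0.05,
                       seed: int | np.random.SeedSequence = 0) -> KinematicSignal:
    """Accelerometer trace: per-axis scaled drive plus white sensor noise.

    ``axis_gains`` model the dominant movement axis of the horizontal
    actuator; units are arbitrary (coherence is scale invariant).
    """
    if kernel is None:
        kernel = hann_pulse_kernel(50.0, train.sample_rate)
    ons = train.onsets[finger]
    if len(ons) > 1:
        soa = np.min(np.diff(np.sort(ons)))
        if len(kernel) > soa:
            warnings.warn(
                f"kernel ({len(kernel)} samples) longer than the "
                f"stimulus-onset asynchrony ({soa} samples): pulses overlap",
                KernelOverlapWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    drive = train.drive(finger, kernel)
    axes = np.empty((3, train.n_samples))
    for a, g in enumerate(axis_gains):
        axes[a] = g * drive + noise_sd * rng.standard_normal(train.n_samples)
    return KinematicSignal(finger=finger, axes=axes, sample_rate=train.sample_rate)


# ---------------------------------------------------------------------------
# sensor-level simulation

@dataclass(frozen=True)
class SensorRecording:
    """Multichannel MEG-like recording with channel metadata."""

    data: np.ndarray  # (channels, samples)
    array: SensorArray
    sample_rate: float

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.shape[0] != self.array.n_channels:
            raise SimulationError("data rows must match the sensor array")
        object.__setattr__(self, "data", data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ArtifactSpec:
    """Square-pulse transients injected to exercise epoch rejection."""

    n_artifacts: int = 0
    amplitude: float = 3000.0  # fT/cm on a gradiometer (x2 on its site's magnetometer)
    duration_ms: float = 200.0


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters of a simulated session.

    ``source_nodes`` maps fingers to grid node indices; ``coupling_gain`` is
    the evoked dipole moment per finger in nAm; ``cross_finger_interference``
    is the dimensionless weight with which other concurrently driven fingers'
    drives mix into (and, at distinct frequencies, de-phase) a finger's
    source.  ``onset_jitter_sd_ms`` is the intrinsic cortical-response onset
    jitter; ``interference_jitter_ms`` the extra jitter per unit interference
    per concurrent distinct-frequency finger.
    """

    source_nodes: Mapping[str, int]
    coupling_gain: Mapping[str, float]
    cross_finger_interference: float = 0.3
    onset_jitter_sd_ms: float = 4.0
    interference_jitter_ms: float = 100.0
    sensor_noise_sd: float = 60.0   # white noise, fT/cm on gradiometers
    pink_noise_amp: float = 80.0    # 1/f background RMS, fT/cm on gradiometers
    mag_noise_ratio: float = 2.0    # magnetometer noise in fT relative to gradiometers
    movement_scale: float = 1.0     # per-condition acceleration amplitude scalar
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    seed: int = 0

    def __post_init__(self):
        if any(g < 0 for g in self.coupling_gain.values()):
            raise SimulationError("coupling gains must be >= 0")
        if self.onset_jitter_sd_ms < 0 or self.interference_jitter_ms < 0:
            raise SimulationError("jitter must be >= 0")


def default_ground_truth(grid: SourceGrid, gain: float = 0.4,
                         seed: int = 0, **overrides) -> GroundTruth:
    """Ground truth with per-finger sources in a hand-knob-like patch.

    The four sources sit within a few millimetres of each other in the
    left Rolandic region, emulating overlapping proprioceptive finger
    representations; each couples with the same gain by default.
    """
    approx = {"D2": (-46.0, -23.0, 53.0), "D3": (-45.0, -24.0, 57.0),
              "D4": (-44.0, -25.0, 58.0), "D5": (-43.0, -26.0, 56.0)}
    nodes = {f: grid.nearest_node(x) for f, x in approx.items()}
    gains = {f: gain for f in approx}
    return GroundTruth(source_nodes=nodes, coupling_gain=gains, seed=seed,
                       **overrides)


def _streams(seed) -> dict:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(4)
    return dict(zip(("noise", "jitter", "artifacts", "acceleration"), children))


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                f_min: float = 0.1, sample_rate: float = 1000.0) -> np.ndarray:
    """Unit-RMS 1/f noise per channel (spectrum flattened below ``f_min``)."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sample_rate)
    amp = 1.0 / np.sqrt(np.maximum(freqs, f_min))
    amp[0] = 0.0
    spec = amp * (rng.standard_normal((n_channels, len(freqs)))
                  + 1j * rng.standard_normal((n_channels, len(freqs))))
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def _tangential_orientation(node_mm: np.ndarray) -> np.ndarray:
    """A unit vector tangential to the head sphere at the node."""
    r = np.linalg.norm(node_mm)
    if r < 1e-9:
        return np.array([1.0, 0.0, 0.0])
    n = node_mm / r
    ref = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    t = np.cross(n, ref)
    return t / np.linalg.norm(t)


def _jittered_impulses(onsets: np.ndarray, sd_ms: float, n_samples: int,
                       fs: float, rng: np.random.Generator) -> np.ndarray:
    x = np.zeros(n_samples)
    if len(onsets) == 0:
        return x
    shift = np.round(rng.normal(0.0, sd_ms, size=len(onsets)) * fs / 1000.0).astype(int) \
        if sd_ms > 0 else np.zeros(len(onsets), dtype=int)
    idx = np.clip(onsets + shift, 0, n_samples - 1)
    np.add.at(x, idx, 1.0)
    return x


def synth_sensor_recording(design: StimulusDesign, truth: GroundTruth,
                           leadfield: LeadField,
                           evoked_kernel: np.ndarray | None = None,
                           train: StimulusTrain | None = None) -> SensorRecording:
    """Project per-finger cortical responses through the lead field, add noise.

    See the module docstring for the generative model.  Bit-reproducible for
    a fixed ``truth.seed``.
    """
    array = leadfield.array
    fs = design.sample_rate
    n = design.n_samples
    if evoked_kernel is None:
        evoked_kernel = biphasic_kernel(300.0, fs)
    if train is None:
        train = make_stimulus_train(design)
    if train.n_samples != n:
        raise SimulationError("stimulus train duration does not match the design")
    for f in design.fingers:
        if not 0 <= truth.source_nodes[f] < leadfield.grid.n_nodes:
            raise SimulationError(f"finger {f}: source node index out of range")

    streams = _streams(truth.seed)
    rng_noise = np.random.default_rng(streams["noise"])
    rng_jit = np.random.default_rng(streams["jitter"])
    rng_art = np.random.default_rng(streams["artifacts"])

    is_grad = np.array([k == GRAD for k in array.kind])
    unit_scale = np.where(is_grad, 1.0, truth.mag_noise_ratio)

    data = np.zeros((array.n_channels, n))
    freqs = design.active_freqs()
    for f in design.fingers:
        others_distinct = sum(1 for g in design.fingers
                              if g != f and abs(freqs[g] - freqs[f]) > 1e-12)
        sd = truth.onset_jitter_sd_ms + (truth.interference_jitter_ms
                                         * truth.cross_finger_interference
                                         * others_distinct)
        impulses = _jittered_impulses(train.onsets[f], sd, n, fs, rng_jit)
        if truth.cross_finger_interference > 0:
            for g in design.fingers:
                if g == f:
                    continue
                impulses = impulses + truth.cross_finger_interference * \
                    _jittered_impulses(train.onsets[g], sd, n, fs, rng_jit)
        source = truth.coupling_gain[f] * fftconvolve(impulses, evoked_kernel)[:n]
        node = truth.source_nodes[f]
        ori = _tangential_orientation(leadfield.grid.nodes[node])
        gains = leadfield.full[node] @ ori  # (channels,)
        data += np.outer(gains, source)

    if truth.sensor_noise_sd > 0:
        data += (truth.sensor_noise_sd * unit_scale)[:, None] * \
            rng_noise.standard_normal((array.n_channels, n))
    if truth.pink_noise_amp > 0:
        data += (truth.pink_noise_amp * unit_scale)[:, None] * \
            _pink_noise(rng_noise, array.n_channels, n, sample_rate=fs)

    art = truth.artifacts
    if art.n_artifacts > 0:
        dur = int(round(art.duration_ms * fs / 1000.0))
        grads = np.nonzero(is_grad)[0]
        for _ in range(art.n_artifacts):
            start = int(rng_art.integers(0, max(n - dur, 1)))
            ch = int(rng_art.choice(grads))
            data[ch, start:start + dur] += art.amplitude
            site_mag = ch + (2 - ch % 3)  # the site's magnetometer channel
            data[site_mag, start:start + dur] += art.amplitude * truth.mag_noise_ratio

    return SensorRecording(data=data, array=array, sample_rate=fs)


def synth_session(design: StimulusDesign, truth: GroundTruth, leadfield: LeadField,
                  acc_noise_sd: float = 0.05):
    """Convenience: one recording plus per-finger accelerometer traces.

    Returns ``(recording, {finger: KinematicSignal}, train)``.  Acceleration
    amplitude is scaled by ``truth.movement_scale`` (per-condition movement
    range differences; coherence is scale invariant, so the default is 1).
    """
    train = make_stimulus_train(design)
    rec = synth_sensor_recording(design, truth, leadfield, train=train)
    acc_seeds = _streams(truth.seed)["acceleration"].spawn(len(design.fingers))
    kinematics = {}
    for i, f in enumerate(design.fingers):
        gains = tuple(truth.movement_scale * g for g in (9.0, 3.0, 1.5))
        kinematics[f] = synth_acceleration(
            train, f, axis_gains=gains, noise_sd=acc_noise_sd, seed=acc_seeds[i])
    return rec, kinematics, train
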