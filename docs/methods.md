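# Methods

This note documents the models, defaults and numerical choices behind the
`ckc` package: what the analysis computes, what the synthetic-data generator
emulates (and deliberately does not), and where the design was genuinely
open.

## The coherence estimate

Coherence is computed from epoch-averaged spectra with a bare
rectangular-window DFT of each 4000 ms epoch — no taper, no Welch
sub-segmentation — so the frequency resolution is exactly
1/epoch_length = 0.25 Hz and the stimulation frequencies 2, 2.5, 3 and
3.5 Hz fall on bin centres (asserted at configuration time via
`assert_freqs_on_bins`). Epochs step by epoch_length − overlap = 3995 ms;
the epoch grid restarts at each stimulation burst (data are acquired in
1-min runs), so a 60 s burst yields exactly 15 epochs and an epoch never
straddles a burst boundary.

Rejection uses strict inequality ("exceeding" the 2000 fT/cm gradiometer /
4000 fT magnetometer peak-to-peak limits); an epoch exactly at threshold is
kept. Reference epochs are normalized to unit Euclidean norm after
rejection. Normalization cannot change the coherence of equal-power epochs
(coherence is scale invariant per epoch set); with unequal-power epochs it
re-weights them, which is the estimator the method prescribes.

The significance threshold
`1 − (α/(N_sens·N_f))^(1/(N_trials/d − 1))` is implemented verbatim with
α exposed (default 0.05) and N_f defaulting to 1 (only the movement
frequency is tested). The overlap divisor `d` defaults to 1: with a 5 ms
overlap on 4000 ms epochs the trials are essentially independent, and the
published use of d mixes units (milliseconds dividing a count). The literal
reading remains available through the `d` parameter.

Known property used by the tests: for independent signals the estimator's
expected coherence is 1/K, and for Y = X + n with equal variances it
converges to SNR/(1+SNR) = 1/2; both are verified by Monte-Carlo at K = 100
and K = 1000.

### Peak statistic and its selection noise

Peak CKC is the max over gradiometers at the stimulation bin (magnetometers
includable by flag); ties break to the lowest channel index, and the planar
partner's coherence is reported alongside. Because the peak is a maximum
over ~10² channels, at small K it rides on selection noise: the null peak
over 64 gradiometers at K = 20 is ≈ 0.2–0.3, which is exactly what the
threshold formula corrects for. Scaled-down simulations therefore use
K ≥ 20–30 so that condition effects clear this floor; real sessions have
K ≈ 200.

## Source model (DICS)

The sensor CSD at the stimulation bin, the sensor–reference cross-spectral
vector and the reference power are estimated from the same epochs. Each
grid node's channels×3 lead field is reduced to the two strongest singular
components (columns `U[:, :2]·s[:2]`, sign fixed by making the
largest-magnitude element of each column positive); the unit-gain
minimum-variance filter `W = (LᴴC_r⁻¹L)⁻¹LᴴC_r⁻¹` uses diagonal loading
`C_r = C + reg·mean(diag C)·I` with reg = 0.05 by default (exposed). The
2-component output is scalarized along the dominant eigenvector of the
source CSD `W C Wᴴ`, and the node value is the ordinary magnitude-squared
coherence of that beamformed source with the reference — guaranteed to lie
in [0, 1] because numerator and denominator come from the same epoch
average (Cauchy–Schwarz). A singular or still-ill-conditioned loaded CSD
(condition number > 1e12) raises an error suggesting more loading rather
than returning garbage.

Limitation: with a strong 1/f background, same-data beamforming loses
20–30% of peak coherence relative to the best sensor (epoch-to-epoch
correlation of low-frequency noise causes partial signal cancellation);
localization is unaffected in our simulations (20/20 recovery within one
grid spacing at SNR ≥ 5 on a 125-node grid), but absolute source CKC values
should be compared across conditions, not against sensor values. The
sensor–source consistency test therefore uses a white-noise-dominated
simulation.

## Group statistics

The permutation test swaps, per subject, the two labels (fingers or
conditions) with probability ½ and recomputes the Euclidean distance
between group means; `p = (b+1)/(m+1)` with a `≥` tail count (add-one rule,
so p > 0 at finite m; conservative at ties). Per-subject paired swaps were
chosen over pooled relabelling because the design is repeated-measures;
pooled relabelling is available behind a flag, as is exact enumeration of
all 2ⁿ swap patterns (used by the tests at n = 4) and the alternative
mean-of-per-subject-distances statistic. The statistic defaults to the
distance between group means, matching how grand-average coordinates are
reported.

ANOVA-family analyses are out of scope by design: the package emits tidy
long-format (subject, finger, condition, level, ckc) tables for external
statistics tooling, with duplicate cells rejected and missing cells flagged
rather than dropped.

## The synthetic-data generator

The generator reproduces the three-condition protocol: simultaneous
stimulation of D2–D5 at 3 Hz in three 1-min bursts; each finger separately
at 3 Hz in three 1-min bursts; and continuous 4-min stimulation at 2, 2.5,
3, 3.5 Hz for D2–D5. Onset trains are strictly periodic within bursts with
the period quantized to the sample grid (333 ms at 3 Hz / 1 kHz).

Generative model per finger:

* **acceleration** — onset train ⊛ 50 ms unimodal pulse per axis with axis
  gains (9, 3, 1.5) and white noise (SD 0.05), mimicking a dominant
  movement axis; a per-condition `movement_scale` models the small
  between-condition movement-range differences but defaults to 1 because
  coherence is scale invariant;
* **cortical source** — onset train, jittered per onset, ⊛ a 300 ms
  biphasic evoked kernel, scaled by the coupling gain (nAm) and projected
  through the node's lead field along a tangential orientation. The kernel
  must carry energy at the 2–3.5 Hz readout frequencies, which is why the
  default spans most of a movement cycle (sustained evoked fields do); a
  very short biphasic kernel would make CKC vanish at the movement
  frequency regardless of coupling strength;
* **cross-finger interference** — other concurrently driven fingers' trains
  mix into each source with weight 0.3, and each concurrent
  distinct-frequency finger adds onset jitter (100 ms × weight per finger).
  At equal frequencies the mixed drives add coherently (the
  summed-afference mechanism behind H1); at distinct frequencies the extra
  jitter scrambles the phase locking and its incoherent residual acts as
  noise at the readout bin (the mechanism behind H2);
* **noise** — independent per-channel white noise (60 fT/cm SD on
  gradiometers) plus 1/f background (80 fT/cm RMS, spectrum flattened below
  0.1 Hz), magnetometers scaled ×2 in their own units; optional square-pulse
  artifact transients (default 3000 fT/cm, 200 ms) exercise rejection;
* **randomness** — one root seed spawns named child streams (noise, jitter,
  artifacts, acceleration), so toggling one component does not shift the
  others; fixed seed ⇒ bit-identical output.

The forward model is the Sarvas single-sphere solution (origin-centred,
90 mm head radius) on a Fibonacci-cap helmet of 102 sites at 102 mm, each
with two orthogonal planar gradiometers (finite-difference over a 16.8 mm
baseline, fT/cm) and one magnetometer (radial field, fT). Radial sources
and the sphere centre are silent, gains decay with depth, and coincident
geometry gives identical gains — the structural properties the analysis
needs — but no anatomy: no BEM, no MRI, no head movement, no physiological
artifacts beyond simple transients.

**Calibration.** The coupling gain (0.4 nAm) and noise levels were chosen
once so that single-finger sensor CKC sits near the ~0.45 level typical of
real separate-finger stimulation at realistic evoked amplitudes
(~50 fT/cm). With four co-located sources summing linearly, the
simultaneous-constant condition saturates near CKC ≈ 1 — the linear toy
model overshoots the ~15% enhancement seen in real data, where cortical
summation is sublinear — so simultaneous-vs-separate comparisons on
synthetic data are meaningful in direction, not magnitude. Passing
directional tests shows the pipeline detects summed afference and phase
scrambling as designed; it does not validate effect sizes on real MEG.

**What pairing shuffles cannot test.** With a strictly periodic stimulus
and the 3995 ms epoch step, the onset phase drifts only ~1 ms per epoch, so
reference epochs are nearly interchangeable and permuting the MEG–reference
pairing preserves the phase lock (this is true of the real protocol as
well). The significance sanity check therefore uses per-epoch random
circular shifts of the reference, which do scramble the phase relation.

## Problem sizes

Simulation-backed tests run at desk scale: a 32-site helmet (96 channels),
one to two 40–60 s bursts per run (K = 10–30 epochs), a 125-node 4-mm
scan grid, and 5–20 seeds per directional claim; `scripts/acceptance.py`
uses the same sizes. The full 102-site, 3×60 s + 4-min configuration is the
`RunConfig()` default and runs unchanged, just longer. Trial-count matching
(the separate-condition K capping the varied-condition K per finger) and
the separate_sum analysis — the onset-locked sum of the four separate
recordings, with rejection thresholds scaled by √n_runs because summing n
independent runs scales background noise by √n — follow the protocol.

## Degenerate inputs and tie-breaks

Zero-power bins are flagged NaN (undefined), never 0; zero-norm reference
epochs and all-zero lead-field blocks raise errors naming the offender;
all-epochs-rejected raises with per-channel peak-to-peak diagnostics;
off-grid stimulation frequencies raise unless an explicit (logged) snap is
requested; argmax ties (channels, nodes) break to the lowest index.
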