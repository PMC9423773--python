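# ckc — corticokinematic coherence for multi-finger proprioceptive stimulation

Corticokinematic coherence (CKC) quantifies the phase coupling between limb
kinematics and cortical magnetoencephalography (MEG) signals. It peaks at
the movement frequency over the primary sensorimotor (SM1) cortex and is
used to localize the cortical proprioceptive hand representation — for
example, when mapping the hand region before brain surgery — and to
quantify proprioceptive processing in clinical groups.

This package implements the full CKC analysis chain for experiments in which
the fingers (D2–D5) are moved by a pneumatic actuator at 2–3.5 Hz, either
one at a time, all together at one frequency, or all together at
finger-specific frequencies. Because such MEG datasets are rarely shareable,
the package ships a first-class synthetic-data generator that emulates the
statistical structure the analysis relies on, so every stage is testable
end to end without any download.

## The statistic

Continuous MEG and the per-finger acceleration magnitude (Euclidean norm of
the three accelerometer axes, band-passed 0.5–195 Hz) are cut into K epochs
of 4000 ms with a 5 ms overlap. Epochs exceeding 2000 fT/cm (gradiometers)
or 4000 fT (magnetometers) peak-to-peak are excluded, and each reference
epoch is normalized to unit Euclidean norm. With X_k(f), Y_k(f) the DFTs of
the k-th MEG and reference epochs,

    Pxx(f) = (1/K) Σ X_k X_k*      Pyy(f) = (1/K) Σ Y_k Y_k*
    Pxy(f) = (1/K) Σ X_k Y_k*      Coh(f) = |Pxy|² / (Pxx · Pyy)

Peak CKC is the maximum coherence at the stimulation frequency over the
gradiometers, with the multiple-comparison-corrected significance threshold

    coh_thr = 1 − (α / (N_sens · N_f))^(1 / (N_trials/d − 1)).

At the source level a DICS (dynamic imaging of coherent sources) beamformer
scans a 3-mm volumetric grid: each node's 3-column lead field is reduced to
its two strongest singular components, a unit-gain minimum-variance spatial
filter is built from the diagonally loaded sensor cross-spectral density at
the stimulation frequency, and the coherence between the beamformed source
and the kinematic reference is mapped; the map maximum gives the peak source
location. Group-level peak coordinates are compared with a nonparametric
permutation test on the Euclidean distance between group means (per-subject
label swaps, add-one p-value).

## Worked example

```python
import ckc

# run the three-condition experiment on synthetic data (desk-scale config)
report = ckc.run_experiment(ckc.RunConfig.demo(seed=1))
cell = report.cell("separate", "D2")
print(f"K={cell['k']}  peak CKC={cell['sensor_peak_ckc']:.3f} "
      f"(threshold {cell['threshold']:.3f}, "
      f"significant={cell['significant']})")
print("source peak at", cell["source_peak_mm"], "mm")

summary = ckc.compare_conditions(report)
print({k: round(v["mean"], 3) for k, v in summary.items()
       if isinstance(v, dict)})
print("H1:", summary["h1_simultaneous_gt_separate"],
      " H2:", summary["h2_varied_lt_separate"])
```

prints

```
K=20  peak CKC=0.318 (threshold 0.314, significant=True)
source peak at [-48.0, -28.0, 56.0] mm
{'simultaneous_constant': 0.978, 'separate': 0.434, 'simultaneous_varied': 0.234, 'separate_sum': 0.706}
H1: True  H2: True
```

The index finger's separate-stimulation CKC (0.32 here, with only K=20
epochs in the reduced demo) exceeds its significance threshold; the source
peak falls in the simulated hand-knob patch. Condition means reproduce the
two directional effects the method is used to demonstrate: simultaneous
same-frequency stimulation of all four fingers yields stronger CKC than
separate stimulation (summed proprioceptive afference, H1), while
simultaneous stimulation at finger-specific frequencies yields weaker CKC
(cross-finger interference scrambles the phase locking, H2).

The same stages are scriptable from the shell:

```bash
ckc simulate --out run1 --seed 1 --condition separate_D2
ckc epoch run1/recording.h5 run1/acceleration_D2.tsv --design run1/design.json --out epochs.h5
ckc coh epochs.h5 --stim-freq 3 --out ckc.json
ckc source epochs.h5 --stim-freq 3 --out source.json --map-out map.tsv
ckc run --demo --out results_dir --seed 1
```

## Layout

- `ckc.design` / `ckc.simulate` / `ckc.forward` — stimulus designs, the
  synthetic MEG + accelerometer generator, and the single-sphere toy
  forward model (102-site helmet: 204 planar gradiometers + 102
  magnetometers).
- `ckc.epoching` — band-pass, acceleration magnitude, segmentation,
  peak-to-peak rejection, reference normalization, trial-count matching.
- `ckc.spectral` — epoch-averaged spectra, coherence, peak CKC,
  significance threshold, onset-locked summation of runs, topography table.
- `ckc.source` — CSD at the stimulation frequency, lead-field rank
  reduction, the DICS coherence map and peak-source extraction.
- `ckc.stats` — group mean coordinates, permutation distance test, tidy
  contrast tables for external ANOVA tooling.
- `ckc.pipeline` / `ckc.cli` — the configured end-to-end experiment and the
  `ckc` command-line interface.

See `docs/methods.md` for the generative model, parameter defaults and
known limitations.
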