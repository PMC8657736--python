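# ergop

Time-frequency analysis of full-field electroretinogram (ffERG) oscillatory
potentials, built for studying how cone photoreceptor dysfunction —
achromatopsia (ACHM) as the model disease — reshapes the fast (75–300 Hz)
oscillations that ride the rising b-wave of dark-adapted flash responses.

The package is aimed at visual electrophysiologists and methods developers
who want a fully reproducible, simulation-backed implementation of this
analysis chain:

1. **simulate** — synthetic ERG cohorts (controls vs ACHM) with calibrated
   a-/b-waves, two OP bursts, noise and between-subject variability;
2. **preprocess** — 0.3–300 Hz zero-phase band-pass, 5-sweep and both-eye
   averaging to one trace per subject;
3. **features** — a-/b-wave amplitudes and implicit times, OP and sub-band
   traces;
4. **timefreq** — complex Morlet scalograms in baseline-relative dB;
5. **stats** — Shapiro–Wilk + Wilcoxon rank-sum on scalar features, and a
   cluster-based permutation test over the time-frequency plane.

## The core methods

**Morlet scalogram.** Each subject trace is convolved with complex Morlet
wavelets `cmw(t) = e^{i2πft}·e^{−t²/2s²}`, `s = n/(2πf)`, where the cycle
count *n* grows log-linearly from 3 at 10 Hz to 7 at 300 Hz (temporal
precision at low f, spectral precision at high f). Power `|x∗cmw|²` is
normalized per frequency by its mean pre-stimulus (−20…0 ms) power and
expressed as `10·log₁₀(P/P_baseline)` dB; points inside the cone of
influence (within 2s of an epoch edge) are masked out.

**Cluster permutation test.** Welch's t (one-tailed, control > ACHM) is
computed at every valid (time, frequency) point; points with p < 0.05 form
4-connected clusters scored by summed t (cluster mass). Observed masses are
compared with the distribution of the *maximum* cluster mass under random
relabelings of subjects (default 1000 permutations), giving familywise-
corrected cluster p-values `p = (1+#{null ≥ mass})/(1+n_perm)`.

## Worked example

Recover the published control DA 3.0 waveform values from a noise-free
preset trace, then run the two-group time-frequency comparison on a
simulated cohort:

```python
from dataclasses import replace
from ergop import (preset, generate_trace, extract_wave_features,
                   CohortConfig, simulate_cohort, subject_trace_from_sweeps,
                   WaveletSpec, subject_scalogram, stack_maps,
                   cluster_permutation_test)

p = replace(preset("control", "DA3"), noise_sd_uV=0.0, drift_sd_uV=0.0)
f = extract_wave_features(generate_trace(p, 5000.0, "DA3"))
print(f"a: {f.a_amp_uV:.1f} uV @ {f.a_time_ms:.1f} ms   "
      f"b: {f.b_amp_uV:.1f} uV @ {f.b_time_ms:.1f} ms")

cfg = CohortConfig(20, 20, "DA3", 5000.0, preset("control", "DA3"),
                   preset("achm", "DA3"), between_subject_cv=0.2, seed=101)
cohort = simulate_cohort(cfg)
spec = WaveletSpec.default(5000.0)
scals = {"control": [], "achm": []}
for rec in cohort.values():
    scals[rec["group"]].append(
        subject_scalogram(subject_trace_from_sweeps(rec["sweeps"]), spec))
maps_c, mask_c = stack_maps(scals["control"])
maps_a, mask_a = stack_maps(scals["achm"])
res = cluster_permutation_test(maps_c, maps_a, n_permutations=500,
                               seed=101, valid_mask=mask_c & mask_a)
best = min(res.clusters, key=lambda c: c.p_value)
print(f"dominant cluster: mass={best.mass:.0f}, p={best.p_value:.4f}")
```

prints

```
a: -264.8 uV @ 14.6 ms   b: 449.8 uV @ 48.4 ms
dominant cluster: mass=73266, p=0.0020
```

The first line shows that the simulator's calibration makes the published
group means exactly recoverable by the extractor (a-wave baseline-to-trough,
b-wave trough-to-peak, implicit times from flash onset). The second line is
the headline group effect: the control-vs-ACHM power difference forms one
dominant significant cluster, and inspecting it (see
`ergop.stats.cluster_extent` / `mass_fraction`) shows it concentrated above
100 Hz within the first 60 ms — reduced high-frequency OP power in ACHM,
with the low-frequency burst largely spared.

There is also a CLI for file-based runs:

```sh
ergop simulate --n-control 10 --n-achm 10 --condition DA3 --seed 1 --out-dir cohort/
ergop run-all run.out_dir=run/ run.conditions=DA3 run.seed=1
```

which writes trace TSVs, a cohort manifest, per-subject features, a group
summary table, scalograms (HDF5), cluster tables, and a JSON run report;
every output names the SHA-256 hash of the resolved configuration, and
reruns with the same config are byte-identical.

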