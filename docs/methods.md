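# Methods

## Scope and model

`ergop` analyzes dark-adapted full-field electroretinograms (ffERG) in the
time-frequency domain, with the oscillatory potentials (OPs) as the object of
interest. It covers five stages: cohort simulation, acquisition-style
preprocessing, time-domain feature extraction, complex-Morlet scalograms in
baseline-relative dB, and a cluster-based permutation comparison of two
groups (healthy controls vs achromatopsia, ACHM). Because no public ERG
cohort with per-sweep traces exists for this design, the simulator is a
first-class, tested component: it defines the study conditions under which
every downstream claim is checked.

## Synthetic ERG model

A noise-free trace is the sum of four components on a uniform grid spanning
−100…+250 ms around flash onset (onset is a sample; components are zero for
t ≤ 0):

- **a-wave**: a negative Gaussian lobe (default SD 5 ms). The width is a free
  shape parameter; 5 ms gives a realistic trough FWHM (~12 ms) while keeping
  the lobe's spectral tail out of the 75–300 Hz OP band (< 5% RMS leakage,
  measured ~2%).
- **b-wave**: a positive Gaussian lobe (default SD 12 ms).
- **two OP bursts**: Gabor atoms (cosine under a Gaussian envelope). Defaults:
  an early low-frequency burst (85 Hz, centered 20 ms, 25 µV peak envelope,
  SD 8 ms) and a later high-frequency burst (160 Hz, centered 28 ms, 20 µV,
  SD 6 ms). No published per-burst amplitudes exist for this protocol; these
  are package presets chosen so the bursts ride the rising b-wave within the
  first 50 ms, clearly separated in frequency.

Gaussian lobes are not a biophysical retina model; they are chosen because
trough/peak placement is analytically controllable, so a cohort can be
parameterized directly by published group means.

### Calibration

Clinical convention measures the a-wave baseline-to-trough and the b-wave
trough-to-peak, both on the *composite* trace, where lobes and bursts
overlap. The generator therefore solves jointly for both lobes' gain and
center (damped fixed-point iteration on a dense 0.02 ms grid, sub-grid
parabolic refinement) so that the composite trough equals `(a_amp_uV,
a_time_ms)` and the composite trough-to-peak excursion equals `b_amp_uV`
with its peak at `b_time_ms`, to 0.005 µV / 0.02 ms. Each center's step is
halved whenever its residual changes sign: near an OP-ripple trough the
composite argmax jumps discontinuously between neighbouring ripple peaks, and
no exact solution exists; in that (rare, jitter-induced) case the calibration
accepts the nearest attainable peak if amplitude residuals are < 0.05 µV and
timing is within 3 ms. Infeasible targets — a trough-to-peak target below
the burst ripple, or below what any positive b lobe can reach — raise a
`CalibrationError` rather than silently distorting the morphology.

### Presets and group effects

The four presets (`control_DA3`, `achm_DA3`, `control_DA10`, `achm_DA10`)
set a-/b-wave amplitudes and implicit times to published group means for the
DA 3.0 and DA 10.0 flashes (e.g. control DA 3.0: a = −264.8 µV at 14.6 ms,
b = 449.8 µV at 48.4 ms). The ACHM presets additionally attenuate the
high-frequency burst to 25% of the control amplitude and delay it by 3 ms,
and attenuate the low-frequency burst to 85% — "strongly reduced but not
absent" high-band activity with near-normal low-band activity, the contrast
the cluster test is meant to detect.

### Between-subject variability and noise

Subject-level parameters are lognormal multiplicative perturbations of the
group means (unit mean, sign preserved), controlled by one coefficient of
variation (default 0.2, matching published amplitude CVs of ~20–25%).
Amplitudes share 80% of their log-variance through a common response-scale
factor with 20% independent per component, because component amplitudes
co-vary strongly within a subject and fully independent draws occasionally
produce impossible morphologies (a b-peak below the OP ripple). Implicit
times jitter at 0.3× the amplitude CV, matching the ~3× smaller published
time CVs. Each sweep adds white Gaussian noise (default SD 10 µV) and
band-limited (< 5 Hz) baseline drift (default SD 5 µV). Randomness derives
from one master seed via counter-based child streams keyed on
(group, subject, eye, sweep), so outputs are reproducible under reordering.

The simulator does **not** model nystagmus or blink artifacts, photoreceptor
adaptation, correlated (1/f or mains) noise, asymmetry between eyes, or any
LA/flicker condition. Passing tests therefore demonstrate that the analysis
machinery recovers known structure under realistic amplitudes and noise —
not that it is robust to every artifact of clinical recordings.

## Preprocessing

Each sweep is band-passed 0.3–300 Hz with a 4th-order Butterworth applied
forward-backward (zero-phase, odd signal extension), mirroring the
acquisition bandwidth; only the bandwidth is standardized, the family and
order are package conventions. Zero-phase filtering is required so implicit
times are unbiased (< 0.2 ms trough shift on a symmetric lobe). The five
sweeps of each eye are averaged, then the two eyes, yielding one trace per
subject and condition. Filtering precedes averaging; by linearity the order
is immaterial for the mean, but it is fixed for reproducibility.

## Feature extraction

On the subject trace, the a-wave is the global minimum in (3, 35] ms
(errors if no sub-baseline trough exists), and the b-wave is the largest
local maximum after the trough up to 120 ms, earliest sample winning ties —
robust to OP ripple riding on the b-wave. Both extremum times are refined by
3-point parabolic interpolation (1 kHz sampling alone would quantize times
to 1 ms). b-amplitude is trough-to-peak by default (`b_amp_ref="baseline"`
switches to baseline-referenced); trough-to-peak is what makes the published
amplitude table self-consistent. The OP trace is the 75–300 Hz zero-phase
band-pass of the subject trace; sub-band traces use 50–100 Hz and
150–200 Hz. A band edge at or above 0.45·fs is clipped with a logged warning.

## Time-frequency decomposition

The mother wavelet is the complex Morlet `exp(i2πft)·exp(−t²/2s²)` with
`s = n/(2πf)`. The cycle count rises log-linearly from n = 3 at 10 Hz to
n = 7 at 300 Hz: `n(f) = exp(log 3 + (log 7 − log 3)·(log f − log 10)/(log 300 − log 10))`.
The default grid is 10–300 Hz in 2 Hz steps (146 frequencies). Kernels are
truncated at ±4 SD (tail contribution < e⁻⁸) and normalized to **unit gain
at the center frequency** (Fourier transform = 1 at f). Unit-energy
normalization was considered and rejected: it makes the kernel's peak
spectral density scale as 1/√σ_f, biasing raw power toward low frequencies
strongly enough to mislocalize a 150 Hz probe by one 2 Hz bin. Any
per-frequency scaling cancels in the baseline ratio, so this choice only
affects raw-power diagnostics.

Power is the squared magnitude of the linear convolution (computed in the
frequency domain; verified against direct convolution to 1e−9). Points
within 2s of either epoch edge are flagged invalid (cone of influence) and
excluded from statistics rather than imputed; epochs are generated at
−100…+250 ms precisely so that the −20…+100 ms analysis window stays
edge-safe except at the lowest frequencies. Each frequency row is divided by
its mean power over the pre-stimulus baseline (−20…0 ms; configurable) and
converted to dB via `10·log10` — a power, not amplitude, scale. dB maps are
invariant to global trace rescaling (amplifier gain). Baseline power is
floored at 1e−30 to keep all-zero inputs defined. Scalograms are computed
from subject-averaged traces (one per subject), at each condition's native
rate (5 kHz DA 3.0, 1 kHz DA 10.0), never resampled; group maps are
pointwise means of subject dB maps with AND-combined validity.

## Statistics

Scalar features: Shapiro–Wilk normality per group (reported), then the
two-sided Wilcoxon rank-sum (Mann–Whitney; exact for small tie-free samples,
normal approximation with tie correction otherwise). Identical constant
inputs raise a degenerate-data error.

Time-frequency comparison: Welch's two-sample t at every valid point,
one-tailed control > ACHM by default. The groups are independent and of
unequal size, so a paired statistic is not applicable; Welch avoids the
equal-variance assumption. Points with p < 0.05 (one-tail) form clusters
under 4-connectivity (time neighbor, frequency neighbor — the conservative
choice); each cluster is scored by its summed t (mass). The null
distribution is the maximum cluster mass over random permutations of the
subjects' group labels (group sizes preserved; 1000 permutations by
default), which controls the familywise error across the plane. Cluster
p-values use the add-one rule `p = (1 + #{null ≥ observed})/(1 + n_perm)`,
so p ≥ 1/(n_perm+1) and the test is never anti-conservative by construction.
Permutations, like everything else, are seeded; identical inputs and seed
reproduce the result exactly.

## Validation problem sizes

The shipped tests exercise: exact recovery of all four preset parameter sets
from noise-free traces (1 µV / 0.5 ms at 5 kHz; 2 µV at 1 kHz); the
rank-sum test against exhaustive enumeration at n = 3+3; the cluster finder
against a flood-fill oracle on 100 random 20×20 masks; familywise type-I
error of the permutation test on 100 null cohorts of 8+8 white-noise-derived
dB maps at 200 permutations (observed rate 0.05, accepted band 0.01–0.12);
and the headline group effect on simulated cohorts of 20+20 subjects
(DA 3.0, 5 kHz, 500 permutations), where the dominant cluster is significant
(p ≈ 0.002) with ≥ 80% (observed ~95%) of its mass above 100 Hz and before
60 ms. Feature-level separation is checked by drawing n = 51 vs 41 subjects
from the published group mean/SD table (rank-sum p < 0.001). These sizes
were chosen as the smallest that make the respective statistical statements
stable across seeds.

## Known limitations

- The generator's OP burst amplitudes are presets, not published values;
  absolute dB magnitudes of simulated scalograms are therefore arbitrary,
  and only relative/structural claims (localization, group contrast) are
  meaningful.
- The calibration guarantees composite extrema, not lobe "identity": the
  fitted a-lobe gain/center differ from the nominal amplitude/time whenever
  components overlap (that is the point of calibrating).
- One scalogram per subject (averaged trace); single-trial time-frequency
  analysis is out of scope.
- No multiple-comparison correction across the two flash conditions; each
  condition is tested on its own plane.
- Cluster inference is at the cluster level: the familywise guarantee
  applies to cluster existence, not to individual points inside a cluster.
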