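# Methods

This note documents the generative model, the preprocessing and
measurement chain, the statistics, and the numerical and design choices
behind `p300kit`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic cohort model

**Session design.** One recording is 120 visual stimuli, of which
`round(120 × 0.33) = 40` are targets placed by a seeded uniform shuffle
(a Bernoulli-per-trial mode is available via
`SessionConfig.bernoulli_targets`). Inter-stimulus intervals are i.i.d.
Uniform(3 s, 7 s) and onsets are their cumulative sums, so a session lasts
roughly 10 minutes; sampling rate 500 Hz; channels Fz, Cz, Pz, EOG. The
subject mentally counts targets; the simulated count report is
`true count + round(N(bias_g, sd_g))` with group-specific bias/sd chosen
so the two groups' report distributions match the published behavioral
summaries (HC 40.55 ± 1.61, MCI 39.75 ± 2.29). Reports deviating more than
10 % from truth exclude the subject, as in the study design.

**Latent structure.** Each subject carries a latency factor Z_L and an
amplitude factor Z_A (standard normal, correlation configurable, default
0). The value of each of the 12 measurement cells (2 conditions × 3
channels, latency and amplitude) is
`mean_cell + sd_cell * (λ·Z + sqrt(1−λ²)·ε_cell)` with cell loading
λ = 0.6 — chosen once as a typical test-retest-like within-subject
consistency for ERP peaks; it controls how strongly cells covary within a
subject and therefore the power of within-subject contrasts. Cell means
and sds default to the published HC/MCI group cells. Latencies are clipped
to [250, 700] ms and amplitudes floored at 0.5 µV; clipping (rather than
truncated-normal resampling) shifts large-sample cell means by well under
the calibration tolerance asserted in the tests (3·sd/√n).

**Scores.** Neuropsychological scores are a Gaussian copula over the
published marginal means/sds: score i is
`c_i·Z_L + d_i·Z_A + sqrt(1−c_i²−d_i²)·η_i` mapped through the marginal
and then rounded/capped per test (e.g. MMSE integer ≤ 30, total
recognition ≤ 15, Stroop seconds at one decimal). The implied correlation
matrix is positive semi-definite iff `c_i² + d_i² ≤ 1` per test; violations
raise an error naming the test. Default couplings are modest values with
the signs the analysis is expected to detect (e.g. digit-span forward
negatively coupled to latency, Stroop interference negatively to
amplitude); all are configurable, and observed score–peak correlations are
attenuated by the cell loading (≈ c_i·λ) and by score discretization. The
depression-scale (GDS) exclusion rule (> 11) is **not** enforced by
default because the published MCI GDS spread implies such scores existed
in the sample; `enforce_gds_cutoff=True` resamples them instead.

**Rendering.** Each EEG channel is the sum of (i) 1/f-power background
noise synthesized in the frequency domain and normalized to sd 4 µV — a
typical residual level for elderly EEG once band-limited to 0.5–30 Hz;
(ii) a 10 Hz alpha sinusoid of amplitude 2 µV with random phase per
channel; (iii) one Gaussian P300 bump per stimulus, FWHM 120 ms, centered
at the cell's latency with the cell's peak amplitude; and (iv) blink
transients: a ~300 ms biphasic waveform at Poisson rate 8/min, amplitude
150 µV on EOG, propagated to Fz/Cz/Pz with weights 0.30/0.15/0.06
(front-to-back decay). The EOG channel carries blinks plus white noise and
no ERP. An optional 50 Hz sinusoid exercises the notch filter. Recordings
are rendered float32, matching acquisition-hardware precision.

**What the generator does not emulate.** No head-model forward
projection, saccades, electrode drift, channel-specific impedance noise,
non-Gaussian ERP shapes, latency jitter across single trials
(the single-trial latency equals the subject's cell latency), or
habituation. Passing tests therefore demonstrate correctness of the
pipeline's operations and calibration of its statistics under this model,
not performance on real recordings — in particular single-trial latency
jitter in real data widens averaged peaks rather than shifting them, which
this model cannot show.

## Preprocessing chain

Order: 0.1 Hz high-pass (Butterworth order 2, zero-phase) → 50 Hz notch
(second-order IIR, Q = 30, zero-phase) → ICA ocular cleanup → 0.5–30 Hz
band-pass (order 4, zero-phase) → epoch [−200, +800) ms → baseline-correct
on [−200, 0) ms → automatic rejection → random equalization of condition
counts → minimum-20-epochs check. All filters are applied
forward–backward (`sosfiltfilt`), so the effective magnitude order is
doubled and phase is identically zero; a symmetric pulse's peak does not
move, which the tests assert exactly.

**ICA.** Extended Infomax is implemented in-package: symmetric PCA
whitening, natural-gradient updates over seeded-shuffled sample blocks,
per-component sub/super-Gaussian switching by the sign of the activation
kurtosis, learning-rate annealing with halving on divergence.
Non-convergence is a flag on the model, not an exception. The fit runs on
a subsampled (~10 000-sample) copy of the 0.5–30 Hz-filtered data and
includes the EOG channel: with only three EEG channels, the blink needs
its dominant direction (the EOG) inside the decomposition to separate
cleanly from frontal brain activity. Components whose activation
correlates with the EOG at |r| ≥ 0.7 are removed — an automatic,
reproducible proxy for the manual EOG-guided cleanup such studies report.
The implementation is cross-checked against `mne.preprocessing.infomax`
on known source mixtures in the test suite.

**Rejection criteria.** An epoch is rejected if any EEG channel (EOG is
exempt) violates any of: (a) |amplitude| > 70 µV anywhere; (b)
adjacent-sample step > 50 µV/ms (the only well-defined discrete reading of
a µV/ms limit at 2 ms sampling); (c) max−min > 50 µV in any sliding 200 ms
window; (d) max−min < 0.5 µV in any sliding 100 ms window (flatline).
Windows slide over every offset with full support, via O(n) running
max/min filters. Relaxing (a)–(c) and tightening (d) by a common factor
can only retain more epochs (asserted as a property test).

## Peak measurement

Retained epochs are averaged per condition/channel; the P300 peak is the
global maximum of the average in the **closed** window [300, 600] ms
(boundary samples eligible, earliest sample wins ties), giving amplitude
(µV) and latency (ms). A local-peak mode (largest strict local maximum,
falling back to the global maximum) is available behind a flag. Grand
averages weight each subject equally regardless of epoch count.

**Known attenuation.** The 0.5 Hz high-pass removes the sub-0.5 Hz
spectral mass of the P300 template — about 6 % of peak amplitude for the
default 120 ms-FWHM bump (the narrower the template in frequency, the
larger the loss; no physiological template escapes it). Latency is
unaffected (zero phase). The noiseless-recovery tests therefore assert
exact latency (±2 ms) and amplitude within 10 %; with default noise, peak
picking on residual noise adds a small positive amplitude bias that
partially offsets this attenuation.

## Statistics

- **Group tests:** pooled-variance (Student) two-sample t-tests — every
  printed df in the source analyses is n1+n2−2 — available from raw data
  or directly from summary statistics (identical algebra, property-tested);
  Pearson chi-square without continuity correction for the 2×2 sex table.
- **Mixed ANOVA:** univariate SS decomposition (weighted marginal means;
  sequential/Type-I, which coincides with the balanced formulas at equal
  n). Between stratum: group vs subjects-within-group. Within strata:
  condition, AP, condition × AP, each with its ×group interaction, tested
  against the matching effect × subject-within-group error.
  Greenhouse–Geisser epsilon is computed (pooled within-group covariance,
  orthonormal contrasts) and reported for the three-level factor;
  headline rows use uncorrected integer-df p values, as the source
  analyses print. Degenerate inputs (zero error SS) and missing cells are
  hard errors — no imputation. Verified in the tests against an
  independent regression-partition oracle to 1e−8, against a group-label
  permutation null, and for type-I calibration at α = 0.05 over 2 000
  null cohorts; it also matches R's `aov` on toy designs, including
  unequal group sizes.
- **Post-hocs:** four simple effects on electrode-averaged latency —
  paired t (target vs non-target) within each group, pooled independent t
  (HC vs MCI) within each condition — with Bonferroni multiplier 4,
  capped at 1. Both raw and adjusted p are emitted.
- **Correlations:** Pearson r with pairwise deletion; a zero-variance
  variable (e.g. a test every control answers perfectly) yields an
  undefined-result record excluded from FDR, not an exception.
  Benjamini–Hochberg step-up runs within each population × condition
  panel (HC / MCI / whole × target / non-target) across channels ×
  measures × the 10 cognitive tests; the depression screener (GDS) is not
  part of the default battery. Family choice is configurable.

## Determinism and seeds

Every stochastic operation takes a seed. The pipeline derives per-subject
child generators from the master seed by subject index
(`SeedSequence(entropy=seed, spawn_key=(index,))`), so a subject's
recording is bit-identical regardless of cohort size, and a fixed
(config, seed) pair reproduces every output byte-for-byte. The run
manifest records the seed, a config hash, and the full config; re-running
from the manifest reproduces the run.

## Problem sizes used in validation

The test suite validates generator calibration on 2 000-subject latent
draws per group (tolerance 3·sd/√n per cell), ANOVA type-I calibration on
2 000 scaled-down (10 + 10) null cohorts, permutation agreement at 1 000
permutations, and end-to-end recovery on 50 seeded 20 + 20 cohorts run
through the full EEG chain (group-mean latency recovery within ±10 ms,
interaction detection in the majority of cohorts). The acceptance script
reruns the full chain on 5 cohorts and the type-I check on 500 cohorts.

## Known limitations

- Single-trial latency jitter and trial-to-trial amplitude variability are
  not modeled; recovery errors on real data will be larger.
- The ANOVA's unequal-n behavior is sequential (Type I); at the balanced
  designs this package targets, all types coincide.
- The FDR family definition (per population × condition panel) is one
  defensible reading of "FDR-corrected"; other groupings change which
  correlations flag.
- ICA with three EEG channels plus EOG separates blinks well in this
  model but is far below the channel counts used for ICA on real caps.
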