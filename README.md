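# p300kit

A tested, reusable pipeline for visual-oddball **P300** event-related
potential (ERP) analysis in **mild cognitive impairment (MCI)** research.
It reproduces, end to end, the classic clinical workflow: a 120-stimulus
visual oddball session (target probability 0.33, inter-stimulus intervals
3–7 s) recorded at 500 Hz from midline electrodes Fz/Cz/Pz plus EOG;
zero-phase Butterworth filtering, 50 Hz notch, extended-Infomax ICA ocular
cleanup, 1000 ms stimulus-locked epochs with 200 ms baseline, fully
automatic artifact rejection, random target/non-target epoch equalization;
P300 peak amplitude/latency in the 300–600 ms window; and the group
statistics battery — pooled t-tests, chi-square, a 2 × 3 × 2 mixed-design
repeated-measures ANOVA with Bonferroni simple-effect post-hocs, and
FDR-corrected brain–behavior Pearson correlations.

Because raw clinical recordings of this kind are rarely shareable, the
package ships a first-class **synthetic cohort generator** with ground
truth: per-subject latent P300 latency/amplitude factors drawn from
group-level normal distributions calibrated to published HC/MCI summary
cells, neuropsychological test scores coupled to those latents through a
Gaussian-copula one-factor model, 1/f background EEG, alpha activity, and
stereotyped blink artifacts. Every analysis step can therefore be validated
against known truth.

## Who it is for

Researchers and methodologists in clinical neurophysiology who want to

- prototype or teach the standard oddball-P300 analysis chain on realistic
  data with known ground truth,
- stress-test peak-measurement and artifact-rejection choices, or
- run power/calibration experiments for mixed-design ERP studies
  (e.g. MCI vs healthy controls).

## The model in brief

For subject $s$ in group $g$, cell (condition $c$, channel $e$):

$$\mathrm{lat}_{s,ce} = \mu^{g}_{ce} + \sigma^{g}_{ce}\,
  (\lambda Z^{L}_s + \sqrt{1-\lambda^2}\,\varepsilon_{s,ce}),$$

with $Z^L_s$ the subject's latent latency factor, $\lambda$ the cell
loading (default 0.6), and $(\mu^{g}_{ce}, \sigma^{g}_{ce})$ the group
calibration cells; amplitudes follow the same structure with factor
$Z^A_s$. Neuropsychological score $i$ is
$t_i = c_i Z^L + d_i Z^A + \sqrt{1-c_i^2-d_i^2}\,\eta_i$ mapped through the
test's marginal mean/sd with test-specific rounding and caps (a Gaussian
copula), so $(c_i, d_i)$ set the score–ERP couplings directly.

The mixed ANOVA is the univariate sums-of-squares decomposition with
between factor group (HC vs MCI) and within factors condition
(target/non-target) and anterior–posterior electrode (Fz/Cz/Pz); each
within effect and its group interaction is tested against the matching
effect × subject-within-group stratum, with Greenhouse–Geisser epsilons
reported for the three-level factor. Benjamini–Hochberg FDR is applied
within each population × condition correlation panel.

## Worked example

```python
from p300kit import pipeline

cfg = pipeline.RunConfig(seed=1, output_dir="", write_raw=False,
                         write_epochs=False)
result = pipeline.run_pipeline(cfg)

anova = result.reports["anova_latency"].set_index("effect")
row = anova.loc["condition x group"]
print(f"subjects analyzed : {result.manifest['n_subjects_analyzed']}")
print(f"condition x group : F({row['df1']:.0f},{row['df2']:.0f}) "
      f"= {row['F']:.3f}, p = {row['p']:.4f}")
```

prints (seed 1, default 20 + 20 cohort):

```
subjects analyzed : 36
condition x group : F(1,34) = 11.237, p = 0.0020
```

Four simulated subjects were excluded by the behavioral 10 % count-accuracy
rule, mirroring the study's inclusion criterion, hence the error df of 34.
The significant condition × group interaction is the analysis's headline
phenomenon: the recovered electrode-averaged latencies
(HC 413.2 ms target vs 428.6 ms non-target; MCI 450.4 ms target vs
425.5 ms non-target) show that target processing is *faster* than
non-target in controls but *slower* in MCI — exactly the crossover
injected by the calibrated generator. The simple-effect post-hocs localize
it (HC vs MCI within target: t = −2.96, Bonferroni p = 0.022).

The same run is available from the shell:

```bash
p300kit run --seed 1 --out out_dir        # full bundle with TSV reports
p300kit simulate --seed 1 --out sim_dir   # BrainVision triplets + cohort
p300kit preprocess --in sim_dir/raw/HC000.vhdr --out HC000.npz
p300kit measure --in HC000.npz --out peaks.tsv
p300kit stats --peaks peaks.tsv --cohort sim_dir/cohort.tsv --out reports
```

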