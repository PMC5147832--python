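# smokewas

Cell-type-resolved epigenome-wide association analysis of cigarette smoking.

Smoking leaves strong, reproducible DNA-methylation marks in blood, but
whole-blood measurements mix six-plus leukocyte lineages whose responses
differ: AHRR-like CpGs react in granulocytes, monocytes and B cells while T
cells are spared; GPR15-like CpGs react only in lymphocytes; some CpGs react
in a single cell type and are invisible in whole blood. `smokewas` implements
the analysis toolkit for this problem, for methylation-array analysts working
with beta-value matrices and smoking-exposure covariates:

- **Robust EWAS** — per-CpG association between M-values
  (`M = log2(β/(1−β))`) and a smoking exposure (current status, pack-years,
  years smoked), fitted by Huber M-estimation (tuning constant 1.345, IRLS,
  MAD scale) with adjustment for age, sex, race and leukocyte composition;
  two-sided t(n−p) p-values, Bonferroni family-wise threshold
  `α / n_tested`, and per-CpG smoker-minus-nonsmoker delta-beta with Welch
  t-tests.
- **Reference-based deconvolution** — leukocyte fractions estimated by
  constrained projection `min‖β − R·w‖²` subject to `w ≥ 0, Σw = 1` onto a
  reference panel restricted to lineage-discriminating probes; solved
  exactly by face enumeration over the simplex.
- **Duration rank-change screen** — within the top-K any-smoking CpGs,
  smokers are split at a cigarettes/day cutoff (default 22), years-smoked
  association is refitted per stratum, and CpGs are ranked by the change in
  p-value rank between light and heavy smokers.
- **Cell-type effect profiling** — per-cell-type delta/p profiles for
  candidate CpGs, hierarchical clustering by effect size or significance
  pattern, rule-based lineage-pattern labels (pan-cell, myeloid,
  myeloid+B, lymphoid, T-only, monocyte-only), explicit mixture
  back-projection `Δβ_wb = Σ_c w_c^S β_c^S − Σ_c w_c^N β_c^N`, cotinine
  regressions, and ΔΔCt qPCR fold changes (`FC = 2^(−ΔΔCt)`).
- **Synthetic cohorts with planted truth** — a first-class generator that
  emulates a 450K-style study (default 81 never / 172 current smokers;
  sorted-cell study 14/20) with lineage-specific effects on the logit
  scale, heavy-smoker duration effects, smoker composition shifts, and PBMC
  granulocyte depletion, for power/calibration studies and validation.

Estimators follow scikit-learn conventions (`fit`/`transform`,
`get_params`, trailing-underscore fitted attributes); module-level
functions wrap them for one-call use.

## Worked example

Run the full pipeline on a synthetic cohort (simulate → deconvolve → EWAS →
duration screen → cell-type profiles):

```bash
smokewas run-all --seed 7 --outdir demo
```

or equivalently from Python:

```python
from smokewas.cli import load_config, run_end_to_end
config = load_config(None, seed=7, outdir="demo")
config["cohort"].update({"n_probes": 1000, "n_discriminating": 20})
config["duration"]["top_k"] = 500
run_end_to_end(config)
```

`demo/report.txt` then reads (actual output):

```
n_subjects = 253
n_probes = 1000
n_planted = 40
deconvolution_probes = 120
probes_tested = 1000
bonferroni_threshold = 5e-05
n_significant = 35
recovered_T_only = 5/5
recovered_duration_heavy = 5/5
recovered_lymphoid = 10/10
recovered_monocyte_only = 0/5
recovered_myeloid_plus_B = 10/10
recovered_pan_cell = 5/5
duration_cutoff = 22.0
duration_strata = 86/86
```

Reading the numbers: 253 subjects (81 never / 172 current smokers) were
simulated at 1000 CpGs with 40 planted effects. Deconvolution selected 120
lineage-discriminating probes and estimated each subject's leukocyte
fractions; the EWAS on M-values, adjusted for age, sex, race and the
estimated composition, tested 1000 CpGs at the Bonferroni threshold
0.05/1000 = 5×10⁻⁵ and called 35 significant. Effects planted in broad
lineages (myeloid+B, lymphoid, pan-cell) are recovered completely, while
monocyte-restricted effects (monocytes are ~8% of whole blood, so the
whole-blood delta is attenuated ~12-fold) are missed entirely — the
cell-restricted signals whole-blood EWAS cannot see, which is why the
sorted-cell profiling exists. The duration screen split the 172 smokers
into 86 light / 86 heavy at 22 cigarettes/day.

Per-stage outputs (`ewas_results.tsv`, `estimated_compositions.csv`,
`duration_rank.tsv`, `celltype_profiles.tsv`, `profile_clusters.nwk`) are
plain text with run metadata headers.

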