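# Methods

## Scales and transforms

Methylation is measured as beta values (fraction methylated, in [0, 1]) and
modelled on the M-value scale, `M = log2(β/(1−β))`, which stabilises
variance near the boundaries. Betas are clipped to `[ε, 1−ε]` before the
transform; the default `ε = 1e-6` keeps boundary betas finite (M ≈ ±19.93)
without affecting interior values. `m_to_beta` inverts the transform
exactly (round trip ≤ 1e-12 inside the clip bounds). Out-of-range betas are
treated as data errors and rejected with the offending probe and sample
named; missing betas propagate and are dropped per probe in model fits.

Probe coordinates are stored 1-based (array-manifest convention); the BED
export converts to 0-based half-open. Probes flagged for SNP overlap are
removed before analysis; probes absent from the annotation are retained
with a warning rather than silently dropped, since an incomplete manifest
should not shrink the analysis.

## Robust EWAS

Each probe's M-values are regressed on the exposure (current-vs-never
indicator, pack-years, or years smoked) plus covariates by Huber
M-estimation fitted with iteratively reweighted least squares:

- tuning constant c = 1.345 (95% efficiency at the Gaussian);
- residual scale re-estimated each iteration as the normalized median
  absolute deviation, `median(|r|)/Φ⁻¹(3/4)`;
- at most 50 iterations, convergence when the maximum coefficient change
  falls below 1e-8;
- standard errors from Huber's large-sample covariance with the
  small-sample correction factor (the "H1" form used by standard robust
  regression software); the implementation is cross-checked against
  statsmodels RLM in the test suite to ~1e-7;
- two-sided p-values from the t distribution with n − p degrees of freedom.

With the scale held fixed, IRLS is a majorize-minimise scheme and the Huber
objective is non-increasing; the per-iteration objective history is exposed
and tested under that regime. When the scale collapses to zero (an exact
fit) the estimate reduces to least squares on the support and inference is
degenerate by construction.

Categorical covariates are one-hot encoded with the first level as the
reference. Composition covariates live on the simplex, so the largest-mean
cell type is dropped (logged) to keep the design full rank; rank deficiency
anywhere else is an error naming the collinear columns. The family-wise
threshold is Bonferroni `α / n_tested` with `n_tested` the probes actually
fitted after filtering — the threshold is computed per run and recorded in
the output metadata rather than hard-coded, since the published genome-wide
cutoff depends on an unstated post-filter probe count.

Group delta-beta is the smoker-minus-nonsmoker mean beta with Welch's
unequal-variance t-test. Degenerate probes where both groups are constant
carry either no evidence (identical constants: p = 1, t = 0) or infinite
evidence (distinct constants: p = 0); this rule matters for noiseless
synthetic data.

## Reference-based deconvolution

Leukocyte fractions are estimated by projecting a sample's betas at
lineage-discriminating probes onto the reference panel under simplex
constraints:

    minimise ‖β − R·w‖²  subject to  w ≥ 0, Σw = 1.

Probe selection ranks probes per cell type by the gap between that type's
baseline and the mean of the others and keeps the top `k_per_type` in each
direction (hyper- and hypomethylated; default 50 each, 25 in the pipeline
defaults), ties broken by probe id. The QP is solved exactly by enumerating
the faces of the simplex: the optimum of a convex quadratic over the simplex
lies on some face and solves that face's equality-constrained least-squares
problem (a (k+1)×(k+1) KKT system), so taking the feasible minimum over all
2^C − 1 faces is exhaustive and exact to linear-algebra precision. This is
practical for blood panels (C ≤ ~12 cell types) and removes any dependence
on iteration schedules or convergence tolerances; the test suite verifies
it against a 0.005-step brute-force grid search on 3-type instances. An
option relaxes the constraint to Σw ≤ 1 (implemented by a zero reference
column) for samples containing cell types absent from the panel. Identical
reference columns are rejected naming the collinear cell types; missing
betas at selected probes are imputed as the panel row mean with a logged
count.

## Duration rank-change screen

The screen asks which CpGs track *years of smoking* in heavy smokers
specifically. From the top-K CpGs of the any-smoking EWAS (default
K = 1000), current smokers are split at a cigarettes/day cutoff (default
22, heavy = at/above; `None` uses the smoker median); the years-smoked
association is refitted within each stratum with the same covariate set
(composition covariates retained by default, a flag drops them); CpGs are
ranked by p within stratum with ties broken by probe id; and the signed
rank change `rank_light − rank_heavy` is reported, largest first, with the
absolute value alongside so either ordering is recoverable.

The screen's discriminative power comes from the candidate set: top
smoking-associated CpGs carry duration trends shared by both strata, so
their ranks correlate across strata and their rank changes concentrate near
zero, letting a heavy-only CpG (top rank in heavy, bottom ranks in light)
stand out. Against a background of duration-*null* probes the two strata's
ranks are independent uniform permutations, null rank changes follow a wide
triangular distribution, and no procedure based on rank differences can
reliably place a single planted probe first — the validation suite measures
both regimes (the dose-graded background recovers the planted probe in the
top 5 in ~100% of replicates; the pure-null background in ~2%, as the
order-statistics argument predicts).

## Cell-type profiling

Per-probe, per-cell-type smoker-minus-nonsmoker delta-beta and Welch p are
assembled into profiles, with whole-blood/PBMC mixtures as extra columns.
Profiles are clustered by agglomerative hierarchical clustering (default
Euclidean distance, average linkage — the common heatmap defaults; both
configurable, signed delta by default with an absolute-value option, or
−log10 p). Rows are sorted by probe id before linkage so the tree and flat
labels are invariant to input row order; the tree is exported as Newick.

Lineage response patterns are labelled from the significance indicator
vector across sorted cell types (per-test α = 0.05, unadjusted — matching
per-CpG starring in small sorted-cell studies). Rules are applied most
specific first: pan_cell (all types), myeloid (CD14 ∧ CD15, no lymphoid),
myeloid_plus_B (myeloid + B, T spared — the AHRR-like pattern), T_only
(the ITGAL-like pattern), monocyte_only (MYO1G-like), lymphoid (only
lymphoid types — the GPR15-like pattern), none. Checking T_only before
the broader lymphoid rule keeps every label reachable; a nominal
priority ordering with lymphoid first would shadow T_only entirely.

Whole-blood back-projection uses the mixture identity

    Δβ_wb = Σ_c w_c^smoker · β̄_c^smoker − Σ_c w_c^never · β̄_c^never,

which reduces to `Σ_c w_c Δβ_c` at equal compositions and makes the
attenuation of lineage-restricted effects explicit (a monocyte-only effect
is diluted by the ~8% monocyte fraction). For noiseless synthetic data the
identity is exact because the mixture is a convex combination and group
means commute with it; this is tested to 1e-12.

Cotinine regressions are ordinary least squares of beta on log2 cotinine
(detection floor 0.1 ng/mL before the log; raw-scale option). qPCR fold
changes use ΔΔCt: `ΔCt = Ct_target − Ct_reference`, ΔΔCt relative to the
never-smoker mean ΔCt per cell type and gene, `FC = 2^(−ΔΔCt)`; fold
changes are invariant to shifting both cycle thresholds of a sample.

## Synthetic cohort generator

The generator emulates a 450K-style smoking study and is the package's
validation substrate. All randomness derives from one seed fanned out to
per-stage substreams.

**Subjects.** Defaults mirror a whole-blood study of 81 never / 172 current
smokers (sorted-cell study: 14/20). Cigarettes/day straddles the heavy
cutoff (22/day) with a configurable heavy fraction (default 0.5, giving
86/86 strata); years smoked is truncated normal (mean 17.3, sd 8.6, range
2–42); pack-years is exactly `(cpd/20) × years`; cotinine scales ~8 ng/mL
per cigarette/day with lognormal scatter (≈225 ng/mL at 28/day) and is
near zero in never-smokers.

**Reference panel.** Each cell type gets `n_discriminating` signature
probes (baseline ~0.9 in that type, ~0.1 elsewhere, alternating
direction); remaining probes share a bimodal baseline (low/high Beta
mixture). `celltype_sd` adds per-type logit jitter to shared probes
(default 0, i.e. shared probes are identical across types and hence immune
to composition shifts; the confounding experiments use 1.0 logit, the
regime of lineage-variable CpGs where composition confounding acts).

**Effects.** Planted on the logit scale per lineage class. Default sizes:
myeloid/myeloid+B −1.5 logits (≈ −24% beta at a high baseline, the
AHRR-like magnitude), lymphoid −0.6 (≈ −11%, GPR15-like), pan-cell −1.0,
T-only −0.8, monocyte-only +0.8; duration_heavy probes carry −0.05
logit/year applied only to smokers at/above the heavy cutoff; dose_graded
probes carry a per-probe slope shared by all smokers (|slope| ~
U(0.005, 0.02) logit/yr, 70% negative), sized so light-stratum associations
are nominally significant at sorted-cell sample sizes — these emulate the
top smoking-associated CpGs the duration screen operates on. Planting
prefers probes with mean baseline in [0.4, 0.9], where a logit shift yields
the double-digit beta deltas seen at smoking loci; if that pool is too
small the full shared set is used (logged).

**Noise and mixing.** Per-cell-type betas are
`inverse-logit(logit(baseline) + effects + N(0, noise_sd))` with default
noise_sd 0.35 logits, independent across probes and cell types — noise on
the logit scale keeps betas strictly inside (0,1) and is naturally
heteroskedastic on the beta scale. Whole blood is the exact convex
combination of the cell-type matrices under per-subject Dirichlet
compositions (concentration 40, giving within-group granulocyte sd ≈ 8
percentage points). Group means differ by the measured CBC shifts of
smokers (+6% granulocytes, −5.4% lymphocytes, −0.7% monocytes). PBMC
mixtures multiply granulocyte weights by a retention factor (default 0.05)
and renormalise.

**What the generator does not model:** probe-type chemistry bias, batch
effects, mQTL/genetic variation, age-related methylation drift, spatial
correlation between neighbouring CpGs, and cross-subject correlation
structure. Passing validation therefore demonstrates the estimators'
statistical behaviour under the stated mixture-and-noise model, not
robustness to array artefacts — normalisation and batch correction are
assumed done upstream.

## Validation experiment sizes

The validation suite (`smokewas.validation`, exercised by the test suite
and `scripts/acceptance.py`) uses: 100 six-type mixtures for composition
recovery and 20 three-type instances against a 0.005-step grid oracle;
2000 null probes at n = 250 for type-I error and KS uniformity; 1000
lineage-variable probes for the confounding comparison; 400 probes for the
noiseless conservation identity; 50 replicates × 1000 probes × 253
subjects for the duration screen (both backgrounds); 20 replicates of the
14/20 sorted-cell study for cluster recovery. These sizes give binomial
standard errors of ~0.5 percentage points on the calibration rates while
keeping a full validation run in single-digit minutes on one CPU.

## Pipeline

The `smokewas` CLI orchestrates simulate → deconvolve → EWAS → duration →
profiles with a YAML config overridable by flags, per-stage stderr logging
and timing, and a run report (plain text plus a key/value sidecar). Output
files carry metadata headers (package version, seed, hash of the
analysis-relevant config), and a fixed config + seed reproduces numeric
outputs byte-identically. A stage failure aborts the run naming the stage;
the report records what completed.
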