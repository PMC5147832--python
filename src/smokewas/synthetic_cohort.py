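"""Synthetic 450K-style cohort generator with planted smoking effects.

Emulates a whole-blood smoking methylation study: a reference panel of
per-cell-type mean methylomes, subject covariates (smoking status,
cigarettes/day, years smoked, pack-years, serum cotinine, age, sex, race),
lineage-specific smoking effects planted on the logit (M-value) scale,
per-cell-type beta matrices with logit-normal noise, and whole-blood / PBMC
mixtures formed as exact convex combinations of the cell-type matrices with
a smoker-shifted leukocyte composition.

All randomness flows from a single seed fanned out to per-stage substreams
(`numpy.random.SeedSequence.spawn`), so each stage is independently
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import validate_sample_sheet

logger = logging.getLogger(__name__)

DEFAULT_CELL_TYPES = ("CD14", "CD15", "CD19", "CD4T", "CD8T", "CD56")

#: leukocyte lineage roles used for planted-effect classes and for pattern
#: classification; CD2 is the pan-T marker used in sorted-cell studies
MYELOID_TYPES = frozenset({"CD14", "CD15", "Mono", "Neu", "Eos", "Gran"})
GRANULOCYTE_TYPES = frozenset({"CD15", "Neu", "Eos", "Gran"})
B_TYPES = frozenset({"CD19", "Bcell"})
T_TYPES = frozenset({"CD2", "CD4T", "CD8T"})
NK_TYPES = frozenset({"CD56", "NK"})

#: effect classes -> cell types carrying the static smoking effect
EFFECT_CLASS_MEMBERS = {
    "pan_cell": lambda ct: True,
    "myeloid": lambda ct: ct in MYELOID_TYPES,
    "myeloid_plus_B": lambda ct: ct in MYELOID_TYPES or ct in B_TYPES,
    "lymphoid": lambda ct: ct in B_TYPES or ct in T_TYPES or ct in NK_TYPES,
    "T_only": lambda ct: ct in T_TYPES,
    "monocyte_only": lambda ct: ct in {"CD14", "Mono"},
    "duration_heavy": lambda ct: True,
    "dose_graded": lambda ct: True,
    "null": lambda ct: False,
}

#: default static effect sizes (logit units).  The myeloid-plus-B class is
#: modelled on the AHRR-like response (~ -24% beta at a high baseline); the
#: lymphoid class on the GPR15-like response (~ -11% beta).
DEFAULT_EFFECT_SIZES = {
    "pan_cell": -1.0,
    "myeloid": -1.5,
    "myeloid_plus_B": -1.5,
    "lymphoid": -0.6,
    "T_only": -0.8,
    "monocyte_only": 0.8,
    "duration_heavy": 0.0,
    "dose_graded": 0.0,
    "null": 0.0,
}

DEFAULT_DURATION_SLOPE = -0.05  # logit units per year of smoking, heavy only

#: |slope| range (logit/year, all smokers) for the dose_graded class, which
#: emulates top smoking-associated CpGs with modest shared duration trends
#: (nominal significance at sorted-cell study sizes); sign is mostly negative
#: (smoking predominantly hypomethylates)
DOSE_GRADED_SLOPE_RANGE = (0.005, 0.02)
DOSE_GRADED_NEG_FRACTION = 0.7
DEFAULT_HEAVY_CUTOFF = 22      # cigarettes/day; >= cutoff is "heavy"

#: group mean leukocyte fractions (never / current): smokers gain ~6%
#: granulocytes at the expense of lymphocytes (~-5%) and monocytes (~-1%),
#: the magnitude of smoking-associated CBC shifts in whole blood
NEVER_COMPOSITION = {"CD14": 0.080, "CD15": 0.510, "CD19": 0.080,
                     "CD4T": 0.220, "CD8T": 0.080, "CD56": 0.030}
SMOKER_COMPOSITION = {"CD14": 0.073, "CD15": 0.571, "CD19": 0.075,
                      "CD4T": 0.195, "CD8T": 0.062, "CD56": 0.024}

LOGIT_BOUND = 35.0  # keeps expit strictly inside (0, 1) in float64


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    x = np.clip(x, -LOGIT_BOUND, LOGIT_BOUND)
    return 1.0 / (1.0 + np.exp(-x))


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class ReferencePanel:
    """Per-cell-type mean methylomes.

    Attributes
    ----------
    baseline : DataFrame
        probes x cell types, mean beta in [0, 1].
    discriminating : Series
        probe -> cell type whose signature the probe carries, or "" for
        shared-baseline probes.
    """
    baseline: pd.DataFrame
    discriminating: pd.Series = field(default=None)

    def __post_init__(self):
        if self.discriminating is None:
            self.discriminating = pd.Series("", index=self.baseline.index)

    @property
    def probe_ids(self):
        return self.baseline.index

    @property
    def cell_types(self):
        return list(self.baseline.columns)

    @property
    def has_discriminating(self) -> bool:
        return bool((self.discriminating != "").any())


# ---------------------------------------------------------------------------
# subjects
# ---------------------------------------------------------------------------

def generate_subjects(n_never: int, n_current: int, heavy_fraction: float = 0.5,
                      cpd_cutoff: int = DEFAULT_HEAVY_CUTOFF,
                      seed: int = 0) -> pd.DataFrame:
    """Simulate a sample sheet of never and current smokers.

    Cigarettes/day for current smokers straddles ``cpd_cutoff``: a
    ``heavy_fraction`` of smokers draw at/above the cutoff, the rest below
    (light smokers 10..cutoff-1, heavy cutoff..60).  Years smoked follows a
    truncated normal (mean 17, sd 9, range 2-42); pack-years is exactly
    ``(cpd/20) * years``.  Serum cotinine scales with cigarettes/day
    (about 8 ng/mL per cigarette/day with lognormal scatter) and is near
    zero for never-smokers.
    """
    if n_never < 0 or n_current < 0:
        raise ValueError("subject counts must be non-negative")
    if not 0.0 <= heavy_fraction <= 1.0:
        raise ValueError("heavy_fraction must be in [0, 1]")
    rng_cpd, rng_years, rng_cot, rng_demo = _spawn(seed, 4)

    n = n_never + n_current
    status = np.array(["never"] * n_never + ["current"] * n_current)

    n_heavy = int(round(heavy_fraction * n_current))
    cpd = np.zeros(n)
    light = rng_cpd.integers(10, cpd_cutoff, size=n_current - n_heavy)
    heavy = rng_cpd.integers(cpd_cutoff, 61, size=n_heavy)
    smoker_cpd = np.concatenate([light, heavy]).astype(float)
    rng_cpd.shuffle(smoker_cpd)
    cpd[n_never:] = smoker_cpd

    years = np.zeros(n)
    draws = rng_years.normal(17.3, 8.6, size=n_current)
    years[n_never:] = np.clip(np.round(draws, 1), 2.0, 42.0)

    pack_years = cpd / 20.0 * years

    cotinine = np.abs(rng_cot.normal(2.0, 1.5, size=n))
    smoker_cot = cpd[n_never:] * 8.0 * np.exp(rng_cot.normal(0.0, 0.4, size=n_current))
    cotinine[n_never:] = smoker_cot

    age = np.clip(np.round(rng_demo.normal(34.0, 9.0, size=n)), 19, 65)
    sex = rng_demo.choice(["male", "female"], size=n, p=[0.6, 0.4])
    race = rng_demo.choice(["white", "black"], size=n, p=[0.7, 0.3])

    sheet = pd.DataFrame({
        "sample_id": [f"S{i + 1:04d}" for i in range(n)],
        "smoking_status": status,
        "cigarettes_per_day": cpd,
        "years_smoked": years,
        "pack_years": pack_years,
        "cotinine": np.round(cotinine, 2),
        "age": age,
        "sex": sex,
        "race": race,
    }).set_index("sample_id", drop=False)
    return validate_sample_sheet(sheet)


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

def generate_reference_panel(n_probes: int,
                             cell_types=DEFAULT_CELL_TYPES,
                             n_discriminating: int = 60,
                             celltype_sd: float = 0.0,
                             seed: int = 0) -> ReferencePanel:
    """Simulate per-cell-type mean methylomes.

    For each cell type, ``n_discriminating`` probes are given a signature:
    baseline near one pole (0.9) in that cell type and near the other (0.1)
    in all others, alternating hyper/hypo direction.  Remaining probes share
    a common baseline drawn from a bimodal distribution (mixture of low and
    high Beta components, the typical CpG methylation landscape).

    ``celltype_sd`` adds independent per-cell-type logit jitter to the shared
    probes, modelling the modest between-lineage baseline differences of real
    methylomes (default 0: shared probes are identical across cell types).
    """
    cell_types = list(cell_types)
    n_disc_total = n_discriminating * len(cell_types)
    if n_probes < n_disc_total:
        raise ValueError(
            f"need at least {n_disc_total} probes for "
            f"{n_discriminating} discriminating probes per cell type; got {n_probes}")
    rng, = _spawn(seed, 1)

    probe_ids = pd.Index([f"cg{i + 1:08d}" for i in range(n_probes)], name="probe_id")
    baseline = np.empty((n_probes, len(cell_types)))
    discriminating = pd.Series("", index=probe_ids)

    # shared bimodal background
    n_shared = n_probes - n_disc_total
    low = rng.beta(2.0, 10.0, size=n_shared)
    high = rng.beta(10.0, 2.0, size=n_shared)
    pick_high = rng.random(n_shared) < 0.5
    shared = np.where(pick_high, high, low)
    shared = np.clip(shared, 0.02, 0.98)
    baseline[:n_shared, :] = shared[:, None]
    if celltype_sd > 0:
        jitter = rng.normal(0.0, celltype_sd, size=(n_shared, len(cell_types)))
        baseline[:n_shared, :] = _expit(_logit(baseline[:n_shared, :]) + jitter)

    # lineage signatures
    row = n_shared
    for j, ct in enumerate(cell_types):
        for k in range(n_discriminating):
            hyper = k % 2 == 0  # alternate direction: hyper then hypo in ct
            own = rng.uniform(0.88, 0.95) if hyper else rng.uniform(0.05, 0.12)
            other = rng.uniform(0.05, 0.12) if hyper else rng.uniform(0.88, 0.95)
            baseline[row, :] = other
            baseline[row, j] = own
            discriminating.iloc[row] = ct
            row += 1

    panel = ReferencePanel(
        baseline=pd.DataFrame(baseline, index=probe_ids, columns=cell_types),
        discriminating=discriminating,
    )
    return panel


# ---------------------------------------------------------------------------
# planted effects
# ---------------------------------------------------------------------------

def make_effect_truth(panel: ReferencePanel,
                      class_counts: dict[str, int],
                      effect_sizes: dict[str, float] | None = None,
                      duration_slope: float = DEFAULT_DURATION_SLOPE,
                      baseline_range: tuple[float, float] | None = (0.4, 0.9),
                      seed: int = 0) -> pd.DataFrame:
    """Assign effect classes to probes and emit the planted-truth table.

    Probes are drawn without replacement from the panel's shared
    (non-discriminating) probes so planted effects never corrupt the
    deconvolution signature set.  Planting prefers probes with mean baseline
    inside ``baseline_range`` (smoking-responsive CpGs typically sit at
    intermediate-to-high methylation, where a logit shift produces the
    double-digit beta differences seen at loci like AHRR); if that pool is
    too small the full shared set is used.  Unassigned shared probes are
    null.

    Returns a DataFrame indexed by probe_id with columns ``effect_class``,
    one ``effect_<cell type>`` column per cell type (logit units) and
    ``duration_slope`` (logit units per year, nonzero only for
    ``duration_heavy``).
    """
    sizes = dict(DEFAULT_EFFECT_SIZES)
    if effect_sizes:
        sizes.update(effect_sizes)
    unknown = set(class_counts) - set(EFFECT_CLASS_MEMBERS)
    if unknown:
        raise ValueError(f"unknown effect classes: {sorted(unknown)}")
    rng, = _spawn(seed, 1)

    pool = panel.probe_ids[panel.discriminating == ""]
    n_wanted = sum(class_counts.values())
    if n_wanted > len(pool):
        raise ValueError(f"requested {n_wanted} effect probes but only "
                         f"{len(pool)} shared probes available")
    if baseline_range is not None:
        lo, hi = baseline_range
        mean_base = panel.baseline.loc[pool].mean(axis=1)
        in_range = pool[(mean_base >= lo) & (mean_base <= hi)]
        if len(in_range) >= n_wanted:
            pool = in_range
        else:
            logger.warning("only %d shared probes in baseline range %s for "
                           "%d planted effects; using all shared probes",
                           len(in_range), baseline_range, n_wanted)
    chosen = rng.choice(pool, size=n_wanted, replace=False)

    truth = pd.DataFrame({"effect_class": "null"}, index=panel.probe_ids)
    for ct in panel.cell_types:
        truth[f"effect_{ct}"] = 0.0
    truth["duration_slope"] = 0.0
    truth["duration_slope_all"] = 0.0

    pos = 0
    for cls, count in class_counts.items():
        probes = chosen[pos:pos + count]
        pos += count
        truth.loc[probes, "effect_class"] = cls
        member = EFFECT_CLASS_MEMBERS[cls]
        for ct in panel.cell_types:
            if member(ct):
                truth.loc[probes, f"effect_{ct}"] = sizes[cls]
        if cls == "duration_heavy":
            truth.loc[probes, "duration_slope"] = duration_slope
        elif cls == "dose_graded":
            # shared modest per-probe duration trend across all smokers
            lo, hi = DOSE_GRADED_SLOPE_RANGE
            mag = rng.uniform(lo, hi, size=count)
            sign = np.where(rng.random(count) < DOSE_GRADED_NEG_FRACTION,
                            -1.0, 1.0)
            truth.loc[probes, "duration_slope_all"] = mag * sign
    return truth


# ---------------------------------------------------------------------------
# per-cell-type betas
# ---------------------------------------------------------------------------

def synthesize_celltype_betas(panel: ReferencePanel, sheet: pd.DataFrame,
                              truth: pd.DataFrame, noise_sd: float = 0.35,
                              heavy_cutoff: float = DEFAULT_HEAVY_CUTOFF,
                              seed: int = 0) -> dict[str, pd.DataFrame]:
    """Simulate a beta matrix (probes x subjects) per cell type.

    For subject *s* and cell type *c*::

        logit(beta) = logit(baseline_c) + smoker_s * effect_c
                      + (heavy_s ? duration_slope * years_s : 0)
                      + Normal(0, noise_sd)

    Smoking effects and noise live on the logit scale so betas stay strictly
    inside (0, 1) and noise is naturally heteroskedastic on the beta scale.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    effect_cols = [c.removeprefix("effect_") for c in truth.columns
                   if c.startswith("effect_") and c != "effect_class"]
    unknown = set(effect_cols) - set(panel.cell_types)
    if unknown:
        raise ValueError(f"truth references unknown cell types: {sorted(unknown)}")

    rngs = _spawn(seed, len(panel.cell_types))
    truth = truth.reindex(panel.probe_ids).fillna(
        {"duration_slope": 0.0, "duration_slope_all": 0.0,
         "effect_class": "null"})
    if "duration_slope_all" not in truth.columns:
        truth = truth.assign(duration_slope_all=0.0)

    smoker = (sheet["smoking_status"] == "current").to_numpy(dtype=float)
    heavy = smoker * (sheet["cigarettes_per_day"].to_numpy() >= heavy_cutoff)
    years = sheet["years_smoked"].to_numpy(dtype=float)

    matrices = {}
    for ct, rng in zip(panel.cell_types, rngs):
        base_logit = _logit(panel.baseline[ct].to_numpy())[:, None]
        eff = truth.get(f"effect_{ct}", pd.Series(0.0, index=panel.probe_ids))
        eff = eff.to_numpy()[:, None]
        slope = truth["duration_slope"].to_numpy()[:, None]
        slope_all = truth["duration_slope_all"].to_numpy()[:, None]
        logits = (base_logit
                  + eff * smoker[None, :]
                  + slope * (heavy * years)[None, :]
                  + slope_all * (smoker * years)[None, :])
        if noise_sd > 0:
            logits = logits + rng.normal(0.0, noise_sd,
                                         size=(len(panel.probe_ids), len(sheet)))
        matrices[ct] = pd.DataFrame(_expit(logits), index=panel.probe_ids,
                                    columns=sheet["sample_id"])
    return matrices


# ---------------------------------------------------------------------------
# composition and mixing
# ---------------------------------------------------------------------------

def generate_compositions(sheet: pd.DataFrame,
                          never_mean: dict[str, float] | None = None,
                          smoker_mean: dict[str, float] | None = None,
                          concentration: float = 40.0,
                          pbmc_retention: float = 0.05,
                          seed: int = 0) -> pd.DataFrame:
    """Draw per-subject leukocyte fractions from group-specific Dirichlets.

    Smoker and never-smoker groups have different mean compositions
    (smokers: more granulocytes, fewer T cells); ``concentration`` controls
    the within-group spread.  ``pbmc_depletion`` is the granulocyte retention
    factor applied when synthesising a PBMC mixture.
    """
    never_mean = never_mean or NEVER_COMPOSITION
    smoker_mean = smoker_mean or SMOKER_COMPOSITION
    cell_types = list(never_mean)
    rng, = _spawn(seed, 1)

    rows = np.empty((len(sheet), len(cell_types)))
    for i, (_, subj) in enumerate(sheet.iterrows()):
        mean = smoker_mean if subj["smoking_status"] == "current" else never_mean
        alpha = np.array([mean[ct] for ct in cell_types]) * concentration
        rows[i] = rng.dirichlet(alpha)
    comp = pd.DataFrame(rows, index=sheet["sample_id"], columns=cell_types)
    comp["pbmc_depletion"] = pbmc_retention
    return comp


def mix_to_whole_blood(celltype_matrices: dict[str, pd.DataFrame],
                       compositions: pd.DataFrame,
                       pbmc: bool = False,
                       granulocyte_types=("CD15",)) -> pd.DataFrame:
    """Form a mixed (whole-blood or PBMC) beta matrix.

    Per probe and sample the mixture is the exact convex combination
    ``sum_c w_c * beta_c``.  For a PBMC mixture the granulocyte weights are
    multiplied by each sample's retention factor and the weights renormalised
    before mixing (PBMC preparation largely removes granulocytes).
    """
    cell_types = [c for c in compositions.columns if c != "pbmc_depletion"]
    missing = set(cell_types) - set(celltype_matrices)
    if missing:
        raise ValueError(f"no beta matrix for cell types: {sorted(missing)}")
    ref = celltype_matrices[cell_types[0]]
    for ct in cell_types[1:]:
        if not celltype_matrices[ct].index.equals(ref.index):
            diff = ref.index.symmetric_difference(celltype_matrices[ct].index)
            raise ValueError(
                f"probe sets differ between {cell_types[0]} and {ct}: "
                f"{list(diff[:5])}{'...' if len(diff) > 5 else ''}")

    samples = ref.columns
    aligned = compositions.reindex(samples)
    if aligned[cell_types].isna().any().any():
        missing_s = aligned.index[aligned[cell_types].isna().any(axis=1)]
        raise ValueError(f"no composition for samples: {list(missing_s[:5])}")
    weights = aligned[cell_types].to_numpy(dtype=float).copy()
    if pbmc:
        retention = aligned["pbmc_depletion"].to_numpy(dtype=float)
        for g in granulocyte_types:
            if g in cell_types:
                weights[:, cell_types.index(g)] *= retention
        weights /= weights.sum(axis=1, keepdims=True)

    mixed = np.zeros((len(ref.index), len(samples)))
    for j, ct in enumerate(cell_types):
        mixed += celltype_matrices[ct].reindex(columns=samples).to_numpy() * weights[:, j]
    return pd.DataFrame(mixed, index=ref.index, columns=samples)


# ---------------------------------------------------------------------------
# one-call cohort
# ---------------------------------------------------------------------------

def simulate_cohort(n_never: int = 81, n_current: int = 172,
                    n_probes: int = 2000,
                    class_counts: dict[str, int] | None = None,
                    cell_types=DEFAULT_CELL_TYPES,
                    n_discriminating: int = 60,
                    celltype_sd: float = 0.0,
                    noise_sd: float = 0.35,
                    heavy_cutoff: float = DEFAULT_HEAVY_CUTOFF,
                    heavy_fraction: float = 0.5,
                    concentration: float = 40.0,
                    pbmc_retention: float = 0.05,
                    seed: int = 0) -> dict:
    """Generate a full synthetic study: sheet, panel, truth, cell-type betas,
    compositions and whole-blood/PBMC mixtures.

    Default cohort sizes mirror a whole-blood smoking study (81 never / 172
    current smokers); the cell-type study is obtained by passing the sorted
    cell matrices directly.  Returns a dict with keys ``sheet``, ``panel``,
    ``truth``, ``celltype_betas``, ``compositions``, ``whole_blood``,
    ``pbmc``.
    """
    seeds = np.random.SeedSequence(seed).spawn(5)
    sub = [int(s.generate_state(1)[0] % (2 ** 31)) for s in seeds]
    sheet = generate_subjects(n_never, n_current, heavy_fraction=heavy_fraction,
                              cpd_cutoff=int(heavy_cutoff), seed=sub[0])
    panel = generate_reference_panel(n_probes, cell_types=cell_types,
                                     n_discriminating=n_discriminating,
                                     celltype_sd=celltype_sd, seed=sub[1])
    if class_counts is None:
        class_counts = {"myeloid_plus_B": 10, "lymphoid": 10, "pan_cell": 5,
                        "T_only": 5, "monocyte_only": 5, "duration_heavy": 5}
    truth = make_effect_truth(panel, class_counts, seed=sub[2])
    betas = synthesize_celltype_betas(panel, sheet, truth, noise_sd=noise_sd,
                                      heavy_cutoff=heavy_cutoff, seed=sub[3])
    comps = generate_compositions(sheet, concentration=concentration,
                                  pbmc_retention=pbmc_retention, seed=sub[4])
    whole_blood = mix_to_whole_blood(betas, comps, pbmc=False)
    pbmc = mix_to_whole_blood(betas, comps, pbmc=True)
    return {"sheet": sheet, "panel": panel, "truth": truth,
            "celltype_betas": betas, "compositions": comps,
            "whole_blood": whole_blood, "pbmc": pbmc}
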