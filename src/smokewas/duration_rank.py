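"""Stratified rank-change screen for smoking-duration effects.

Long-term heavy smokers may carry methylation changes that track years of
smoking but are absent or weak in lighter smokers.  The screen:

1. takes the top-K probes from an any-smoking EWAS,
2. restricts to current smokers and splits them at a cigarettes/day cutoff
   (below = light, at/above = heavy),
3. refits the association with *years smoked* within each stratum,
4. ranks probes by p-value within stratum (ties broken by probe id), and
5. reports the signed rank change (light rank minus heavy rank), largest
   first — probes near the top rose furthest when moving from light to
   heavy smokers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .ewas import RobustEWAS


class StratifiedRankChange(BaseEstimator):
    """Rank-change analysis of duration effects between smoking strata.

    Parameters
    ----------
    top_k : int
        Probes carried forward from the any-smoking results (default 1000).
    cpd_cutoff : float or None
        Cigarettes/day split; ``None`` uses the smoker median rounded to the
        nearest integer.  Heavy is defined as >= cutoff.
    covariates : tuple of str
        Covariate set for the within-stratum duration model.
    use_compositions : bool
        Retain composition covariates in the stratified fits (default True).

    Attributes
    ----------
    results_ : pd.DataFrame
        probe_id-indexed p_light, p_heavy, rank_light, rank_heavy,
        rank_change (= rank_light - rank_heavy) and abs_rank_change, sorted
        by descending rank_change.
    cutoff_ : float
        The cigarettes/day cutoff actually applied.
    """

    def __init__(self, top_k: int = 1000, cpd_cutoff: float | None = 22,
                 covariates: tuple = ("age", "sex", "race"),
                 use_compositions: bool = True, epsilon: float = 1e-6):
        self.top_k = top_k
        self.cpd_cutoff = cpd_cutoff
        self.covariates = covariates
        self.use_compositions = use_compositions
        self.epsilon = epsilon

    def fit(self, matrix: pd.DataFrame, sheet: pd.DataFrame,
            anysmoking_result: pd.DataFrame,
            compositions: pd.DataFrame | None = None):
        if self.top_k > len(anysmoking_result):
            raise ValueError(f"top_k={self.top_k} exceeds the "
                             f"{len(anysmoking_result)} available probes")
        top = anysmoking_result.sort_values("p_value", kind="mergesort") \
                               .head(self.top_k).index
        missing = top.difference(matrix.index)
        if len(missing):
            raise ValueError(f"top probes absent from matrix: {list(missing[:5])}")

        sub_sheet = sheet.loc[matrix.columns]
        smokers = sub_sheet[sub_sheet["smoking_status"] == "current"]
        if self.cpd_cutoff is None:
            cutoff = float(np.round(smokers["cigarettes_per_day"].median()))
        else:
            cutoff = float(self.cpd_cutoff)
        heavy_ids = smokers.index[smokers["cigarettes_per_day"] >= cutoff]
        light_ids = smokers.index[smokers["cigarettes_per_day"] < cutoff]
        if len(heavy_ids) == 0 or len(light_ids) == 0:
            raise ValueError(
                f"empty stratum at cutoff {cutoff}: "
                f"light={len(light_ids)}, heavy={len(heavy_ids)}")

        sub_matrix = matrix.loc[top]
        strata_p = {}
        for name, ids in (("light", light_ids), ("heavy", heavy_ids)):
            model = RobustEWAS(exposure="years_smoked",
                               covariates=self.covariates,
                               epsilon=self.epsilon)
            comp = None
            if self.use_compositions and compositions is not None:
                comp = compositions.loc[ids]
            model.fit(sub_matrix[ids], sheet.loc[ids], compositions=comp)
            strata_p[name] = model.results_["p_value"].reindex(top)

        res = pd.DataFrame({"p_light": strata_p["light"],
                            "p_heavy": strata_p["heavy"]}, index=top)
        res["rank_light"] = _rank_with_probe_ties(res["p_light"])
        res["rank_heavy"] = _rank_with_probe_ties(res["p_heavy"])
        res["rank_change"] = res["rank_light"] - res["rank_heavy"]
        res["abs_rank_change"] = res["rank_change"].abs()
        res.index.name = "probe_id"
        # largest rank gain first, deterministic tie-break on probe_id
        res = res.sort_index(kind="mergesort") \
                 .sort_values("rank_change", ascending=False, kind="mergesort")

        self.cutoff_ = cutoff
        self.n_light_ = int(len(light_ids))
        self.n_heavy_ = int(len(heavy_ids))
        self.results_ = res
        return self


def _rank_with_probe_ties(p: pd.Series) -> np.ndarray:
    """1-based rank by ascending p; exact p ties ordered by probe_id."""
    order = p.to_frame("p").assign(probe=p.index.astype(str)) \
             .sort_values(["p", "probe"], kind="mergesort").index
    ranks = pd.Series(np.arange(1, len(p) + 1), index=order)
    return ranks.reindex(p.index).to_numpy()


def stratified_rank_change(matrix: pd.DataFrame, sheet: pd.DataFrame,
                           anysmoking_result: pd.DataFrame,
                           top_k: int = 1000, cpd_cutoff: float | None = 22,
                           covariates=("age", "sex", "race"),
                           compositions: pd.DataFrame | None = None,
                           use_compositions: bool = True) -> pd.DataFrame:
    """Functional wrapper around :class:`StratifiedRankChange`."""
    model = StratifiedRankChange(top_k=top_k, cpd_cutoff=cpd_cutoff,
                                 covariates=tuple(covariates),
                                 use_compositions=use_compositions)
    model.fit(matrix, sheet, anysmoking_result, compositions=compositions)
    return model.results_


def write_rank_results(results: pd.DataFrame, path,
                       metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        results.to_csv(fh, sep="\t", index_label="probe_id")
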