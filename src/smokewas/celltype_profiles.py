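"""Cell-type-resolved effect profiling for candidate CpGs.

Builds per-cell-type smoking effect profiles (delta-beta and Welch p per
purified cell type, plus whole-blood/PBMC mixtures), clusters profiles by
effect size or significance pattern, labels each profile's lineage response
pattern, back-projects cell-type effects into the expected whole-blood
delta through the leukocyte mixture, regresses methylation on serum
cotinine, and computes delta-delta-Ct qPCR expression fold changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .ewas import group_delta_beta
from .synthetic_cohort import (B_TYPES, GRANULOCYTE_TYPES, MYELOID_TYPES,
                               NK_TYPES, T_TYPES)

PATTERN_LABELS = ("pan_cell", "myeloid", "myeloid_plus_B", "T_only",
                  "monocyte_only", "lymphoid", "none")


# ---------------------------------------------------------------------------
# association profiles
# ---------------------------------------------------------------------------

def celltype_association(celltype_matrices: dict[str, pd.DataFrame],
                         sheet: pd.DataFrame,
                         probes=None) -> pd.DataFrame:
    """Per-probe, per-cell-type delta-beta and Welch p for candidate CpGs.

    ``celltype_matrices`` maps a cell-type (or mixture, e.g. ``whole_blood``,
    ``pbmc``) label to its beta matrix; every candidate probe must be present
    in every matrix.  Returns a DataFrame indexed by probe with
    ``delta_<label>`` and ``p_<label>`` columns.
    """
    labels = list(celltype_matrices)
    if probes is None:
        probes = celltype_matrices[labels[0]].index
    probes = pd.Index(probes)
    cols = {}
    for label in labels:
        matrix = celltype_matrices[label]
        absent = probes.difference(matrix.index)
        if len(absent):
            raise ValueError(f"probes missing from matrix {label!r}: "
                             f"{list(absent[:5])}")
        gd = group_delta_beta(matrix.loc[probes], sheet)
        cols[f"delta_{label}"] = gd["delta_beta"]
        cols[f"p_{label}"] = gd["p_value"]
    out = pd.DataFrame(cols, index=probes)
    out.index.name = "probe_id"
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class ProfileClusterer(BaseEstimator):
    """Hierarchical clustering of cell-type effect profiles.

    Parameters
    ----------
    mode : {"delta", "neglog10p"}
        Cluster on signed delta-beta columns or on -log10 p-value columns.
    linkage : str
        scipy linkage method (default "average").
    metric : str
        Distance metric (default "euclidean").
    n_clusters : int
        Flat cut size (default 2).
    absolute : bool
        Cluster |delta| instead of signed delta.

    Attributes
    ----------
    linkage_ : ndarray
        scipy linkage matrix over probes sorted by probe_id (deterministic
        under input row permutation).
    labels_ : pd.Series
        Flat cluster labels at the requested cut.
    leaves_ : list of str
        Dendrogram leaf order.
    feature_columns_ : list of str
    """

    def __init__(self, mode: str = "delta", linkage: str = "average",
                 metric: str = "euclidean", n_clusters: int = 2,
                 absolute: bool = False):
        self.mode = mode
        self.linkage = linkage
        self.metric = metric
        self.n_clusters = n_clusters
        self.absolute = absolute

    def fit(self, profiles: pd.DataFrame, columns=None):
        if len(profiles) < 2:
            raise ValueError("need at least two profiles to cluster")
        if self.mode not in ("delta", "neglog10p"):
            raise ValueError(f"unknown mode {self.mode!r}")
        prefix = "delta_" if self.mode == "delta" else "p_"
        use = columns or [c for c in profiles.columns if c.startswith(prefix)]
        if not use:
            raise ValueError(f"no {prefix}* columns in profiles")
        data = profiles.sort_index(kind="mergesort")[use].astype(float)
        if data.isna().any().any():
            data = data.fillna(data.mean())  # column-mean imputation
        values = data.to_numpy()
        if self.mode == "neglog10p":
            values = -np.log10(np.clip(values, np.finfo(float).tiny, 1.0))
        elif self.absolute:
            values = np.abs(values)
        self.feature_columns_ = list(use)
        self.linkage_ = hierarchy.linkage(values, method=self.linkage,
                                          metric=self.metric)
        flat = hierarchy.fcluster(self.linkage_, t=self.n_clusters,
                                  criterion="maxclust")
        self.labels_ = pd.Series(flat, index=data.index, name="cluster")
        leaf_idx = hierarchy.leaves_list(self.linkage_)
        self.leaves_ = [data.index[i] for i in leaf_idx]
        self._index = data.index
        return self

    def fit_predict(self, profiles: pd.DataFrame, columns=None) -> pd.Series:
        return self.fit(profiles, columns=columns).labels_

    def to_newick(self) -> str:
        """Serialise the linkage tree as a Newick string with branch lengths."""
        check_is_fitted(self, "linkage_")
        tree = hierarchy.to_tree(self.linkage_)

        def render(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self._index[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return render(tree, tree.dist) + ";"


def cluster_profiles(profiles: pd.DataFrame, mode: str = "delta",
                     linkage: str = "average", metric: str = "euclidean",
                     n_clusters: int = 2, absolute: bool = False):
    """Functional wrapper: returns (linkage matrix, flat labels, newick)."""
    model = ProfileClusterer(mode=mode, linkage=linkage, metric=metric,
                             n_clusters=n_clusters, absolute=absolute)
    model.fit(profiles)
    return model.linkage_, model.labels_, model.to_newick()


# ---------------------------------------------------------------------------
# response-pattern classification
# ---------------------------------------------------------------------------

def _roles(cell_type: str) -> set[str]:
    roles = set()
    if cell_type in MYELOID_TYPES:
        roles.add("myeloid")
    if cell_type in GRANULOCYTE_TYPES:
        roles.add("granulocyte")
    if cell_type in {"CD14", "Mono"}:
        roles.add("monocyte")
    if cell_type in B_TYPES:
        roles.add("B")
    if cell_type in T_TYPES:
        roles.add("T")
    if cell_type in NK_TYPES:
        roles.add("NK")
    return roles


def classify_response_pattern(profile: pd.Series, alpha: float = 0.05,
                              cell_types=None) -> str:
    """Label a profile's lineage response from its significance pattern.

    The significance indicator vector across purified cell types (p < alpha,
    unadjusted within the small sorted-cell study) is matched against
    lineage rules, most specific first:

    - ``pan_cell``       significant in every cell type
    - ``myeloid``        CD14 and CD15 significant, no lymphoid signal
    - ``myeloid_plus_B`` myeloid plus B cells, T cells spared (the AHRR-like
      granulocyte > monocyte >> B pattern)
    - ``T_only``         significant only in T cells (ITGAL-like)
    - ``monocyte_only``  significant only in monocytes (MYO1G-like)
    - ``lymphoid``       significant only in lymphoid types, B or T involved
      (GPR15-like)
    - ``none``           nothing significant

    Mixture columns (whole blood, PBMC) are ignored.
    """
    p_cols = [c for c in profile.index if c.startswith("p_")]
    if cell_types is None:
        cell_types = [c[2:] for c in p_cols
                      if _roles(c[2:])]  # only labelled leukocyte types
    sig = {ct: bool(profile[f"p_{ct}"] < alpha) for ct in cell_types}
    sig_types = {ct for ct, s in sig.items() if s}
    roles_sig = set().union(*(_roles(ct) for ct in sig_types)) if sig_types else set()
    myeloid_types = {ct for ct in cell_types if "myeloid" in _roles(ct)}
    t_types = {ct for ct in cell_types if "T" in _roles(ct)}
    b_types = {ct for ct in cell_types if "B" in _roles(ct)}
    lymphoid_types = {ct for ct in cell_types
                      if _roles(ct) & {"B", "T", "NK"}}

    if not sig_types:
        return "none"
    if sig_types == set(cell_types):
        return "pan_cell"
    if myeloid_types and myeloid_types <= sig_types \
            and not (roles_sig & {"B", "T", "NK"}):
        return "myeloid"
    if myeloid_types and b_types and (myeloid_types | b_types) <= sig_types \
            and not (roles_sig & {"T"}):
        return "myeloid_plus_B"
    if t_types and sig_types <= t_types:
        return "T_only"
    if sig_types == {ct for ct in cell_types if "monocyte" in _roles(ct)} and sig_types:
        return "monocyte_only"
    if sig_types <= lymphoid_types:
        return "lymphoid"
    return "none"


def classify_profiles(profiles: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Apply :func:`classify_response_pattern` to every row."""
    return profiles.apply(classify_response_pattern, axis=1, alpha=alpha) \
                   .rename("pattern")


# ---------------------------------------------------------------------------
# mixture back-projection
# ---------------------------------------------------------------------------

def _check_simplex(weights: pd.Series, name: str) -> None:
    w = weights.to_numpy(dtype=float)
    if (w < -1e-9).any() or abs(w.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name} weights are not on the simplex "
                         f"(sum={w.sum():.6f}, min={w.min():.3g})")


def predict_wholeblood_delta(mean_beta_never: pd.DataFrame,
                             mean_beta_current: pd.DataFrame,
                             weights_never: pd.Series,
                             weights_current: pd.Series) -> pd.Series:
    """Expected whole-blood delta-beta from cell-type effects and composition.

    predicted delta = sum_c w_c^smoker * beta_c^smoker
                    - sum_c w_c^never  * beta_c^never

    which reduces to ``sum_c w_c * delta_c`` when the two groups share the
    same composition.  ``mean_beta_*`` are probes x cell-types group means;
    ``weights_*`` the group-mean compositions.
    """
    _check_simplex(weights_never, "never")
    _check_simplex(weights_current, "current")
    cell_types = list(mean_beta_never.columns)
    wn = weights_never.reindex(cell_types)
    wc = weights_current.reindex(cell_types)
    if wn.isna().any() or wc.isna().any():
        raise ValueError("weights missing for some cell types")
    pred = (mean_beta_current @ wc) - (mean_beta_never @ wn)
    return pred.rename("predicted_delta")


# ---------------------------------------------------------------------------
# cotinine regression
# ---------------------------------------------------------------------------

def cotinine_regression(betas: pd.Series, cotinine: pd.Series,
                        log_transform: bool = True,
                        detection_floor: float = 0.1) -> dict:
    """OLS of methylation beta on (log2-transformed) serum cotinine.

    Cotinine values below the detection floor are raised to it before the
    log transform.  Returns slope, intercept, r_squared and the two-sided
    slope p-value.
    """
    x = cotinine.reindex(betas.index).to_numpy(dtype=float)
    y = betas.to_numpy(dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if log_transform:
        x = np.log2(np.maximum(x, detection_floor))
    if np.ptp(x) == 0:
        raise ValueError("cotinine predictor has zero variance")
    if np.ptp(y) == 0:
        # constant response: flat fit carries no association
        return {"slope": 0.0, "intercept": float(y[0]), "r_squared": 0.0,
                "p_value": 1.0, "n": int(len(x))}
    res = stats.linregress(x, y)
    return {"slope": res.slope, "intercept": res.intercept,
            "r_squared": res.rvalue ** 2, "p_value": res.pvalue,
            "n": int(len(x))}


# ---------------------------------------------------------------------------
# qPCR fold change
# ---------------------------------------------------------------------------

def ddct_fold_change(records: pd.DataFrame, sheet: pd.DataFrame,
                     calibrator_status: str = "never") -> pd.DataFrame:
    """Delta-delta-Ct expression fold change relative to nonsmokers.

    ``records`` has sample_id, cell_type, target_gene, ct_target and
    ct_reference (the normalizer gene's cycle threshold).  Within each
    (cell_type, target_gene) group: dCt = ct_target - ct_reference,
    ddCt = dCt - mean(dCt over the calibrator group), FC = 2**(-ddCt).
    The fold change computed at the calibrator group's mean dCt is exactly 1.
    """
    req = {"sample_id", "cell_type", "target_gene", "ct_target", "ct_reference"}
    missing_cols = req - set(records.columns)
    if missing_cols:
        raise ValueError(f"expression records lack columns: {sorted(missing_cols)}")
    if records[["ct_target", "ct_reference"]].isna().any().any():
        bad = records.loc[records[["ct_target", "ct_reference"]].isna().any(axis=1),
                          "sample_id"]
        raise ValueError(f"missing cycle thresholds for samples: "
                         f"{list(bad[:5])}")
    if ((records["ct_target"] <= 0) | (records["ct_reference"] <= 0)).any():
        raise ValueError("cycle thresholds must be positive")

    out = records.copy()
    out["dct"] = out["ct_target"] - out["ct_reference"]
    status = sheet["smoking_status"].reindex(out["sample_id"]).to_numpy()
    out["smoking_status"] = status

    results = []
    for (ct, gene), grp in out.groupby(["cell_type", "target_gene"], sort=True):
        calib = grp.loc[grp["smoking_status"] == calibrator_status, "dct"]
        if calib.empty:
            raise ValueError(f"no {calibrator_status!r} calibrator samples for "
                             f"({ct}, {gene})")
        ddct = grp["dct"] - calib.mean()
        fc = 2.0 ** (-ddct)
        res = grp[["sample_id", "cell_type", "target_gene", "smoking_status"]].copy()
        res["ddct"] = ddct
        res["fold_change"] = fc
        results.append(res)
    return pd.concat(results, ignore_index=True)


def write_profiles(profiles: pd.DataFrame, path,
                   metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        profiles.to_csv(fh, sep="\t", index_label="probe_id")


def read_expression_records(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
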