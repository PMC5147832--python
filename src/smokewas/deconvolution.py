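"""Reference-based leukocyte deconvolution by constrained projection.

Estimates the cell-type composition of a mixed methylation sample by
projecting its beta profile at lineage-discriminating probes onto the
reference panel under simplex constraints::

    minimise  || beta - R w ||^2   subject to  w >= 0,  sum(w) = 1

This is the constrained-projection form of reference-based cell-mixture
estimation used to obtain the cell-count covariates for whole-blood EWAS.
The solver enumerates the faces of the simplex (feasible for the ~6-12
leukocyte types of a blood panel) and solves each face's equality-constrained
least-squares problem exactly, returning the feasible minimiser — exact to
linear-algebra precision, no iteration schedule or tolerance tuning.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .synthetic_cohort import ReferencePanel

logger = logging.getLogger(__name__)

SIMPLEX_TOL = 1e-9
MAX_ENUMERABLE_TYPES = 14


# ---------------------------------------------------------------------------
# probe selection
# ---------------------------------------------------------------------------

def select_discriminating_probes(panel: ReferencePanel, k_per_type: int = 50) -> pd.Index:
    """Pick the probes that best separate each cell type from the rest.

    For each cell type, ranks probes by the gap between that type's baseline
    and the mean baseline of all other types, and keeps the ``k_per_type``
    largest positive gaps (hypermethylated in the type) and the ``k_per_type``
    most negative (hypomethylated), when available.  Ties break on probe_id
    so the selection is deterministic.
    """
    if k_per_type < 1:
        raise ValueError("k_per_type must be >= 1")
    baseline = panel.baseline
    if baseline.shape[1] < 2:
        raise ValueError("need at least two cell types to discriminate")
    selected: set = set()
    for ct in baseline.columns:
        others = baseline.drop(columns=ct).mean(axis=1)
        gap = baseline[ct] - others
        table = pd.DataFrame({"gap": gap, "probe": gap.index})
        hyper = table[table["gap"] > 0] \
            .sort_values(["gap", "probe"], ascending=[False, True]).head(k_per_type)
        hypo = table[table["gap"] < 0] \
            .sort_values(["gap", "probe"], ascending=[True, True]).head(k_per_type)
        if len(hyper) == 0 and len(hypo) == 0:
            raise ValueError(
                f"no probes discriminate cell type {ct!r} "
                f"(needed up to {k_per_type} per direction, found 0)")
        selected.update(hyper["probe"])
        selected.update(hypo["probe"])
    # preserve panel probe order
    return panel.probe_ids[panel.probe_ids.isin(selected)]


# ---------------------------------------------------------------------------
# exact simplex-constrained least squares
# ---------------------------------------------------------------------------

def _solve_face(R: np.ndarray, b: np.ndarray, support: tuple[int, ...]):
    """Least squares on one simplex face: min ||b - R_S w||^2, sum w = 1.

    KKT system for the equality-constrained problem; returns (w_S, objective)
    or None when the face's normal equations are singular.
    """
    Rs = R[:, support]
    k = len(support)
    G = Rs.T @ Rs
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2.0 * G
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    kkt[k, k] = 0.0
    rhs = np.concatenate([2.0 * Rs.T @ b, [1.0]])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError:
        return None
    w = sol[:k]
    resid = b - Rs @ w
    return w, float(resid @ resid)


def simplex_lstsq(R: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Global minimiser of ||b - Rw||^2 over the probability simplex.

    Enumerates every face of the simplex and takes the feasible solution with
    the smallest objective.  The global optimum of a convex QP over the
    simplex lies on some face and solves that face's equality-constrained
    problem, so the enumeration is exhaustive.
    """
    n_types = R.shape[1]
    if n_types > MAX_ENUMERABLE_TYPES:
        raise ValueError(f"face enumeration supports up to "
                         f"{MAX_ENUMERABLE_TYPES} cell types, got {n_types}")
    best_w, best_obj = None, np.inf
    idx = range(n_types)
    for size in range(1, n_types + 1):
        for support in combinations(idx, size):
            out = _solve_face(R, b, support)
            if out is None:
                continue
            w_s, obj = out
            if (w_s >= -SIMPLEX_TOL).all() and obj < best_obj:
                w = np.zeros(n_types)
                w[list(support)] = np.clip(w_s, 0.0, None)
                w /= w.sum()
                best_w, best_obj = w, obj
    if best_w is None:
        raise np.linalg.LinAlgError("no feasible face solution found")
    return best_w, best_obj


def _check_degenerate(R: np.ndarray, cell_types: list[str]) -> None:
    for i, j in combinations(range(R.shape[1]), 2):
        if np.allclose(R[:, i], R[:, j], atol=1e-10):
            raise ValueError(
                f"reference columns for {cell_types[i]!r} and "
                f"{cell_types[j]!r} are identical; panel is degenerate")


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class CompositionEstimator(TransformerMixin, BaseEstimator):
    """Estimate leukocyte fractions of mixed samples from a reference panel.

    Parameters
    ----------
    k_per_type : int
        Discriminating probes retained per cell type and per direction
        (hyper- and hypomethylated).
    sum_to_one : bool
        Enforce sum(w) = 1 exactly (default).  When False the constraint
        relaxes to sum(w) <= 1, allowing mass from cell types absent from
        the panel (implemented by augmenting the panel with a zero column
        whose weight is dropped from the report).

    Attributes
    ----------
    probes_ : pd.Index
        Selected discriminating probes.
    reference_ : pd.DataFrame
        Panel baselines restricted to the selected probes.
    cell_types_ : list of str
    """

    def __init__(self, k_per_type: int = 50, sum_to_one: bool = True):
        self.k_per_type = k_per_type
        self.sum_to_one = sum_to_one

    def fit(self, panel: ReferencePanel, y=None):
        if not panel.has_discriminating and panel.discriminating is not None:
            # panel generated without a signature set; selection may still
            # succeed if baselines happen to separate, so only warn via check
            pass
        self.probes_ = select_discriminating_probes(panel, self.k_per_type)
        self.reference_ = panel.baseline.loc[self.probes_]
        self.cell_types_ = list(panel.baseline.columns)
        _check_degenerate(self.reference_.to_numpy(), self.cell_types_)
        return self

    def transform(self, betas: pd.DataFrame) -> pd.DataFrame:
        """Estimate compositions for each sample (column) of a beta matrix.

        Missing betas at selected probes are imputed as the panel row mean;
        the imputation count is logged.  Returns a DataFrame indexed by
        sample with one column per cell type plus ``residual_norm``.
        """
        check_is_fitted(self, "reference_")
        missing_probes = self.probes_.difference(betas.index)
        if len(missing_probes):
            raise ValueError(
                f"{len(missing_probes)} selected probes absent from input: "
                f"{list(missing_probes[:5])}")
        X = betas.loc[self.probes_]
        R = self.reference_.to_numpy()
        if not self.sum_to_one:
            R = np.hstack([R, np.zeros((R.shape[0], 1))])

        n_imputed = int(X.isna().to_numpy().sum())
        if n_imputed:
            row_means = self.reference_.mean(axis=1)
            X = X.apply(lambda col: col.fillna(row_means))
            logger.info("imputed %d missing betas at selected probes", n_imputed)

        rows = []
        for sample in X.columns:
            b = X[sample].to_numpy(dtype=float)
            w, obj = simplex_lstsq(R, b)
            if not self.sum_to_one:
                w = w[:-1]  # drop slack mass
            rows.append(np.concatenate([w, [np.sqrt(obj)]]))
        out = pd.DataFrame(rows, index=X.columns,
                           columns=self.cell_types_ + ["residual_norm"])
        out.index.name = "sample_id"
        return out

    def fit_transform(self, panel, betas=None, **kwargs):  # noqa: D102
        if betas is None:
            raise ValueError("fit_transform needs the mixed beta matrix")
        return self.fit(panel).transform(betas)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def estimate_composition(sample_betas: pd.Series | pd.DataFrame,
                         panel_subset: ReferencePanel | pd.DataFrame) -> pd.DataFrame:
    """Composition estimate(s) for pre-selected probes.

    ``panel_subset`` is a reference panel (or bare baseline DataFrame)
    already restricted to the probes of ``sample_betas``; no further probe
    selection happens here.
    """
    baseline = panel_subset.baseline if isinstance(panel_subset, ReferencePanel) else panel_subset
    if isinstance(sample_betas, pd.Series):
        sample_betas = sample_betas.to_frame(name=sample_betas.name or "sample")
    aligned = baseline.reindex(sample_betas.index)
    if aligned.isna().any().any():
        missing = sample_betas.index.difference(baseline.index)
        raise ValueError(f"panel lacks probes: {list(missing[:5])}")
    cell_types = list(baseline.columns)
    R = aligned.to_numpy(dtype=float)
    _check_degenerate(R, cell_types)
    rows = []
    for sample in sample_betas.columns:
        w, obj = simplex_lstsq(R, sample_betas[sample].to_numpy(dtype=float))
        rows.append(np.concatenate([w, [np.sqrt(obj)]]))
    out = pd.DataFrame(rows, index=sample_betas.columns,
                       columns=cell_types + ["residual_norm"])
    out.index.name = "sample_id"
    return out


def write_compositions(compositions: pd.DataFrame, path,
                       metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        compositions.to_csv(fh, index_label="sample_id")


def read_compositions(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col="sample_id")
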