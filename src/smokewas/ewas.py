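"""Per-probe robust-regression EWAS on M-values.

Each probe's M-values are regressed on a smoking exposure (current status,
pack-years or years smoked) plus demographic covariates and, for mixed
samples, estimated leukocyte composition, using Huber M-estimation fitted by
iteratively reweighted least squares (IRLS).  Two-sided p-values come from
the t distribution with n - p degrees of freedom; family-wise significance
uses a Bonferroni threshold computed from the number of probes actually
tested.  Group delta-beta (smoker minus nonsmoker mean beta) and its Welch
t-test accompany each probe.

The Huber tuning constant defaults to 1.345 (95% efficiency at the Gaussian),
with residual scale re-estimated each iteration by the normalized median
absolute deviation.  Standard errors use the standard large-sample
M-estimator covariance (Huber's 1973 form with the small-sample correction
factor, the "H1" covariance of common robust-regression software).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .preprocess import beta_to_m, DEFAULT_EPSILON

logger = logging.getLogger(__name__)

MAD_GAUSS = stats.norm.ppf(0.75)  # 0.6745: normalizes MAD to sigma
EXPOSURES = ("status", "pack_years", "years_smoked", "cigarettes_per_day")


# ---------------------------------------------------------------------------
# Huber IRLS
# ---------------------------------------------------------------------------

@dataclass
class HuberFit:
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    scale: float
    n_iter: int
    converged: bool
    objective_history: np.ndarray
    df_resid: int


def _huber_rho(u: np.ndarray, c: float) -> np.ndarray:
    au = np.abs(u)
    return np.where(au <= c, 0.5 * u ** 2, c * au - 0.5 * c ** 2)


def huber_irls(y: np.ndarray, X: np.ndarray, c: float = 1.345,
               max_iter: int = 50, tol: float = 1e-8,
               update_scale: bool = True, scale: float | None = None) -> HuberFit:
    """Huber M-estimation by iteratively reweighted least squares.

    Starts from OLS; at each iteration residuals are standardized by the
    normalized MAD scale (re-estimated unless ``update_scale`` is False or a
    fixed ``scale`` is supplied) and observations beyond the Huber corner
    ``c`` are downweighted by ``c/|u|``.  Convergence is declared when the
    maximum coefficient change falls below ``tol``.

    ``objective_history`` records sum(rho(resid/scale)) at each iteration;
    with a fixed scale IRLS is a majorize-minimise scheme and the history is
    non-increasing.
    """
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta

    fixed_scale = scale
    objective = []
    converged = False
    it = 0
    s = fixed_scale if fixed_scale is not None else _mad_scale(resid)
    for it in range(1, max_iter + 1):
        if update_scale and fixed_scale is None:
            s = _mad_scale(resid)
        if s < 1e-12:
            # (near-)exact fit: Huber reduces to OLS on the support
            converged = True
            break
        u = resid / s
        objective.append(float(_huber_rho(u, c).sum()))
        w = np.minimum(1.0, c / np.maximum(np.abs(u), 1e-300))
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        resid = y - X @ beta
        if delta < tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break
    objective.append(float(_huber_rho(resid / max(s, 1e-12), c).sum()))

    bse = _h1_bse(X, resid, s, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(bse > 0, beta / np.where(bse > 0, bse, 1.0), np.inf)
    pvals = np.clip(2.0 * stats.t.sf(np.abs(tvals), df=n - p),
                    np.finfo(float).tiny, 1.0)
    return HuberFit(params=beta, bse=bse, tvalues=tvals, pvalues=pvals,
                    scale=float(s), n_iter=it, converged=converged,
                    objective_history=np.asarray(objective), df_resid=n - p)


def _mad_scale(resid: np.ndarray) -> float:
    return float(np.median(np.abs(resid)) / MAD_GAUSS)


def _h1_bse(X: np.ndarray, resid: np.ndarray, scale: float, c: float) -> np.ndarray:
    """Huber (1973) covariance with small-sample correction factor."""
    n, p = X.shape
    if scale < 1e-12:
        return np.zeros(p)
    u = resid / scale
    psi = np.clip(u, -c, c)
    psi_deriv = (np.abs(u) <= c).astype(float)
    m = psi_deriv.mean()
    k = 1.0 + p / n * psi_deriv.var() / m ** 2
    xtx_inv = np.linalg.pinv(X.T @ X)
    factor = k ** 2 * (np.sum(psi ** 2) / (n - p) * scale ** 2) / (psi_deriv.sum() / n) ** 2
    return np.sqrt(np.clip(factor * np.diag(xtx_inv), 0.0, None))


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def build_design(sheet: pd.DataFrame, exposure: str,
                 covariates=("age", "sex", "race"),
                 compositions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the regression design: intercept, exposure, covariates,
    and all-but-one composition column.

    ``exposure`` is ``"status"`` (current-vs-never indicator) or a numeric
    sample-sheet column such as ``pack_years`` or ``years_smoked``.
    Categorical covariates are one-hot encoded with the first level as
    reference.  Composition fractions sum to one, so the largest-mean cell
    type is dropped to keep the design full rank (logged).
    """
    cols = {"const": pd.Series(1.0, index=sheet.index)}
    if exposure == "status":
        cols["exposure"] = (sheet["smoking_status"] == "current").astype(float)
    else:
        if exposure not in sheet.columns:
            raise ValueError(f"exposure column {exposure!r} not in sample sheet")
        cols["exposure"] = sheet[exposure].astype(float)

    for cov in covariates:
        if cov not in sheet.columns:
            raise ValueError(f"covariate {cov!r} not in sample sheet")
        series = sheet[cov]
        if pd.api.types.is_numeric_dtype(series):
            cols[cov] = series.astype(float)
        else:
            levels = sorted(series.astype(str).unique())
            for level in levels[1:]:  # first level is the reference
                cols[f"{cov}[{level}]"] = (series.astype(str) == level).astype(float)

    if compositions is not None:
        comp_cols = [c for c in compositions.columns
                     if c not in ("residual_norm", "pbmc_depletion")]
        comp = compositions.reindex(sheet.index)[comp_cols]
        if comp.isna().any().any():
            missing = sheet.index[comp.isna().any(axis=1)]
            raise ValueError(f"no composition estimate for samples: {list(missing[:5])}")
        dropped = comp.mean().idxmax()
        logger.info("dropping composition column %r (largest mean) to avoid "
                    "simplex collinearity", dropped)
        for ct in comp_cols:
            if ct != dropped:
                cols[f"comp[{ct}]"] = comp[ct].astype(float)

    design = pd.DataFrame(cols, index=sheet.index)
    _check_full_rank(design)
    return design


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"design has {X.shape[0]} samples for {X.shape[1]} parameters")
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-10 * max(1.0, diag.max())
    if bad.any():
        names = [design.columns[i] for i in np.nonzero(bad)[0]]
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns: {names}")


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class RobustEWAS(BaseEstimator):
    """Per-probe Huber-regression EWAS on M-values.

    Parameters
    ----------
    exposure : str
        "status", "pack_years", "years_smoked" or another numeric column.
    covariates : tuple of str
        Sample-sheet columns adjusted for (categoricals one-hot encoded).
    epsilon : float
        Beta clip bound for the M-value transform.
    huber_c, max_iter, tol : float
        IRLS settings (tuning constant, iteration cap, coefficient
        tolerance).
    alpha : float
        Family-wise level for the Bonferroni threshold.

    Attributes
    ----------
    results_ : pd.DataFrame
        Per-probe exposure_coefficient, standard_error, t_statistic,
        p_value, delta_beta, ttest_p, n_used and rank, sorted by p-value.
    threshold_ : float
        Bonferroni threshold alpha / n_tested.
    n_significant_ : int
    design_columns_ : list of str
    """

    def __init__(self, exposure: str = "status",
                 covariates: tuple = ("age", "sex", "race"),
                 epsilon: float = DEFAULT_EPSILON, huber_c: float = 1.345,
                 max_iter: int = 50, tol: float = 1e-8, alpha: float = 0.05):
        self.exposure = exposure
        self.covariates = covariates
        self.epsilon = epsilon
        self.huber_c = huber_c
        self.max_iter = max_iter
        self.tol = tol
        self.alpha = alpha

    def fit(self, matrix: pd.DataFrame, sheet: pd.DataFrame,
            compositions: pd.DataFrame | None = None):
        missing = matrix.columns.difference(sheet.index)
        if len(missing):
            raise ValueError(f"matrix samples absent from sample sheet: "
                             f"{list(missing[:5])}")
        sub_sheet = sheet.loc[matrix.columns]
        design = build_design(sub_sheet, self.exposure, self.covariates,
                              compositions)
        X_full = design.to_numpy(dtype=float)
        self.design_columns_ = list(design.columns)
        exp_idx = self.design_columns_.index("exposure")

        M = beta_to_m(matrix, epsilon=self.epsilon).to_numpy(dtype=float)
        n_probes = M.shape[0]
        out = np.full((n_probes, 5), np.nan)  # coef, se, t, p, n_used
        p_params = X_full.shape[1]
        for i in range(n_probes):
            y = M[i]
            keep = ~np.isnan(y)
            n_used = int(keep.sum())
            out[i, 4] = n_used
            if n_used <= p_params:
                warnings.warn(f"probe {matrix.index[i]!r}: only {n_used} "
                              f"usable samples for {p_params} parameters; "
                              "skipped", UserWarning, stacklevel=2)
                continue
            fit = huber_irls(y[keep], X_full[keep], c=self.huber_c,
                             max_iter=self.max_iter, tol=self.tol)
            tval = fit.params[exp_idx] / fit.bse[exp_idx] if fit.bse[exp_idx] > 0 else np.inf
            pval = 2.0 * stats.t.sf(abs(tval), df=fit.df_resid)
            out[i] = (fit.params[exp_idx], fit.bse[exp_idx], tval,
                      max(pval, np.finfo(float).tiny), n_used)

        results = pd.DataFrame(
            out, index=matrix.index,
            columns=["exposure_coefficient", "standard_error", "t_statistic",
                     "p_value", "n_used"])

        groups = sub_sheet["smoking_status"].value_counts()
        if groups.get("never", 0) >= 2 and groups.get("current", 0) >= 2:
            gd = group_delta_beta(matrix, sub_sheet)
            results["delta_beta"] = gd["delta_beta"]
            results["ttest_p"] = gd["p_value"]
        else:
            results["delta_beta"] = np.nan
            results["ttest_p"] = np.nan

        tested = results["p_value"].notna()
        results.index.name = "probe_id"
        # stable sort: ascending p, ties broken lexicographically by probe_id
        results = results.sort_index(kind="mergesort") \
                         .sort_values("p_value", kind="mergesort")
        results["rank"] = np.arange(1, len(results) + 1)

        self.n_tested_ = int(tested.sum())
        self.threshold_ = bonferroni_threshold(self.n_tested_, self.alpha)
        self.n_significant_ = int((results["p_value"] < self.threshold_).sum())
        self.results_ = results
        return self

    def significant(self) -> pd.DataFrame:
        check_is_fitted(self, "results_")
        return self.results_[self.results_["p_value"] < self.threshold_]


def fit_robust_ewas(matrix: pd.DataFrame, sheet: pd.DataFrame,
                    exposure: str = "status",
                    covariates=("age", "sex", "race"),
                    compositions: pd.DataFrame | None = None,
                    **kwargs) -> pd.DataFrame:
    """Functional wrapper around :class:`RobustEWAS`; returns ``results_``."""
    model = RobustEWAS(exposure=exposure, covariates=tuple(covariates), **kwargs)
    model.fit(matrix, sheet, compositions=compositions)
    return model.results_


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def group_delta_beta(matrix: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Smoker-minus-nonsmoker mean beta difference with Welch's t-test.

    Returns per-probe ``delta_beta`` (mean current - mean never),
    ``t_statistic`` and two-sided unequal-variance ``p_value``.
    """
    sub = sheet.loc[matrix.columns]
    current = matrix.loc[:, (sub["smoking_status"] == "current").to_numpy()]
    never = matrix.loc[:, (sub["smoking_status"] == "never").to_numpy()]
    if current.shape[1] < 2 or never.shape[1] < 2:
        raise ValueError(
            f"need >=2 samples per group, got never={never.shape[1]}, "
            f"current={current.shape[1]}")
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(current, never, axis=1, equal_var=False,
                               nan_policy="omit")
    delta = current.mean(axis=1) - never.mean(axis=1)
    # degenerate probes: both groups constant -> identical groups carry no
    # evidence (p=1), distinct constants carry infinite evidence (p=0)
    const_c = (current.max(axis=1) - current.min(axis=1)) == 0
    const_n = (never.max(axis=1) - never.min(axis=1)) == 0
    both_const = (const_c & const_n).to_numpy()
    if both_const.any():
        same = both_const & (current.iloc[:, 0].to_numpy()
                             == never.iloc[:, 0].to_numpy())
        diff = both_const & ~same
        t = np.where(same, 0.0, t)
        p = np.where(same, 1.0, p)
        t = np.where(diff, np.inf * np.sign(np.where(diff, delta, 1.0)), t)
        p = np.where(diff, 0.0, p)
        delta = delta.where(~same, 0.0)
    return pd.DataFrame({"delta_beta": delta, "t_statistic": t, "p_value": p},
                        index=matrix.index)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise p-value threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


def group_summary(sheet: pd.DataFrame, extra: pd.DataFrame | None = None,
                  variables=None, decimals: int = 1) -> pd.DataFrame:
    """Per-group means/SDs and smoker-minus-nonsmoker differences.

    ``extra`` (e.g. composition estimates or CBC fractions, indexed by
    sample) is joined onto the sheet before summarising.  Returns one row per
    numeric variable with never/current means and SDs and the rounded
    ``difference`` (current - never).
    """
    data = sheet.copy()
    if extra is not None:
        cols = [c for c in extra.columns if c != "residual_norm"]
        data = data.join(extra[cols])
    for status in ("never", "current"):
        if (data["smoking_status"] == status).sum() == 0:
            raise ValueError(f"no samples in group {status!r}")
    if variables is None:
        variables = [c for c in data.columns
                     if pd.api.types.is_numeric_dtype(data[c])
                     and c not in ("sample_id",)]
    never = data[data["smoking_status"] == "never"]
    current = data[data["smoking_status"] == "current"]
    rows = []
    for var in variables:
        m_n, s_n = never[var].mean(), never[var].std(ddof=1)
        m_c, s_c = current[var].mean(), current[var].std(ddof=1)
        rows.append({
            "variable": var,
            "never_mean": round(m_n, decimals), "never_sd": round(s_n, decimals),
            "current_mean": round(m_c, decimals), "current_sd": round(s_c, decimals),
            "difference": round(m_c - m_n, decimals),
        })
    return pd.DataFrame(rows).set_index("variable")


def write_results(results: pd.DataFrame, path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        results.to_csv(fh, sep="\t", index_label="probe_id")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="probe_id")
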