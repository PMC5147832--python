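"""Loading, validation and scale conversion for methylation matrices.

A methylation matrix is a :class:`pandas.DataFrame` of beta values
(methylation fractions in [0, 1]) with probe identifiers as the index and
sample identifiers as the columns.  The sample sheet is a DataFrame keyed by
``sample_id`` carrying smoking exposure and demographic covariates.  Probe
annotations carry genomic coordinates (1-based, array-manifest convention)
and a SNP-overlap exclusion flag.

Association models operate on the M-value scale, ``M = log2(beta/(1-beta))``,
which stabilises the variance of beta values near the 0/1 boundaries.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1e-6

SAMPLE_SHEET_NUMERIC = ("cigarettes_per_day", "years_smoked", "pack_years",
                        "cotinine", "age")
SMOKING_LEVELS = ("never", "current")


class ValidationError(ValueError):
    """Raised when an input matrix, sheet or annotation violates its contract."""


# ---------------------------------------------------------------------------
# scale conversion
# ---------------------------------------------------------------------------

def beta_to_m(beta, epsilon: float = DEFAULT_EPSILON):
    """Convert beta values (methylation fractions) to M-values.

    ``M = log2(b / (1 - b))`` with ``b`` clipped to ``[epsilon, 1 - epsilon]``
    so boundary betas map to large but finite M-values.  Accepts scalars,
    arrays, Series or DataFrames; missing values propagate.

    Parameters
    ----------
    beta : array-like
        Methylation fractions in [0, 1] (NaN allowed).
    epsilon : float
        Clip bound, ``0 < epsilon < 0.5``.
    """
    if not 0.0 < epsilon < 0.5:
        raise ValidationError(f"epsilon must be in (0, 0.5), got {epsilon}")
    values = np.asarray(beta, dtype=float) if np.isscalar(beta) else beta
    arr = np.asarray(values, dtype=float)
    bad = (arr < 0.0) | (arr > 1.0)  # NaN compares False, so it propagates
    if bad.any():
        _raise_out_of_range(values, bad)
    clipped = np.clip(arr, epsilon, 1.0 - epsilon)
    m = np.log2(clipped / (1.0 - clipped))
    return _like(beta, m)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: ``beta = 2**m / (1 + 2**m)``.

    Round-trips ``beta_to_m`` to within 1e-12 for betas inside the clip
    bounds.  Non-finite input raises.
    """
    arr = np.asarray(m, dtype=float)
    if np.any(np.isinf(arr)):
        raise ValidationError("M-values must be finite")
    # expit(m * ln 2) computed stably for large |m|
    out = np.empty_like(arr)
    pos = arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-arr[pos]))
    e = np.exp2(arr[~pos])
    out[~pos] = e / (1.0 + e)
    return _like(m, out)


def _like(template, arr):
    if isinstance(template, pd.DataFrame):
        return pd.DataFrame(arr, index=template.index, columns=template.columns)
    if isinstance(template, pd.Series):
        return pd.Series(arr, index=template.index, name=template.name)
    if np.isscalar(template):
        return float(arr)
    return arr


def _raise_out_of_range(values, bad):
    if isinstance(values, pd.DataFrame):
        rows, cols = np.nonzero(np.asarray(bad))
        probe, sample = values.index[rows[0]], values.columns[cols[0]]
        raise ValidationError(
            f"beta outside [0, 1] at probe {probe!r}, sample {sample!r}")
    if isinstance(values, pd.Series):
        idx = values.index[np.nonzero(np.asarray(bad))[0][0]]
        raise ValidationError(f"beta outside [0, 1] at {idx!r}")
    raise ValidationError("beta outside [0, 1]")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check a beta matrix: unique probe/sample ids, values in [0,1] or NaN."""
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate probe ids: {dupes[:5]}")
    if matrix.columns.duplicated().any():
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
    arr = matrix.to_numpy(dtype=float)
    bad = ((arr < 0.0) | (arr > 1.0)) & ~np.isnan(arr)
    if bad.any():
        _raise_out_of_range(matrix, bad)
    return matrix


def validate_sample_sheet(sheet: pd.DataFrame, rounding_tol: float = 0.05) -> pd.DataFrame:
    """Check sample-sheet invariants.

    Never-smokers must have zero cigarettes/day, years smoked and pack-years;
    pack-years must equal (cigarettes_per_day / 20) * years_smoked within a
    rounding tolerance; ages must be positive.
    """
    if "sample_id" in sheet.columns and sheet["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample sheet")
    unknown = set(sheet["smoking_status"]) - set(SMOKING_LEVELS)
    if unknown:
        raise ValidationError(f"unknown smoking_status levels: {sorted(unknown)}")
    never = sheet["smoking_status"] == "never"
    for col in ("cigarettes_per_day", "years_smoked", "pack_years"):
        if col in sheet and (sheet.loc[never, col] != 0).any():
            raise ValidationError(f"never-smokers must have {col} == 0")
    if {"cigarettes_per_day", "years_smoked", "pack_years"} <= set(sheet.columns):
        expected = sheet["cigarettes_per_day"] / 20.0 * sheet["years_smoked"]
        off = (sheet["pack_years"] - expected).abs() > rounding_tol * np.maximum(1.0, expected)
        if off.any():
            bad_id = sheet.loc[off].index[0]
            raise ValidationError(f"pack_years inconsistent with cpd*years at {bad_id!r}")
    if (sheet["age"] <= 0).any():
        raise ValidationError("age must be positive")
    return sheet


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    if annotation.index.duplicated().any():
        raise ValidationError("duplicate probe ids in annotation")
    if (annotation["position"] <= 0).any():
        raise ValidationError("annotation positions must be positive (1-based)")
    return annotation


# ---------------------------------------------------------------------------
# probe filtering
# ---------------------------------------------------------------------------

def filter_probes(matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Drop probes flagged for exclusion (SNP overlap at the CpG site).

    Probes present in the matrix but missing from the annotation are retained
    with a warning (conservative: an incomplete manifest should not silently
    shrink the analysis).  Retained probe order and values are unchanged.
    """
    validate_matrix(matrix)
    missing = matrix.index.difference(annotation.index)
    if len(missing):
        warnings.warn(
            f"{len(missing)} probes missing from annotation were retained",
            UserWarning, stacklevel=2)
    flags = annotation["exclude_flag"].reindex(matrix.index, fill_value=False)
    keep = ~flags.astype(bool)
    removed = int((~keep).sum())
    logger.info("filter_probes: removed %d of %d probes", removed, len(matrix))
    if removed == len(matrix):
        warnings.warn("all probes excluded; returning empty matrix",
                      UserWarning, stacklevel=2)
    return matrix.loc[keep]


# ---------------------------------------------------------------------------
# file I/O (plain-text interchange formats)
# ---------------------------------------------------------------------------

def read_matrix(path) -> pd.DataFrame:
    """Read a beta matrix from tab-separated text (probe_id column first)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = "probe_id"
    return validate_matrix(df)


def write_matrix(matrix: pd.DataFrame, path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        matrix.to_csv(fh, sep="\t", index_label="probe_id")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, comment="#")
    if "sample_id" not in sheet.columns:
        raise ValidationError("sample sheet must have a sample_id column")
    sheet = sheet.set_index("sample_id", drop=False)
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        sheet.to_csv(fh, index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", comment="#")
    ann = ann.set_index("probe_id", drop=False)
    ann["exclude_flag"] = ann["exclude_flag"].astype(bool)
    return validate_annotation(ann)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def annotation_to_bed(annotation: pd.DataFrame, path) -> None:
    """Export probe coordinates as BED (0-based, half-open)."""
    bed = pd.DataFrame({
        "chrom": annotation["chromosome"],
        "start": annotation["position"] - 1,
        "end": annotation["position"],
        "name": annotation["probe_id"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)
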