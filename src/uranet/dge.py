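"""Single-replicate differential expression against a panel-wide background.

In a drug screen run as one replicate per condition there is no within-condition
variance to estimate, so each gene's own expression across *all* conditions is
used as its null background. Per gene, log2 abundances are centred on the panel
mean, scored with a robust z (median / MAD), converted to two-sided normal
p-values and Benjamini-Hochberg adjusted. A (drug, gene) pair is called a DEG
when p_adj < alpha.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: consistency factor making the MAD an unbiased scale estimate under normality
MAD_SCALE = 1.4826

DEG_COLUMNS = ["drug", "gene", "log2_ratio", "robust_z", "p_value", "p_adj",
               "direction", "is_deg"]


class EmptyUniverseError(ValueError):
    """No genes survive filtering; downstream stages have no universe."""


class InsufficientBackgroundError(ValueError):
    """Fewer than 3 conditions: the panel cannot serve as its own background."""


def _validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"duplicate gene identifier: {dup!r}")
    if matrix.columns.has_duplicates:
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise ValueError(f"duplicate condition identifier: {dup!r}")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise ValueError("expression matrix contains negative abundances")


def read_matrix(path) -> pd.DataFrame:
    """Read a genes x conditions CPM matrix from TSV (optionally gzipped)."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    _validate_matrix(matrix)
    return matrix


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def filter_by_cpm(matrix: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Retain genes whose mean CPM across all conditions is strictly > threshold.

    The condition set is unchanged. An empty result is returned as-is;
    :func:`call_degs` raises :class:`EmptyUniverseError` when it receives one.
    """
    if threshold < 0:
        raise ValueError("CPM threshold must be >= 0")
    keep = matrix.mean(axis=1) > threshold
    return matrix.loc[keep]


def log_normalize_vs_panel_mean(matrix: pd.DataFrame,
                                pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(cpm + c) centred on each gene's mean across all conditions.

    Row means of the result are 0 by construction; the sign convention is
    positive = up versus the panel average.
    """
    log2 = np.log2(matrix.to_numpy(dtype=float) + pseudocount)
    ratios = log2 - log2.mean(axis=1, keepdims=True)
    return pd.DataFrame(ratios, index=matrix.index, columns=matrix.columns)


def robust_z_scores(log_ratios: pd.DataFrame) -> pd.DataFrame:
    """Per-gene robust z across conditions: (x - median) / (1.4826 * MAD).

    Degenerate rows fall back gracefully: when the MAD is 0 the sample SD
    replaces the scaled MAD as denominator; when the SD is also 0 the row is
    constant and every z is 0.
    """
    if log_ratios.shape[1] < 3:
        raise InsufficientBackgroundError(
            f"robust z needs >= 3 conditions, got {log_ratios.shape[1]}")
    x = log_ratios.to_numpy(dtype=float)
    med = np.median(x, axis=1, keepdims=True)
    dev = x - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    denom = np.where(mad > 0, MAD_SCALE * mad, sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0, dev / denom, 0.0)
    return pd.DataFrame(z, index=log_ratios.index, columns=log_ratios.columns)


def p_values_from_z(z) -> np.ndarray | pd.DataFrame:
    """Two-sided standard-normal tail: p = 2 * Phi(-|z|), in (0, 1]."""
    arr = np.asarray(z, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("z-scores must be finite")
    p = 2.0 * stats.norm.sf(np.abs(arr))
    # extreme |z| underflows the normal tail; keep p strictly positive
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    if isinstance(z, pd.DataFrame):
        return pd.DataFrame(p, index=z.index, columns=z.columns)
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr <= 0) | (arr > 1)) or not np.isfinite(arr).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def call_degs(matrix: pd.DataFrame, alpha: float = 0.05, *,
              cpm_threshold: float = 1.0, pseudocount: float = 1.0,
              bh_scope: str = "per_drug") -> pd.DataFrame:
    """Run the full single-replicate DE stage and return one row per (drug, gene).

    Parameters
    ----------
    matrix
        Genes x conditions CPM matrix (linear scale).
    alpha
        Adjusted-p cutoff defining a DEG.
    cpm_threshold
        Mean-CPM filter applied before normalization.
    bh_scope
        ``"per_drug"`` adjusts across genes within each condition (each drug is
        one experiment); ``"global"`` pools all (drug, gene) pairs.

    Returns
    -------
    DataFrame with columns drug, gene, log2_ratio, robust_z, p_value, p_adj,
    direction (sign of robust_z), is_deg (p_adj < alpha).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if bh_scope not in ("per_drug", "global"):
        raise ValueError(f"unknown bh_scope: {bh_scope!r}")
    _validate_matrix(matrix)
    filtered = filter_by_cpm(matrix, cpm_threshold)
    if filtered.shape[0] == 0:
        raise EmptyUniverseError(
            f"no genes with mean CPM > {cpm_threshold}; empty gene universe")
    ratios = log_normalize_vs_panel_mean(filtered, pseudocount)
    z = robust_z_scores(ratios)
    p = p_values_from_z(z)

    p_arr = p.to_numpy()
    if bh_scope == "per_drug":
        p_adj = np.column_stack(
            [bh_adjust(p_arr[:, j]) for j in range(p_arr.shape[1])])
    else:
        p_adj = bh_adjust(p_arr.ravel()).reshape(p_arr.shape)

    n_genes, n_drugs = filtered.shape
    out = pd.DataFrame({
        "drug": np.repeat(filtered.columns.to_numpy(), n_genes),
        "gene": np.tile(filtered.index.to_numpy(), n_drugs),
        "log2_ratio": ratios.to_numpy().ravel(order="F"),
        "robust_z": z.to_numpy().ravel(order="F"),
        "p_value": p_arr.ravel(order="F"),
        "p_adj": p_adj.ravel(order="F"),
    })
    out["direction"] = np.sign(out["robust_z"]).astype(int)
    out["is_deg"] = out["p_adj"] < alpha
    return out[DEG_COLUMNS]


def write_deg_table(degs: pd.DataFrame, path) -> None:
    degs.to_csv(path, sep="\t", index=False)


def read_deg_table(path) -> pd.DataFrame:
    degs = pd.read_csv(path, sep="\t",
                       dtype={"drug": str, "gene": str})
    missing = set(DEG_COLUMNS) - set(degs.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    return degs
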