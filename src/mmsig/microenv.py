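"""Tumor-immune-microenvironment (TIME) expression unmixing.

Whole bone marrow (WBM) is modeled as a two-component mixture of CD138+
tumor cells and everything else. Given matched WBM and CD138+ expression
profiles and the per-sample tumor fraction p (the summed proportion of the
plasma-cell catalogs from any deconvolution tool), the microenvironment
profile is recovered by algebraic inversion:

    E_time = (E_wbm - E_mm * p) / (1 - p)

Negative unmixed values are estimation artifacts of the linear inversion
and are deliberately retained (clipping would bias downstream
correlations). Immune-compartment proportions can be renormalized to sum
to 1 after removing the tumor fraction, and TIME genes correlated with a
signature score are selected by Spearman rho and P thresholds.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PLASMA_CATALOGS",
    "cd138_fraction",
    "renormalize_immune",
    "time_expression",
    "filter_abundant_cells",
    "correlate_with_score",
    "spearman_exact_pvalue",
]

# Cell catalogs counted as the CD138+ (tumor/plasma) compartment.
PLASMA_CATALOGS = ("Plasma cells", "B cells memory", "MM plasma cells", "PlasmaMemory")


def cd138_fraction(proportions: pd.DataFrame, plasma_catalogs=PLASMA_CATALOGS) -> pd.Series:
    """Per-sample tumor fraction: sum of the plasma-cell catalog proportions."""
    missing = [c for c in plasma_catalogs if c not in proportions.columns]
    if missing:
        raise KeyError(f"plasma catalogs missing from proportion matrix: {missing}")
    p = proportions[list(plasma_catalogs)].sum(axis=1)
    return p.clip(lower=0.0, upper=np.nextafter(1.0, 0.0)).rename("p_mm")


def renormalize_immune(proportions: pd.DataFrame, p_mm: pd.Series,
                       plasma_catalogs=PLASMA_CATALOGS) -> pd.DataFrame:
    """Scale non-plasma proportions to sum to 1 per sample.

    Samples with p_mm == 1 (no microenvironment) are excluded with a warning.
    """
    immune_cols = [c for c in proportions.columns if c not in set(plasma_catalogs)]
    p = p_mm.reindex(proportions.index)
    full = p >= 1.0
    if full.any():
        warnings.warn(f"excluding {int(full.sum())} samples with tumor fraction 1")
    out = proportions.loc[~full, immune_cols].div(1.0 - p[~full], axis=0)
    return out


def time_expression(e_wbm: pd.DataFrame, e_mm: pd.DataFrame, p_mm: pd.Series) -> pd.DataFrame:
    """Unmix the microenvironment profile: (E_wbm - E_mm * p) / (1 - p)."""
    if not e_wbm.columns.equals(e_mm.columns) or not e_wbm.index.equals(e_mm.index):
        raise ValueError("E_wbm and E_mm must share genes and samples")
    p = p_mm.reindex(e_wbm.columns).to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("tumor fractions must lie in [0, 1]")
    keep = p < 1.0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} samples with tumor fraction 1")
    cols = e_wbm.columns[keep]
    pk = p[keep]
    num = e_wbm.loc[:, cols].to_numpy() - e_mm.loc[:, cols].to_numpy() * pk[None, :]
    return pd.DataFrame(num / (1.0 - pk)[None, :], index=e_wbm.index, columns=cols)


def filter_abundant_cells(immune_proportions: pd.DataFrame, min_avg: float = 0.01) -> list[str]:
    """Cell types with across-sample mean proportion >= min_avg."""
    means = immune_proportions.mean(axis=0)
    # small tolerance so a mean of exactly min_avg survives float summation
    return [c for c in immune_proportions.columns if means[c] >= min_avg - 1e-12]


@lru_cache(maxsize=None)
def _rank_product_counts(n: int) -> dict[int, int]:
    """Distribution of sum_i i*pi(i) over all permutations of 1..n (DP over subsets)."""
    max_t = sum(i * i for i in range(1, n + 1))
    dp = {0: np.zeros(max_t + 1, dtype=np.float64)}
    dp[0][0] = 1.0
    for mask in range(2**n - 1):
        if mask not in dp:
            continue
        arr = dp[mask]
        i = bin(mask).count("1") + 1  # next position to assign
        for j in range(1, n + 1):
            bit = 1 << (j - 1)
            if mask & bit:
                continue
            shift = i * j
            nxt = mask | bit
            if nxt not in dp:
                dp[nxt] = np.zeros(max_t + 1, dtype=np.float64)
            dp[nxt][shift:] += arr[: max_t + 1 - shift]
        del dp[mask]
    full = dp[2**n - 1]
    return {t: int(c) for t, c in enumerate(full) if c > 0}


def spearman_exact_pvalue(rho: float, n: int) -> float:
    """Exact two-sided permutation P-value of Spearman rho (untied ranks).

    Enumerates the exact null distribution of sum_i i*pi(i) by dynamic
    programming over subsets; feasible for n <= 12.
    """
    if n > 12:
        raise ValueError("exact Spearman P only supported for n <= 12")
    counts = _rank_product_counts(n)
    denom = n * (n**2 - 1)
    total = sum(counts.values())
    hits = 0
    for t, c in counts.items():
        rho_t = (12 * t - 3 * n * (n + 1) ** 2) / denom
        if abs(rho_t) >= abs(rho) - 1e-12:
            hits += c
    return hits / total


def _spearman_vectorized(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman rho of X against y with t-approximation P-values."""
    n = y.size
    ry = stats.rankdata(y)
    rx = np.apply_along_axis(stats.rankdata, 1, X)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum(axis=1) * (ry_c**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx_c @ ry_c) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.isnan(t)] = np.nan
    p[np.isinf(t)] = 0.0
    return rho, p


def correlate_with_score(
    time_expr: pd.DataFrame,
    scores: pd.Series,
    gene_universe=None,
    rho_thresh: float = 0.1,
    p_thresh: float = 0.01,
    method: str = "auto",
) -> pd.DataFrame:
    """Genes whose TIME expression correlates with the signature score.

    Spearman correlation per gene against the per-sample score; retain
    genes with |rho| > rho_thresh and P < p_thresh, labeled by sign.
    P-values use the t-approximation with average ranks; with
    ``method="exact"`` (or "auto" at n <= 12 with untied data) the exact
    permutation distribution is used instead. Constant genes are skipped.
    """
    scores = scores.reindex(time_expr.columns)
    if scores.isna().any():
        raise ValueError("scores missing for some samples")
    n = len(scores)
    if n < 10 and method != "exact":
        raise ValueError("need at least 10 samples (or method='exact')")
    sub = time_expr if gene_universe is None else time_expr.loc[
        time_expr.index.intersection(pd.Index(gene_universe))
    ]
    X = sub.to_numpy(dtype=float)
    y = scores.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("scores are constant")
    nonconst = X.std(axis=1) > 0
    X, genes = X[nonconst], sub.index[nonconst]
    rho, p = _spearman_vectorized(X, y)
    use_exact = method == "exact" or (method == "auto" and n <= 12)
    if use_exact:
        untied_y = len(np.unique(y)) == n
        for i in range(len(genes)):
            if untied_y and len(np.unique(X[i])) == n:
                p[i] = spearman_exact_pvalue(rho[i], n)
    out = pd.DataFrame({"gene": genes, "rho": rho, "pvalue": p})
    out["direction"] = np.where(out["rho"] > 0, "positive", "negative")
    keep = (out["rho"].abs() > rho_thresh) & (out["pvalue"] < p_thresh)
    return out[keep].reset_index(drop=True)
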