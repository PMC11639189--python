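"""Construction of driver-gene dysregulation signatures.

For each recurrently mutated driver gene, every gene's expression is
regressed on mutation status with age and gender as covariates
(``expression ~ mutated + age + gender``, ordinary least squares). The
mutation coefficient's sign and P-value become a pair of weight vectors:

* beta > 0:  ``w_up = min(-log10 P, cap) / cap``, ``w_dn = 0``
* beta < 0:  ``w_dn = min(-log10 P, cap) / cap``, ``w_up = 0``

so every weight lies in [0, 1] and at most one of the pair is nonzero.
With the default cap of 10, P = 1e-10 maps to the ceiling weight 1.

A sample is "mutated" in a gene if it carries at least one non-synonymous
variant (missense, missense_splice, stop_gain, frameshift) of that gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import NONSYNONYMOUS_CLASSES

__all__ = [
    "RegressionEffect",
    "GeneSignature",
    "mutated_samples",
    "mutation_status",
    "select_recurrent_genes",
    "fit_mutation_effect",
    "fit_mutation_effects",
    "build_signature",
    "write_signature",
    "read_signature",
]

_P_FLOOR = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class RegressionEffect:
    """Effect of one driver's mutation status on one gene's expression."""

    gene: str
    beta: float
    pvalue: float
    valid: bool = True


@dataclass
class GeneSignature:
    """Per-gene up/down weight vectors for one perturbed driver gene."""

    signature_gene: str
    table: pd.DataFrame  # index: gene; columns: w_up, w_dn
    cap: float = 10.0
    log_base: float = 10.0

    def __post_init__(self) -> None:
        w_up = self.table["w_up"].to_numpy()
        w_dn = self.table["w_dn"].to_numpy()
        if ((w_up < 0) | (w_up > 1) | (w_dn < 0) | (w_dn > 1)).any():
            raise ValueError("weights must lie in [0, 1]")
        if (w_up * w_dn != 0).any():
            raise ValueError("w_up and w_dn must be mutually exclusive per gene")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def w_up(self) -> pd.Series:
        return self.table["w_up"]

    @property
    def w_dn(self) -> pd.Series:
        return self.table["w_dn"]


def mutated_samples(mutations: pd.DataFrame, gene: str) -> set[str]:
    """Samples with >= 1 non-synonymous variant of *gene*."""
    sub = mutations[
        (mutations["gene"] == gene)
        & mutations["variant_class"].isin(NONSYNONYMOUS_CLASSES)
    ]
    return set(sub["sample_id"])


def mutation_status(mutations: pd.DataFrame, gene: str, samples) -> np.ndarray:
    """0/1 non-synonymous mutation indicator aligned to *samples*."""
    hit = mutated_samples(mutations, gene)
    return np.fromiter((s in hit for s in samples), dtype=int, count=len(samples))


def select_recurrent_genes(
    mutations: pd.DataFrame,
    candidate_genes,
    min_samples: int = 30,
) -> list[str]:
    """Candidates whose non-synonymous mutated-sample count >= min_samples.

    Returned sorted by mutated-sample count descending (ties by gene id).
    Candidates absent from the mutation table are skipped with a warning.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    known = set(mutations["gene"]) if len(mutations) else set()
    counts = {}
    for gene in candidate_genes:
        if gene not in known:
            warnings.warn(f"candidate gene {gene!r} absent from mutation table; skipped")
            continue
        counts[gene] = len(mutated_samples(mutations, gene))
    selected = [(g, c) for g, c in counts.items() if c >= min_samples]
    selected.sort(key=lambda gc: (-gc[1], gc[0]))
    return [g for g, _ in selected]


def fit_mutation_effects(
    expression: pd.DataFrame,
    mutated: np.ndarray,
    age: np.ndarray,
    gender: np.ndarray,
) -> pd.DataFrame:
    """OLS of every gene's expression on mutation status, age and gender.

    The design matrix is shared across genes, so the fit is a single
    least-squares solve for all rows of the expression matrix. Returns a
    DataFrame indexed by gene with columns ``beta``, ``pvalue``, ``valid``.

    Rows with (numerically) zero residual variance are handled explicitly:
    a constant expression row is invalid, while a perfect nonzero fit keeps
    its coefficient with the P-value floored at the smallest positive float.
    """
    y = expression.to_numpy(dtype=float)
    n = y.shape[1]
    mutated = np.asarray(mutated, dtype=float)
    if mutated.shape != (n,):
        raise ValueError("mutated must align with expression columns")
    if len(np.unique(mutated)) < 2:
        raise ValueError("mutation status must contain both classes")
    X = np.column_stack([np.ones(n), mutated, np.asarray(age, float), np.asarray(gender, float)])
    k = X.shape[1]
    if n < k + 5:
        raise ValueError(f"need at least {k + 5} samples for a {k}-parameter fit, got {n}")

    # pinv tolerates rank-deficient designs (e.g. a constant gender column)
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta_all = y @ (X @ xtx_inv)  # genes x 4
    resid = y - beta_all @ X.T
    df = n - k
    sigma2 = (resid**2).sum(axis=1) / df
    scale = np.maximum((y - y.mean(axis=1, keepdims=True)) ** 2, 1e-300).sum(axis=1) / n
    perfect = sigma2 <= 1e-12 * np.maximum(scale, 1e-12)

    beta = beta_all[:, 1]
    se = np.sqrt(np.maximum(sigma2, _P_FLOOR) * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df)
    pval = np.clip(pval, _P_FLOOR, 1.0)
    pval[perfect & (beta != 0)] = _P_FLOOR

    constant_row = y.std(axis=1) == 0
    valid = ~constant_row
    pval[~valid] = 1.0
    beta = np.where(valid, beta, 0.0)
    return pd.DataFrame(
        {"beta": beta, "pvalue": pval, "valid": valid}, index=expression.index
    )


def fit_mutation_effect(
    expression_row,
    mutated,
    age,
    gender,
    gene: str = "",
) -> RegressionEffect:
    """Single-gene convenience wrapper around :func:`fit_mutation_effects`."""
    row = pd.DataFrame([np.asarray(expression_row, float)], index=[gene or "gene"])
    res = fit_mutation_effects(row, mutated, age, gender).iloc[0]
    return RegressionEffect(
        gene=gene or "gene",
        beta=float(res["beta"]),
        pvalue=float(res["pvalue"]),
        valid=bool(res["valid"]),
    )


def build_signature(
    effects: pd.DataFrame,
    signature_gene: str,
    cap: float = 10.0,
    log_base: float = 10.0,
) -> GeneSignature:
    """Turn per-gene regression effects into a [0,1]-normalized signature.

    *effects* is the output of :func:`fit_mutation_effects` (or a DataFrame
    with columns beta/pvalue and optional valid). Weights are
    ``min(-log(P)/log(log_base), cap) / cap`` on the side given by the sign
    of beta; invalid or zero-beta genes get weight 0 on both sides.
    """
    if cap <= 0:
        raise ValueError("cap must be > 0")
    if log_base <= 1:
        raise ValueError("log_base must be > 1")
    beta = effects["beta"].to_numpy(dtype=float)
    pval = effects["pvalue"].to_numpy(dtype=float)
    valid = (
        effects["valid"].to_numpy(dtype=bool)
        if "valid" in effects
        else np.ones(len(effects), dtype=bool)
    )
    if (pval <= 0).any():
        warnings.warn("non-positive P-values floored at the smallest positive float")
        pval = np.maximum(pval, _P_FLOOR)
    raw = np.minimum(-np.log(pval) / np.log(log_base), cap) / cap
    raw[~np.isfinite(beta) | ~valid] = 0.0
    w_up = np.where(valid & (beta > 0), raw, 0.0)
    w_dn = np.where(valid & (beta < 0), raw, 0.0)
    table = pd.DataFrame({"w_up": w_up, "w_dn": w_dn}, index=effects.index)
    return GeneSignature(signature_gene=signature_gene, table=table, cap=cap, log_base=log_base)


def write_signature(signature: GeneSignature, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# signature_gene={signature.signature_gene}\n")
        fh.write(f"# cap={signature.cap}\n")
        fh.write(f"# log_base={signature.log_base}\n")
        signature.table.rename_axis("gene").to_csv(fh, sep="\t")


def read_signature(path) -> GeneSignature:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh, sep="\t", index_col="gene")
    return GeneSignature(
        signature_gene=meta.get("signature_gene", ""),
        table=table[["w_up", "w_dn"]],
        cap=float(meta.get("cap", 10.0)),
        log_base=float(meta.get("log_base", 10.0)),
    )
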