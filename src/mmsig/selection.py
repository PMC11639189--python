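"""Mutation-burden enrichment and selection-pressure ratios.

Two per-gene statistics summarize whether a gene is mutated more often
than chance:

* the **enrichment ratio** observed / expected, where the expected count
  assumes mutations land uniformly at each patient's per-base rate over the
  gene's coding length: expected = length_bp * sum_over_patients(rate_i);
* a raw nonsynonymous/synonymous count ratio — (missense + missense_splice
  + stop_gain + frameshift) / synonymous — as a coarse indicator of
  selection pressure. This is a plain count ratio, *not* a site-normalized
  dN/dS: it ignores the differing numbers of nonsynonymous and synonymous
  sites per gene and any trinucleotide mutation-context model.

Observed counts default to total variant calls (a patient with two
missense calls in a gene contributes two), matching how the enrichment
arithmetic treats per-patient rates; counting distinct mutated samples is
available via ``mode="samples"``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .synthetic import NONSYNONYMOUS_CLASSES

__all__ = [
    "VARIANT_CLASSES",
    "summarize_mutations",
    "per_patient_rates",
    "expected_mutations",
    "enrichment_ratio",
    "nonsyn_syn_ratio",
    "gene_enrichment",
]

VARIANT_CLASSES = ("missense", "missense_splice", "stop_gain", "frameshift", "synonymous")


def summarize_mutations(
    mutations: pd.DataFrame, genes=None, mode: str = "calls"
) -> pd.DataFrame:
    """Per-gene variant-class counts and non-synonymous observed count.

    mode="calls" counts every variant call; mode="samples" counts distinct
    mutated samples.
    """
    if mode not in ("calls", "samples"):
        raise ValueError("mode must be 'calls' or 'samples'")
    df = mutations.copy()
    if genes is not None:
        df = df[df["gene"].isin(set(genes))]
    rows = {}
    for gene, sub in df.groupby("gene"):
        counts = {c: int((sub["variant_class"] == c).sum()) for c in VARIANT_CLASSES}
        nonsyn = sub[sub["variant_class"].isin(NONSYNONYMOUS_CLASSES)]
        observed = len(set(nonsyn["sample_id"])) if mode == "samples" else len(nonsyn)
        rows[gene] = {**counts, "observed": observed}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    return out.sort_index()


def per_patient_rates(mutations: pd.DataFrame, callable_bases: float) -> pd.Series:
    """Mutations per callable base for every patient (all variant classes)."""
    if callable_bases <= 0:
        raise ValueError("callable_bases must be > 0")
    counts = mutations.groupby("sample_id").size()
    return (counts / callable_bases).rename("rate")


def expected_mutations(per_patient_rates, length_bp: float) -> float:
    """Expected mutation count for a gene: length * sum of per-patient rates."""
    rates = np.asarray(per_patient_rates, dtype=float)
    if rates.size == 0:
        raise ValueError("per-patient rate vector is empty")
    if (rates < 0).any():
        raise ValueError("rates must be >= 0")
    if length_bp <= 0:
        raise ValueError("length_bp must be > 0")
    return float(length_bp * rates.sum())


def enrichment_ratio(observed: float, expected: float, decimals: int | None = None) -> float:
    """Observed / expected mutation count, optionally rounded for reporting."""
    if observed < 0:
        raise ValueError("observed must be >= 0")
    if expected <= 0:
        raise ValueError("expected must be > 0 for the ratio to be defined")
    ratio = observed / expected
    return round(ratio, decimals) if decimals is not None else ratio


def nonsyn_syn_ratio(class_counts, decimals: int | None = None) -> float:
    """Nonsynonymous / synonymous call-count ratio.

    *class_counts* maps variant classes to counts. Returns NaN (with a
    warning) when no synonymous calls exist — the ratio is then not
    evaluable, never infinite.
    """
    counts = dict(class_counts)
    syn = counts.get("synonymous", 0)
    nonsyn = sum(counts.get(c, 0) for c in NONSYNONYMOUS_CLASSES)
    if nonsyn < 0 or syn < 0:
        raise ValueError("counts must be >= 0")
    if syn == 0:
        warnings.warn("no synonymous calls; nonsynonymous/synonymous ratio not evaluable")
        return float("nan")
    ratio = nonsyn / syn
    return round(ratio, decimals) if decimals is not None else ratio


def gene_enrichment(
    mutations: pd.DataFrame,
    gene_lengths: pd.Series,
    callable_bases: float,
    mode: str = "calls",
) -> pd.DataFrame:
    """Per-gene enrichment table from a mutation table and gene lengths.

    Combines :func:`summarize_mutations`, :func:`per_patient_rates`,
    :func:`expected_mutations` and the two ratios.
    """
    summary = summarize_mutations(mutations, genes=gene_lengths.index, mode=mode)
    rates = per_patient_rates(mutations, callable_bases)
    rows = []
    for gene in summary.index:
        length = float(gene_lengths[gene])
        expected = expected_mutations(rates, length)
        observed = float(summary.loc[gene, "observed"])
        counts = summary.loc[gene, list(VARIANT_CLASSES)].to_dict()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ns_s = nonsyn_syn_ratio(counts)
        rows.append(
            {
                "gene": gene,
                "observed": observed,
                "length_bp": length,
                "expected": expected,
                "ratio": enrichment_ratio(observed, expected) if expected > 0 else np.nan,
                "ns_s_ratio": ns_s,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
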