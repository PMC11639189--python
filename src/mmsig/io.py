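"""Tab-delimited readers/writers for the standard cohort file set."""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_expression",
    "read_mutations",
    "read_clinical",
    "read_gene_list",
    "write_scores",
    "read_scores",
]


def read_expression(path) -> pd.DataFrame:
    """Gene x sample expression matrix; first column gene ids, header sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def read_mutations(path) -> pd.DataFrame:
    """Mutation table with columns sample_id, gene, variant_class."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "gene", "variant_class"}
    if not required.issubset(df.columns):
        raise ValueError(f"mutation table must have columns {sorted(required)}")
    return df


def read_clinical(path) -> pd.DataFrame:
    """Clinical table indexed by sample_id."""
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def read_gene_list(path) -> list[str]:
    """One gene id per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
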