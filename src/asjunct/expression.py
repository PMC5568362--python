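"""Length-weighted gene expression from per-model FPKM values.

For one gene in one library under one mapper, expression is
``sum(FPKM_i * length_i) / primary_transcript_length`` over the gene's
models. Library expression is the mean of the two mapper values, sample
expression the median over replicate libraries, and a gene counts as
expressed in a sample when that median is strictly above one.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .event_caller import EvidenceDesign

logger = logging.getLogger(__name__)

EXPRESSION_THRESHOLD = 1.0  # strictly above -> expressed


def mapper_expression(
    models: Iterable[tuple[float, float]], primary_length: float
) -> float:
    """Normalized expression for one gene x library x mapper.

    ``models`` are (fpkm, length) pairs; genes with no models score 0.
    """
    if primary_length <= 0:
        raise ValueError("primary transcript length must be positive")
    return sum(f * l for f, l in models) / primary_length


def library_expression(mapper_values: Sequence[float | None]) -> float:
    """Mean of the two per-mapper values; a missing mapper counts as 0."""
    vals = []
    for v in mapper_values:
        if v is None:
            logger.warning("missing mapper value treated as 0")
            v = 0.0
        vals.append(v)
    if len(vals) != 2:
        raise ValueError(f"expected two mapper values, got {len(vals)}")
    return (vals[0] + vals[1]) / 2.0


def sample_expression(library_values: Sequence[float]) -> float:
    """Median over replicate libraries."""
    if len(library_values) == 0:
        raise ValueError("sample without replicate libraries")
    return float(np.median(library_values))


def is_expressed(sample_values: Iterable[float]) -> bool:
    """Expressed iff any sample value is strictly above one."""
    return any(v > EXPRESSION_THRESHOLD for v in sample_values)


def read_expression_table(path: str) -> pd.DataFrame:
    """Read the per-model expression TSV (model_id, library_id, mapper_id, fpkm, length)."""
    df = pd.read_csv(path, sep="\t", dtype={"model_id": str, "library_id": str, "mapper_id": str})
    required = {"model_id", "library_id", "mapper_id", "fpkm", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    return df


def compute_gene_expression(
    expression: pd.DataFrame,
    model_gene: Mapping[str, str],
    primary_lengths: Mapping[str, float],
    design: EvidenceDesign,
) -> pd.DataFrame:
    """Per-gene, per-sample expression over all annotated genes.

    Returns a tidy frame (gene_id, sample_id, value, expressed) where
    ``expressed`` marks the per-sample call; genes without any model in a
    library contribute 0 for that library.
    """
    df = expression.copy()
    df["gene_id"] = df["model_id"].map(model_gene)
    df = df.dropna(subset=["gene_id"])
    df["product"] = df["fpkm"] * df["length"]
    per_mapper = (
        df.groupby(["gene_id", "library_id", "mapper_id"], sort=False)["product"]
        .sum()
        .reset_index()
    )
    per_mapper["value"] = per_mapper.apply(
        lambda r: r["product"] / primary_lengths[r["gene_id"]], axis=1
    )

    genes = sorted(primary_lengths)
    lib_sample = design.library_sample
    libraries = sorted(lib_sample)
    # dense gene x library x mapper grid, absent combinations are 0
    wide = per_mapper.pivot_table(
        index="gene_id", columns=["library_id", "mapper_id"], values="value", fill_value=0.0
    )
    full_cols = pd.MultiIndex.from_product([libraries, list(design.mappers)])
    wide = wide.reindex(index=genes, columns=full_cols, fill_value=0.0).fillna(0.0)
    # library expression: mean of the two mappers
    lib_expr = wide.T.groupby(level=0).mean().T
    rows = []
    for sample, libs in design.samples.items():
        med = lib_expr[list(libs)].median(axis=1)
        for gid, value in med.items():
            rows.append(
                {
                    "gene_id": gid,
                    "sample_id": sample,
                    "value": float(value),
                    "expressed": bool(value > EXPRESSION_THRESHOLD),
                }
            )
    out = pd.DataFrame(rows).sort_values(["gene_id", "sample_id"]).reset_index(drop=True)
    return out


def expressed_genes(gene_expression: pd.DataFrame) -> set[str]:
    """Genes expressed in at least one sample."""
    mask = gene_expression["expressed"]
    return set(gene_expression.loc[mask, "gene_id"].unique())
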