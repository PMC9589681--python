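"""Genomic nutrient-stress indices (Omega_N, Omega_P, Omega_Fe).

Surface-ocean macronutrients are often below detection, so historical
nutrient stress is read from the genome instead: the more abundant a
clade's nutrient-acquisition genes are relative to its single-copy core
genes, the stronger the selection for scavenging that nutrient has been.
For each designated stress gene the coverage is normalized to the summed
SCCG coverage of the sample, converted to a Z-score across samples, and
the Z-scores are summed per category (N, P, Fe) into the Omega index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd


@dataclass
class StressGeneSet:
    """Genes designated as indicators of one nutrient-stress category."""

    category: str          # e.g. "N", "P", "Fe"
    gene_ids: list[str]


@dataclass
class OmegaTable:
    """Per-sample Omega indices plus the per-gene intermediates."""

    omega: pd.DataFrame        # index: sample, columns: categories
    z_scores: pd.DataFrame     # index: sample, columns: genes
    normalized: pd.DataFrame   # index: sample, columns: genes


def normalized_stress_coverage(
    stress_cov: pd.DataFrame, sccg_total_cov: pd.Series
) -> pd.DataFrame:
    """Stress-gene coverage divided by the sample's summed SCCG coverage.

    ``stress_cov`` is samples x genes; samples with zero (or missing) SCCG
    coverage are excluded with a warning.
    """
    totals = sccg_total_cov.reindex(stress_cov.index)
    bad = totals.index[(totals <= 0) | totals.isna()]
    if len(bad):
        warnings.warn(
            f"excluding {len(bad)} sample(s) with zero SCCG coverage: "
            f"{list(bad[:5])}",
            UserWarning, stacklevel=2,
        )
        stress_cov = stress_cov.drop(index=bad)
        totals = totals.drop(index=bad)
    return stress_cov.div(totals, axis=0)


def omega_index(
    normalized: pd.DataFrame, sets: Sequence[StressGeneSet]
) -> OmegaTable:
    """Z-score each gene across samples and sum per category.

    Z-scores use the sample standard deviation (ddof 1); genes with zero
    variance contribute 0.  Categories must be disjoint; a category with
    no genes present yields Omega = 0 everywhere.  Needs >= 2 samples.
    """
    if len(normalized) < 2:
        raise ValueError("Z-scores need at least 2 samples")
    claimed: set[str] = set()
    for s in sets:
        overlap = claimed & set(s.gene_ids)
        if overlap:
            raise ValueError(f"gene(s) in multiple categories: {sorted(overlap)}")
        claimed |= set(s.gene_ids)

    mean = normalized.mean(axis=0)
    sd = normalized.std(axis=0, ddof=1)
    # a gene whose spread is at float-rounding level is constant in practice;
    # dividing by such an sd would amplify representation noise into
    # arbitrary Z-scores
    scale = normalized.abs().max(axis=0)
    degenerate = sd <= 1e-12 * scale.where(scale > 0, other=1.0)
    z = (normalized - mean).div(sd.mask(degenerate)).fillna(0.0)

    omega = pd.DataFrame(index=normalized.index)
    for s in sets:
        present = [g for g in s.gene_ids if g in z.columns]
        omega[s.category] = z[present].sum(axis=1) if present else 0.0
    return OmegaTable(omega=omega, z_scores=z, normalized=normalized)


def read_stress_gene_sets(path: str | Path) -> list[StressGeneSet]:
    """Read a gene_id -> category mapping TSV (columns gene_id, category)."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if not {"gene_id", "category"} <= set(df.columns):
        raise ValueError("stress-gene TSV needs columns gene_id, category")
    return [
        StressGeneSet(category=cat, gene_ids=list(grp["gene_id"]))
        for cat, grp in df.groupby("category", sort=True)
    ]
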