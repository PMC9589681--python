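"""Depth selection, read rarefaction, and per-gene coverage.

Sequencing depth varies by orders of magnitude between samples and biases
the coverage slope (deeper libraries recruit disproportionately to the
origin).  The remedy is rarefaction: every sample's SCCG reads are
subsampled, without replacement, to one shared depth chosen so that the
expected mean genome coverage meets a floor (default 5x, the minimum at
which a replication slope is recoverable), and the whole analysis is
repeated over independent subsamples (default 30) whose spread yields a
standard error.

Samples with fewer reads than the common depth are excluded (QC flag
``below_min_coverage``), never upsampled.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CoverageProfile, GeneOrderMap, MappedReadTable

DEFAULT_N_REPLICATES = 30
DEFAULT_TARGET_COVERAGE = 5.0
DEFAULT_READ_LENGTH = 150.0


@dataclass
class RarefactionPlan:
    """A shared subsampling depth and replication scheme for one ecotype."""

    ecotype_id: str
    depth_reads: int
    n_replicates: int = DEFAULT_N_REPLICATES
    seed: int = 0
    target_mean_coverage: float = DEFAULT_TARGET_COVERAGE
    assumed_read_length: float = DEFAULT_READ_LENGTH

    def __post_init__(self) -> None:
        if self.depth_reads < 1:
            raise ValueError("depth_reads must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def select_rarefaction_depth(
    gene_order: GeneOrderMap,
    assumed_read_length: float = DEFAULT_READ_LENGTH,
    target_mean_coverage: float = DEFAULT_TARGET_COVERAGE,
) -> int:
    """Number of reads whose expected mean SCCG coverage meets the target.

    depth = ceil(target * total_SCCG_length / read_length).  Using one
    assumed read length (rather than each sample's empirical mean) keeps the
    depth shared across all samples.
    """
    if assumed_read_length <= 0:
        raise ValueError("assumed_read_length must be > 0")
    if target_mean_coverage <= 0:
        raise ValueError("target_mean_coverage must be > 0")
    total = gene_order.total_gene_length
    if total == 0:
        raise ValueError("gene order has zero total length")
    raw = target_mean_coverage * total / assumed_read_length
    # guard against float error pushing an exact integer up by one
    return int(math.ceil(round(raw, 9)))


def _replicate_rng(seed: int, sample_id: str, replicate: int) -> np.random.Generator:
    """Deterministic stream for (seed, sample, replicate).

    The sample id is folded through a stable hash so adding or reordering
    samples never perturbs another sample's draws.
    """
    digest = hashlib.blake2b(sample_id.encode("utf-8"), digest_size=8).digest()
    sample_key = int.from_bytes(digest, "big")
    ss = np.random.SeedSequence(entropy=[seed, sample_key, replicate])
    return np.random.default_rng(ss)


def rarefy_reads(
    table: MappedReadTable, plan: RarefactionPlan
) -> list[MappedReadTable] | None:
    """Subsample a read table to the plan's depth, in replicate.

    Returns ``n_replicates`` tables of exactly ``depth_reads`` reads each,
    drawn uniformly without replacement, or ``None`` if the sample has fewer
    reads than the depth (the caller flags it ``below_min_coverage``).
    Exclusion is a QC outcome, not an error.
    """
    n = table.n_reads
    if n < plan.depth_reads:
        return None
    out = []
    for r in range(plan.n_replicates):
        if n == plan.depth_reads:
            sub = table.records
        else:
            rng = _replicate_rng(plan.seed, table.sample_id, r)
            idx = rng.choice(n, size=plan.depth_reads, replace=False)
            sub = table.records.iloc[np.sort(idx)]
        out.append(table.replace_records(sub.reset_index(drop=True)))
    return out


def rarefied_coverage_matrix(
    table: MappedReadTable, gene_order: GeneOrderMap, plan: RarefactionPlan
) -> np.ndarray | None:
    """Coverage profiles for all rarefaction replicates, as one array.

    Row r is the coverage profile of replicate r, drawn with the same
    deterministic stream as `rarefy_reads` (so the two routes agree); the
    per-read DataFrames are never materialized.  Returns ``None`` when the
    sample is below the depth, mirroring `rarefy_reads`.
    """
    n = table.n_reads
    if n < plan.depth_reads:
        return None
    codes, lengths = gene_codes_and_lengths(table, gene_order)
    out = np.empty((plan.n_replicates, gene_order.n_genes))
    for r in range(plan.n_replicates):
        if n == plan.depth_reads:
            sel_codes, sel_lengths = codes, lengths
        else:
            rng = _replicate_rng(plan.seed, table.sample_id, r)
            idx = np.sort(rng.choice(n, size=plan.depth_reads, replace=False))
            sel_codes, sel_lengths = codes[idx], lengths[idx]
        out[r] = coverage_from_codes(sel_codes, sel_lengths, gene_order)
    return out


def gene_codes_and_lengths(
    table: MappedReadTable, gene_order: GeneOrderMap
) -> tuple[np.ndarray, np.ndarray]:
    """Per-read (order_index, read_length) arrays; validates gene ids.

    Categorical gene_id columns are resolved through their categories so
    the per-read mapping is O(reads) with no string work.
    """
    table.validate_against(gene_order)
    idx = gene_order.order_index_of()
    col = table.records["gene_id"]
    if isinstance(col.dtype, pd.CategoricalDtype):
        cat_to_order = idx.reindex(col.cat.categories).to_numpy()
        codes = cat_to_order[col.cat.codes.to_numpy()]
    else:
        codes = col.map(idx).to_numpy()
    lengths = table.records["read_length"].to_numpy(dtype=float)
    return codes.astype(np.int64), lengths


def coverage_from_codes(
    codes: np.ndarray, lengths: np.ndarray, gene_order: GeneOrderMap
) -> np.ndarray:
    summed = np.bincount(codes, weights=lengths, minlength=gene_order.n_genes)
    return summed / gene_order.gene_lengths


def compute_coverage(
    table: MappedReadTable,
    gene_order: GeneOrderMap,
    replicate_index: int = 0,
) -> CoverageProfile:
    """Per-gene coverage = summed read lengths / gene length.

    Genes with no reads get 0.  The result is ordered along the genome
    (by ``order_index``).
    """
    codes, lengths = gene_codes_and_lengths(table, gene_order)
    coverage = coverage_from_codes(codes, lengths, gene_order)
    return CoverageProfile(
        sample_id=table.sample_id,
        replicate_index=replicate_index,
        coverage=coverage,
    )
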