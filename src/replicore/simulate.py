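"""Synthetic read tables and diel series with known ground truth.

The generator is the forward model of the estimators: per-gene expected
coverage is tent-shaped around a chosen terminus (lambda_g = c_true +
(2 R / L) d_g, d_g the circular distance from the terminus to the gene
midpoint), per-gene read counts are drawn Poisson or negative-binomial
around expectations scaled to a total read budget, and all reads carry a
fixed length (150 bp by default, typical short-read chemistry).  Two
optional distortions probe robustness:

* ``ori_bias_strength`` multiplies lambda_g by
  1 + s * log10(total_reads / 1e5) * (1 - 2 d_g / L), truncated at 0 — a
  deliberately simple depth-dependent origin/terminus imbalance used to
  verify that rarefaction removes the depth-slope correlation, not a model
  of library chemistry.
* ``coverage_shape="exponential"`` swaps the linear tent for the
  exponential copy-number profile 2^(R * (1 - 2 d / L)) to test the linear
  fit under model mismatch.

`simulate_diel_series` draws R_obs values from the diel Gaussian-bump
model at evenly spread sampling times with additive normal noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from .diel import DielSeries, assign_day_bins, diel_mean
from .estimator import circular_distance
from .io import GeneOrderMap, MappedReadTable


@dataclass
class DielScenario:
    """Ground-truth parameters for a simulated diel series."""

    t1: float = 20.0            # peak time, h local solar
    tw: float = 2.0             # width of the replication period, h
    c0: float = 0.2             # background slope
    r24: tuple[float, ...] = (0.6, 0.7, 0.8, 0.9, 1.0)  # per-day maxima
    samples_per_day: int = 8
    sigma_obs: float = 0.05
    jitter_h: float = 0.0       # uniform jitter on sampling times

    @property
    def n_days(self) -> int:
        return len(self.r24)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic read-table generator (defaults = the study
    conditions the estimators are validated under)."""

    n_genes: int = 700
    gene_length: int = 800           # bp per gene
    genome_length: int = 1_600_000   # bp; genes evenly spaced within it
    true_R: float = 0.5              # standardized slope (origin excess)
    terminus_bp: int = 400_000
    c_true: float = 5.0              # baseline (terminus) coverage, x
    total_reads: int | None = 20_000  # None: budget implied by the coverage model
    read_length: int = 150
    noise: str = "poisson"           # or "negative_binomial"
    nb_dispersion: float = 10.0
    ori_bias_strength: float = 0.0
    coverage_shape: str = "tent"     # or "exponential"
    diel: DielScenario | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("need at least 3 genes")
        if self.gene_length * self.n_genes > self.genome_length:
            raise ValueError("genes do not fit in the genome")
        if self.noise not in {"poisson", "negative_binomial"}:
            raise ValueError(f"unknown noise model {self.noise!r}")


def synthetic_gene_order(config: SimulationConfig) -> GeneOrderMap:
    """Evenly spaced single-copy genes on a circular genome."""
    starts = (
        np.floor(np.arange(config.n_genes) * config.genome_length / config.n_genes)
    ).astype(np.int64)
    genes = pd.DataFrame({
        "gene_id": [f"g{i:05d}" for i in range(config.n_genes)],
        "start": starts,
        "end": starts + config.gene_length,
    })
    return GeneOrderMap(
        reference_id="synthetic_ref",
        genome_length=config.genome_length,
        genes=genes,
    )


def expected_gene_coverage(
    config: SimulationConfig, gene_order: GeneOrderMap
) -> np.ndarray:
    """Per-gene expected coverage lambda_g under the configured shape and
    origin-bias distortion (before scaling to the read budget)."""
    L = config.genome_length
    d = circular_distance(gene_order.midpoints, config.terminus_bp, L)
    if config.coverage_shape == "tent":
        lam = config.c_true + (2.0 * config.true_R / L) * d
    elif config.coverage_shape == "exponential":
        # copy-number profile: doubling controlled by the standardized slope
        lam = config.c_true * 2.0 ** (config.true_R * (2.0 * d / L))
    else:
        raise ValueError(f"unknown coverage_shape {config.coverage_shape!r}")
    if config.ori_bias_strength > 0:
        if config.total_reads is None:
            raise ValueError("ori_bias_strength needs an explicit total_reads")
        factor = 1.0 + (
            config.ori_bias_strength
            * np.log10(config.total_reads / 1e5)
            * (1.0 - 2.0 * d / L)
        )
        lam = lam * np.clip(factor, 0.0, None)
    if (lam < 0).any():
        g = int(np.argmin(lam))
        raise ValueError(
            f"negative expected coverage at gene index {g} "
            f"(lambda = {lam[g]:.4g}); raise c_true or lower true_R"
        )
    return lam


def simulate_read_table(
    config: SimulationConfig, sample_id: str = "S0"
) -> tuple[MappedReadTable, dict[str, Any]]:
    """Draw one sample's mapped-read table from the tent coverage model.

    Expected read counts are lambda_g * gene_length / read_length, scaled
    so they sum to ``total_reads`` before noise; counts are then drawn per
    the noise model and expanded into fixed-length read records.  Returns
    the table and a truth record with every generating parameter.
    """
    gene_order = synthetic_gene_order(config)
    lam = expected_gene_coverage(config, gene_order)
    mu = lam * gene_order.gene_lengths / config.read_length
    total_reads = config.total_reads
    if total_reads is None:
        total_reads = int(round(mu.sum()))  # budget implied by the model
    mu = mu * (total_reads / mu.sum())
    rng = np.random.default_rng(config.seed)
    if config.noise == "poisson":
        counts = rng.poisson(mu)
    else:
        k = config.nb_dispersion
        counts = rng.negative_binomial(k, k / (k + mu))
    codes = np.repeat(
        np.arange(gene_order.n_genes, dtype=np.int32), counts
    )
    records = pd.DataFrame({
        "gene_id": pd.Categorical.from_codes(codes, categories=gene_order.gene_ids),
        "read_length": np.full(len(codes), config.read_length, dtype=np.int64),
    })
    table = MappedReadTable(
        sample_id=sample_id, records=records, ecotype_id="synthetic"
    )
    truth = {
        "sample_id": sample_id,
        "true_R": config.true_R,
        "terminus_bp": config.terminus_bp,
        "c_true": config.c_true,
        "total_reads": total_reads,
        "n_reads_drawn": int(counts.sum()),
        "expected_counts_sum": float(mu.sum()),
        "mean_model_coverage": float(lam.mean()),
        "seed": config.seed,
    }
    return table, truth


def remap_at_depth(
    config: SimulationConfig, depth_reads: int, sample_id: str = "S0"
) -> MappedReadTable:
    """Emulate re-extracting a sample's SCCG reads at a different library depth.

    The origin-bias knob models a mapping-stage artifact whose strength
    depends on the depth of the dataset being mapped, so a re-extraction at
    ``depth_reads`` re-evaluates the bias at that depth (it is not a plain
    subsample of the deeper table, whose read composition would keep the
    parent depth's distortion).
    """
    cfg = dataclasses.replace(config, total_reads=depth_reads)
    return simulate_read_table(cfg, sample_id=sample_id)[0]


def expected_r_at_depth(config: SimulationConfig, depth_reads: int) -> float:
    """Standardized slope of the expected coverage profile after rarefying
    to ``depth_reads``.

    Rarefaction rescales the whole profile to the mean coverage the depth
    implies, so the slope the estimator can recover at that depth is the
    configured shape slope times (depth coverage / model mean coverage).
    This is the ground truth for parameter-recovery comparisons.
    """
    gene_order = synthetic_gene_order(config)
    lam = expected_gene_coverage(config, gene_order)
    depth_cov = depth_reads * config.read_length / gene_order.total_gene_length
    return config.true_R * depth_cov / float(lam.mean())


def simulate_diel_series(
    config: SimulationConfig,
) -> tuple[DielSeries, dict[str, Any]]:
    """Draw a diel series of R_obs values from the Gaussian-bump model.

    Each noon-to-noon day bin d gets ``samples_per_day`` observations at
    evenly spread times; R_obs_i = c0 + (R24_d - c0) * exp(-Delta^2/(2 tw^2))
    + Normal(0, sigma_obs).
    """
    if config.diel is None:
        raise ValueError("config.diel block is required")
    sc = config.diel
    rng = np.random.default_rng(config.seed)
    rows = []
    for d, r24_d in enumerate(sc.r24):
        # noon-to-noon: raw times in [12, 36) mapped back to the clock
        t_raw = 12.0 + (np.arange(sc.samples_per_day) + 0.5) * 24.0 / sc.samples_per_day
        if sc.jitter_h > 0:
            t_raw = t_raw + rng.uniform(-sc.jitter_h, sc.jitter_h, sc.samples_per_day)
            t_raw = np.clip(t_raw, 12.0, np.nextafter(36.0, 12.0))
        for t in t_raw:
            time_h = float(t % 24.0)
            day = d if t < 24.0 else d + 1
            mu = diel_mean(np.array([time_h]), np.array([r24_d]),
                           sc.t1, sc.tw, sc.c0)[0]
            rows.append({
                "time_h": time_h,
                "day": day,
                "R_obs": float(mu + rng.normal(0.0, sc.sigma_obs)),
            })
    series = assign_day_bins(pd.DataFrame(rows))
    truth = {
        "t1": sc.t1, "tw": sc.tw, "c0": sc.c0,
        "r24": list(sc.r24), "sigma_obs": sc.sigma_obs,
        "samples_per_day": sc.samples_per_day, "seed": config.seed,
    }
    return series, truth
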