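"""Terminus identification, tent fit, standardization, aggregation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from replicore import (
    CoverageProfile,
    GeneOrderMap,
    RarefactionPlan,
    SimulationConfig,
    aggregate_r_obs,
    best_fit_terminus,
    circular_distance,
    circular_minimum_position,
    estimate_replication,
    expected_gene_coverage,
    fit_tent,
    fixed_terminus,
    simulate_read_table,
    standardize_slope,
    synthetic_gene_order,
)
from replicore.estimator import DegenerateMinimumWarning
from replicore.io import QC_NEGATIVE_SLOPE


def _profile(cov, sample_id="s"):
    return CoverageProfile(sample_id=sample_id, replicate_index=0,
                           coverage=np.asarray(cov, float))


def _tent_coverage(gm: GeneOrderMap, terminus_bp: int, c: float, R: float):
    d = circular_distance(gm.midpoints, terminus_bp, gm.genome_length)
    return c + (2.0 * R / gm.genome_length) * d


@pytest.fixture
def gm100():
    genes = pd.DataFrame({
        "gene_id": [f"g{i:03d}" for i in range(100)],
        "start": np.arange(100) * 1000,
        "end": np.arange(100) * 1000 + 800,
    })
    return GeneOrderMap(reference_id="r", genome_length=100_000, genes=genes)


class TestCircularMinimum:
    def test_noiseless_tent_minimum(self, gm100):
        cov = _tent_coverage(gm100, terminus_bp=40_400, c=4.0, R=1.0)
        pos = circular_minimum_position(_profile(cov), gm100, window=1)
        assert pos == 40_400  # midpoint of gene 40

    def test_flat_profile_warns_and_returns_first_gene(self, gm100):
        with pytest.warns(DegenerateMinimumWarning):
            pos = circular_minimum_position(_profile(np.full(100, 5.0)), gm100, 5)
        assert pos == 400

    def test_window_must_be_odd(self, gm100):
        with pytest.raises(ValueError):
            circular_minimum_position(_profile(np.ones(100)), gm100, window=4)

    def test_smoothing_wraps_circularly(self, gm100):
        # dip split across the origin: true smoothed minimum is at the wrap
        cov = np.full(100, 5.0)
        cov[[98, 99, 0, 1]] = 1.0
        pos = circular_minimum_position(_profile(cov), gm100, window=3)
        assert pos in (98_400, 99_400, 400, 1_400)


class TestBestFitTerminus:
    def test_noiseless_tent_recovered_exactly(self, gm100):
        cov = _tent_coverage(gm100, terminus_bp=70_400, c=3.0, R=0.7)
        assert best_fit_terminus(_profile(cov), gm100) == 70_400

    def test_localizes_under_poisson_noise(self):
        """A 30x profile (the depth of a typical pre-rarefaction sample)
        localizes the terminus within 2% of the circumference."""
        cfg = SimulationConfig(true_R=0.8, c_true=5.0,
                               total_reads=int(30 * 560_000 / 150), seed=21)
        gm = synthetic_gene_order(cfg)
        lam = expected_gene_coverage(cfg, gm)
        scale = 30.0 / lam.mean()
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            counts = rng.poisson(lam * scale * gm.gene_lengths / 150.0)
            cov = counts * 150.0 / gm.gene_lengths
            pos = best_fit_terminus(_profile(cov), gm)
            err = circular_distance(pos, cfg.terminus_bp, cfg.genome_length)
            hits += err <= 0.02 * cfg.genome_length
        assert hits >= 18


class TestFixedTerminus:
    def test_ordinary_median_away_from_wrap(self):
        assert fixed_terminus([1000, 1200, 1100], 3000) == 1100

    def test_circular_median_across_the_origin(self):
        # brute force over the three candidates puts the median at 0
        assert fixed_terminus([2900, 0, 100], 3000) == 0

    def test_single_sample_identity(self):
        assert fixed_terminus([777], 3000) == 777

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fixed_terminus([], 3000)


class TestTentFit:
    def test_noiseless_exact_recovery(self, gm100):
        L = gm100.genome_length
        cov = _tent_coverage(gm100, 40_400, c=4.0, R=1.0)
        fit = fit_tent(_profile(cov), gm100, 40_400)
        assert fit.slope_per_bp == pytest.approx(2.0 / L, rel=1e-9)
        assert fit.c_fit == pytest.approx(4.0, rel=1e-9)
        assert standardize_slope(fit, L) == pytest.approx(1.0, rel=1e-9)

    def test_flat_profile_gives_zero_slope(self, gm100):
        fit = fit_tent(_profile(np.full(100, 5.0)), gm100, 40_400)
        assert fit.slope_per_bp == pytest.approx(0.0, abs=1e-15)
        assert fit.c_fit == pytest.approx(5.0)

    def test_too_few_genes_rejected(self):
        genes = pd.DataFrame({"gene_id": ["a", "b"], "start": [0, 100],
                              "end": [50, 150]})
        gm = GeneOrderMap(reference_id="r", genome_length=200, genes=genes)
        with pytest.raises(ValueError, match="3 genes"):
            fit_tent(_profile([1.0, 2.0]), gm, 0)

    @pytest.mark.parametrize("b,L,expected", [
        (0.0, 1_600_000, 0.0),
        (4e-7, 1_600_000, 0.32),
    ])
    def test_standardize_arithmetic(self, b, L, expected):
        from replicore import TentFit
        assert standardize_slope(
            TentFit(terminus_bp=0, c_fit=1.0, slope_per_bp=b, rss=0.0), L
        ) == pytest.approx(expected)


class TestAggregate:
    def test_mean_and_se(self):
        r, se, qc = aggregate_r_obs([0.30, 0.32, 0.34])
        assert r == pytest.approx(0.32)
        assert se == pytest.approx(0.02 / np.sqrt(3), rel=1e-6)
        assert qc == frozenset()

    def test_negative_mean_flagged(self):
        r, se, qc = aggregate_r_obs([-0.1, -0.1, -0.1])
        assert r == pytest.approx(-0.1)
        assert QC_NEGATIVE_SLOPE in qc

    def test_single_replicate_has_undefined_se(self):
        r, se, qc = aggregate_r_obs([0.5])
        assert r == 0.5 and np.isnan(se)


class TestPipeline:
    def _batch(self, n_samples, true_R, seed, total_reads=40_000, **cfg_kw):
        tables, cfgs = [], []
        for i in range(n_samples):
            cfg = SimulationConfig(true_R=true_R, total_reads=total_reads,
                                   seed=seed + i, **cfg_kw)
            t, _ = simulate_read_table(cfg, sample_id=f"s{i}")
            tables.append(t)
            cfgs.append(cfg)
        return tables, cfgs

    def test_single_sample_batch_uses_its_own_minimum(self):
        tables, cfgs = self._batch(1, 0.8, seed=3)
        gm = synthetic_gene_order(cfgs[0])
        plan = RarefactionPlan("e", depth_reads=18_000, n_replicates=3, seed=0)
        (est,) = estimate_replication(tables, gm, plan)
        from replicore.rarefaction import rarefied_coverage_matrix

        cov = rarefied_coverage_matrix(tables[0], gm, plan).mean(axis=0)
        assert est.terminus_bp == best_fit_terminus(_profile(cov), gm)

    def test_under_depth_samples_flagged_not_dropped(self):
        tables, cfgs = self._batch(2, 0.5, seed=5)
        small = dataclasses.replace(
            tables[0], sample_id="tiny",
            records=tables[0].records.iloc[:100],
        )
        gm = synthetic_gene_order(cfgs[0])
        plan = RarefactionPlan("e", depth_reads=18_000, n_replicates=3, seed=0)
        ests = estimate_replication(tables + [small], gm, plan)
        by_id = {e.sample_id: e for e in ests}
        assert "below_min_coverage" in by_id["tiny"].qc
        assert np.isnan(by_id["tiny"].R_obs)
        assert by_id["s0"].qc == frozenset()

    def test_all_samples_below_depth_is_an_error(self):
        tables, cfgs = self._batch(2, 0.5, seed=5, total_reads=1000)
        gm = synthetic_gene_order(cfgs[0])
        plan = RarefactionPlan("e", depth_reads=18_000, n_replicates=3, seed=0)
        with pytest.raises(ValueError, match="no samples at depth"):
            estimate_replication(tables, gm, plan)

    def test_flat_coverage_yields_r_near_zero(self):
        tables, cfgs = self._batch(3, 0.0, seed=8)
        gm = synthetic_gene_order(cfgs[0])
        plan = RarefactionPlan("e", depth_reads=18_000, n_replicates=10, seed=1)
        ests = estimate_replication(tables, gm, plan, terminus_bp=400_000)
        for e in ests:
            assert abs(e.R_obs) <= 2 * e.se_R_obs + 0.05

    def test_rotation_equivariance(self, gm100):
        """Rotating all coordinates by delta shifts the terminus and leaves
        R_obs unchanged."""
        delta = 37_000
        L = gm100.genome_length
        rng = np.random.default_rng(17)
        cov = _tent_coverage(gm100, 40_400, c=5.0, R=0.6) + rng.normal(0, 0.3, 100)
        cov = np.clip(cov, 0, None)
        prof = _profile(cov)
        t0 = best_fit_terminus(prof, gm100)
        fit0 = fit_tent(prof, gm100, t0)

        rolled = gm100.genes.copy()
        rolled["start"] = (rolled["start"] + delta) % L
        rolled["end"] = rolled["start"] + 800
        gm_rot = GeneOrderMap(reference_id="r", genome_length=L, genes=rolled)
        # genes re-sort by new start; permute coverage accordingly
        order = rolled.sort_values("start").index.to_numpy()
        prof_rot = _profile(cov[order])
        t1 = best_fit_terminus(prof_rot, gm_rot)
        fit1 = fit_tent(prof_rot, gm_rot, t1)

        assert (t1 - t0) % L == delta % L
        assert standardize_slope(fit1, L) == pytest.approx(
            standardize_slope(fit0, L), rel=1e-9
        )

    def test_scale_equivariance(self, gm100):
        rng = np.random.default_rng(23)
        cov = np.clip(
            _tent_coverage(gm100, 40_400, 5.0, 0.6) + rng.normal(0, 0.3, 100),
            0, None,
        )
        f1 = fit_tent(_profile(cov), gm100, 40_400)
        f3 = fit_tent(_profile(3.0 * cov), gm100, 40_400)
        assert f3.slope_per_bp == pytest.approx(3 * f1.slope_per_bp, rel=1e-9)
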