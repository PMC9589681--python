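"""DCJ distance (vs exhaustive BFS oracle), coverage gaps, ranking."""

import itertools
import random
from collections import deque

import numpy as np
import pytest

from replicore import (
    CoverageProfile,
    SignedGeneOrder,
    count_coverage_gaps,
    dcj_distance,
    mean_dcj,
    rank_references,
)
from replicore.refselect import _adjacencies


def circular(genome_id, signed_genes):
    return SignedGeneOrder(
        genome_id=genome_id,
        chromosomes=[[(str(abs(g)), 1 if g > 0 else -1) for g in signed_genes]],
        circular=[True],
    )


def _matching(order):
    adj, _ = _adjacencies(order)
    return frozenset(frozenset(e) for e in adj)


def bfs_dcj(a, b):
    """Exhaustive oracle: BFS over single DCJ operations on adjacency sets.

    A genome of circular chromosomes is a perfect matching on gene
    extremities; one DCJ operation cuts two adjacencies and rejoins the
    four extremities the other way.
    """
    start, goal = _matching(a), _matching(b)
    if start == goal:
        return 0
    seen = {start}
    frontier = deque([(start, 0)])
    while frontier:
        cur, d = frontier.popleft()
        for e1, e2 in itertools.combinations(cur, 2):
            p, q = tuple(e1)
            r, s = tuple(e2)
            for n1, n2 in (((p, r), (q, s)), ((p, s), (q, r))):
                nxt = (cur - {e1, e2}) | {frozenset(n1), frozenset(n2)}
                if nxt == goal:
                    return d + 1
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append((nxt, d + 1))
    raise AssertionError("unreachable")


def _random_circular(genome_id, n, rng):
    perm = list(range(1, n + 1))
    rng.shuffle(perm)
    return circular(genome_id, [p * rng.choice([1, -1]) for p in perm])


class TestDCJ:
    def test_identity(self):
        a = circular("a", [1, 2, 3])
        assert dcj_distance(a, circular("b", [1, 2, 3])) == 0

    def test_single_inversion_costs_one(self):
        a = circular("a", [1, 2, 3])
        b = circular("b", [1, -2, 3])
        assert dcj_distance(a, b) == 1
        assert bfs_dcj(a, b) == 1

    def test_matches_bfs_oracle_on_random_pairs(self):
        rng = random.Random(0)
        for _ in range(100):
            n = rng.randint(2, 5)
            a = _random_circular("a", n, rng)
            b = _random_circular("b", n, rng)
            assert dcj_distance(a, b) == bfs_dcj(a, b)

    def test_metric_properties(self):
        rng = random.Random(1)
        for _ in range(40):
            n = rng.randint(3, 5)
            a = _random_circular("a", n, rng)
            b = _random_circular("b", n, rng)
            c = _random_circular("c", n, rng)
            dab, dba = dcj_distance(a, b), dcj_distance(b, a)
            assert dab == dba
            assert (dab == 0) == (_matching(a) == _matching(b))
            assert dab <= dcj_distance(a, c) + dcj_distance(c, b)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicates"):
            SignedGeneOrder("a", [[("1", 1), ("1", 1)]], [True])

    def test_restriction_to_shared_genes(self):
        a = circular("a", [1, 2, 3, 4])
        b = circular("b", [1, 2, 3])
        with pytest.warns(UserWarning, match="private"):
            assert dcj_distance(a, b) == 0

    def test_empty_shared_set_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            dcj_distance(circular("a", [1]), circular("b", [2]))

    def test_linear_vs_circular_single_gene(self):
        lin = SignedGeneOrder("l", [[("1", 1), ("2", 1)]], [False])
        circ = circular("c", [1, 2])
        # one cut or join separates the two topologies
        assert dcj_distance(lin, circ) == bfs_dcj_linear_ok(lin, circ)


def bfs_dcj_linear_ok(a, b):
    """Oracle generalized to telomeres: adjacencies plus free extremities.

    Represent a genome as its adjacency set; a DCJ may also cut one
    adjacency into two telomeres or join two telomeres.
    """
    def state(order):
        adj, _ = _adjacencies(order)
        return frozenset(frozenset(e) for e in adj)

    def neighbors(cur):
        edges = list(cur)
        covered = {x for e in edges for x in e}
        singles = all_ext - covered
        for e1, e2 in itertools.combinations(edges, 2):
            p, q = tuple(e1)
            r, s = tuple(e2)
            yield (cur - {e1, e2}) | {frozenset((p, r)), frozenset((q, s))}
            yield (cur - {e1, e2}) | {frozenset((p, s)), frozenset((q, r))}
        for e in edges:  # cut into two telomeres
            yield cur - {e}
        for p, q in itertools.combinations(singles, 2):  # join telomeres
            yield cur | {frozenset((p, q))}
        for e in edges:  # excision/reinsertion with one telomere
            p, q = tuple(e)
            for t in singles:
                yield (cur - {e}) | {frozenset((p, t))}
                yield (cur - {e}) | {frozenset((q, t))}

    genes = {g for chrom in a.chromosomes for g, _ in chrom}
    all_ext = {(g, e) for g in genes for e in ("t", "h")}
    start, goal = state(a), state(b)
    if start == goal:
        return 0
    seen = {start}
    frontier = deque([(start, 0)])
    while frontier:
        cur, d = frontier.popleft()
        for nxt in neighbors(cur):
            if nxt == goal:
                return d + 1
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, d + 1))
    raise AssertionError("unreachable")


class TestMeanDCJ:
    def test_pool_of_clones_is_zero(self):
        a = circular("a", [1, 2, 3])
        pool = [circular("b", [1, 2, 3]), circular("c", [1, 2, 3])]
        assert mean_dcj(a, pool) == 0.0

    def test_arithmetic_mean_of_oracle_distances(self):
        rng = random.Random(7)
        a = _random_circular("a", 5, rng)
        pool = [_random_circular(f"p{i}", 5, rng) for i in range(3)]
        expected = np.mean([bfs_dcj(a, g) for g in pool])
        assert mean_dcj(a, pool) == pytest.approx(expected)

    def test_candidate_excluded_from_its_own_pool(self):
        a = circular("a", [1, 2, 3])
        pool = [a, circular("b", [1, -2, 3])]
        assert mean_dcj(a, pool) == 1.0


def _profile(cov):
    return CoverageProfile(sample_id="p", replicate_index=0,
                           coverage=np.asarray(cov, float))


class TestCoverageGaps:
    def test_single_long_run(self):
        cov = np.ones(100)
        cov[10:25] = 0.0
        assert count_coverage_gaps(_profile(cov), min_run=10) == 1

    def test_all_positive_has_no_gaps(self):
        assert count_coverage_gaps(_profile(np.ones(50)), min_run=5) == 0

    def test_wraparound_run_counted_once(self):
        cov = np.ones(100)
        cov[[98, 99, 0, 1, 2]] = 0.0
        assert count_coverage_gaps(_profile(cov), min_run=5) == 1

    def test_short_runs_ignored(self):
        cov = np.ones(100)
        cov[10:14] = 0.0
        assert count_coverage_gaps(_profile(cov), min_run=5) == 0

    def test_rotation_invariant(self):
        rng = np.random.default_rng(3)
        cov = (rng.random(60) > 0.3).astype(float)
        base = count_coverage_gaps(_profile(cov), min_run=3)
        for k in range(1, 60, 7):
            assert count_coverage_gaps(_profile(np.roll(cov, k)), min_run=3) == base


class TestRanking:
    def test_fewer_gaps_ranks_first(self):
        r = rank_references([("A", 1.0, 5, 50.0), ("B", 1.2, 2, 50.0)], top_k=6)
        assert list(r.table["genome_id"]) == ["B", "A"]

    def test_recruitment_breaks_gap_ties(self):
        r = rank_references([("A", 1.0, 3, 40.0), ("B", 1.2, 3, 60.0)], top_k=6)
        assert list(r.table["genome_id"]) == ["B", "A"]

    def test_identical_triples_alphabetical(self):
        r = rank_references([("B", 1.0, 3, 40.0), ("A", 1.0, 3, 40.0)], top_k=6)
        assert list(r.table["genome_id"]) == ["A", "B"]
        assert list(r.table["rank"]) == [1, 2]

    def test_shortlist_by_lowest_mean_dcj(self):
        cands = [(f"G{i}", float(i), 0, 50.0) for i in range(10)]
        r = rank_references(cands, top_k=6)
        assert set(r.table["genome_id"]) == {f"G{i}" for i in range(6)}
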