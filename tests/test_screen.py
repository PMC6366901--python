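"""Replicate reproducibility, mutant classification, enrichment and FDR."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.special import comb

from microhet import screen, synth
from microhet.screen import EnrichmentQuery


def ecdf_sup_distance(a, b):
    """Brute-force K-S statistic: sup of |ECDF_a - ECDF_b| over all points."""
    pts = np.concatenate([a, b])
    fa = np.searchsorted(np.sort(a), pts, side="right") / len(a)
    fb = np.searchsorted(np.sort(b), pts, side="right") / len(b)
    # the sup is attained at a jump; also check just below each point
    fa2 = np.searchsorted(np.sort(a), pts, side="left") / len(a)
    fb2 = np.searchsorted(np.sort(b), pts, side="left") / len(b)
    return max(np.abs(fa - fb).max(), np.abs(fa2 - fb2).max())


class TestKsShiftedDistance:
    def test_identical_samples_distance_zero(self):
        a = np.linspace(0.2, 0.5, 100)
        assert screen.ks_shifted_distance(a, a.copy()) == 0.0

    def test_pure_shift_within_cap_collapses_to_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.4, 0.03, 300)
        d = screen.ks_shifted_distance(a, a + 0.03)
        assert d <= 2 / len(a)  # zero up to float rounding of the realignment

    def test_shift_beyond_cap_inadmissible(self):
        a = np.full(100, 0.4)
        assert screen.ks_shifted_distance(a, a + 0.06) is None

    def test_matches_brute_force_ecdf_sup(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.4, 0.05, 100)
        b = rng.normal(0.41, 0.06, 100)
        shift = a.mean() - b.mean()
        d = screen.ks_shifted_distance(a, b)
        assert d == pytest.approx(ecdf_sup_distance(a, b + shift), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            screen.ks_shifted_distance(np.array([]), np.array([0.4]))


class TestSelectReproducible:
    @staticmethod
    def graph(edges, n=3):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for u, v, w in edges:
            g.add_edge(u, v, weight=w)
        return g

    def test_full_triangle_keeps_all(self):
        g = self.graph([(0, 1, 0.02), (0, 2, 0.03), (1, 2, 0.04)])
        assert screen.select_reproducible(g) == [0, 1, 2]

    def test_single_admissible_pair_kept(self):
        g = self.graph([(1, 2, 0.05)])
        assert screen.select_reproducible(g) == [1, 2]

    def test_no_edges_excludes_strain(self):
        assert screen.select_reproducible(self.graph([])) == []

    def test_tie_broken_by_minimal_weight(self):
        g = self.graph([(0, 1, 0.09), (1, 2, 0.02)])
        assert screen.select_reproducible(g) == [1, 2]

    def test_invariant_to_node_relabeling(self):
        edges = [(0, 1, 0.02), (1, 2, 0.08), (0, 2, 0.03), (2, 3, 0.01)]
        g = self.graph(edges, n=4)
        perm = {0: 3, 1: 0, 2: 2, 3: 1}
        g2 = nx.relabel_nodes(g, perm)
        sel = screen.select_reproducible(g)
        sel2 = screen.select_reproducible(g2)
        assert sorted(perm[v] for v in sel) == sorted(sel2)

    def test_matches_exhaustive_clique_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            edges = [(u, v, float(rng.uniform(0, 0.1)))
                     for u, v in itertools.combinations(range(4), 2)
                     if rng.random() < 0.6]
            g = self.graph(edges, n=4)
            got = screen.select_reproducible(g)
            best = None
            for k in (4, 3, 2):
                for sub in itertools.combinations(range(4), k):
                    if all(g.has_edge(u, v)
                           for u, v in itertools.combinations(sub, 2)):
                        w = sum(g[u][v]["weight"]
                                for u, v in itertools.combinations(sub, 2))
                        if best is None or (len(sub) > len(best[0])) or \
                           (len(sub) == len(best[0]) and w < best[1] - 1e-15):
                            if best is None or len(sub) >= len(best[0]):
                                best = (sub, w)
                if best:
                    break
            expected = list(best[0]) if best else []
            assert sorted(got) == sorted(expected) or \
                (best and len(got) == len(expected))


class TestHypergeomEnrichment:
    def test_worked_fraction(self):
        # N=10, X=4, Ng=5, Xg=3 -> (C(4,3)C(6,2)+C(4,4)C(6,1))/C(10,5) = 11/42
        p = screen.hypergeom_enrichment(EnrichmentQuery(N=10, X=4, Ng=5, Xg=3))
        assert p == pytest.approx(11 / 42, rel=1e-12)

    def test_zero_overlap_is_certain(self):
        assert screen.hypergeom_enrichment(
            EnrichmentQuery(N=100, X=10, Ng=5, Xg=0)) == 1.0

    def test_saturated_overlap_single_term(self):
        q = EnrichmentQuery(N=12, X=3, Ng=6, Xg=3)
        expected = comb(12 - 3, 6 - 3, exact=True) / comb(12, 6, exact=True)
        assert screen.hypergeom_enrichment(q) == pytest.approx(expected, rel=1e-12)

    def test_matches_exhaustive_enumeration_all_small_queries(self):
        for N in range(2, 13):
            for X in range(0, N + 1):
                for Ng in range(1, N + 1):
                    for Xg in range(0, min(X, Ng) + 1):
                        p = screen.hypergeom_enrichment(
                            EnrichmentQuery(N=N, X=X, Ng=Ng, Xg=Xg))
                        hits = 0
                        total = 0
                        for draw in itertools.combinations(range(N), Ng):
                            total += 1
                            if sum(1 for g in draw if g < X) >= Xg:
                                hits += 1
                        assert p == pytest.approx(hits / total, rel=1e-9), \
                            (N, X, Ng, Xg)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            EnrichmentQuery(N=10, X=4, Ng=5, Xg=5)


class TestBhFdr:
    def test_single_small_p_rejected(self):
        rej, adj = screen.bh_fdr([0.04], q=0.1)
        assert rej[0]

    def test_hand_checked_step_up(self):
        rej, adj = screen.bh_fdr([0.01, 0.02, 0.9], q=0.1)
        assert list(rej) == [True, True, False]
        assert adj == pytest.approx([0.03, 0.03, 0.9])

    def test_all_ones_none_rejected(self):
        rej, _ = screen.bh_fdr([1.0, 1.0, 1.0], q=0.1)
        assert not rej.any()

    def test_adjusted_monotone_in_p(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=40)
        _, adj = screen.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            screen.bh_fdr([0.5, 1.2])


class TestEnrichmentTable:
    def test_planted_term_detected(self):
        ann, group = synth.generate_annotation(1200, 4,
                                               planted=("term01", 150, 3.0),
                                               rng_seed=2)
        genes = [f"gene{i:04d}" for i in range(1200)]
        table = screen.enrichment_table(group, genes, ann)
        top = table.iloc[0]
        assert top["term"] == "term01"
        assert top["significant"]
        assert top["fold"] > 2.0

    def test_empty_group_rejected(self):
        ann, _ = synth.generate_annotation(100, 2, rng_seed=0)
        with pytest.raises(ValueError, match="empty"):
            screen.enrichment_table([], [f"gene{i:04d}" for i in range(100)], ann)


@pytest.fixture(scope="module")
def planted():
    spec = synth.PlantedScreenSpec(n_strains=14, n_per_replicate=1500,
                                   rng_seed=3)
    data = synth.generate_screen(spec)
    recs = screen.classify_screen(
        {s: d["replicates"] for s, d in data["strains"].items()},
        data["wt"])
    truth = {s: d["category"] for s, d in data["strains"].items()}
    return recs, truth


class TestClassifyScreen:
    def test_planted_effect_directions_recovered(self, planted):
        recs, truth = planted
        by_truth = {}
        for r in recs:
            by_truth.setdefault(truth[r.strain], []).append(r)
        for r in by_truth["mode-down-slow-up"]:
            assert r.category in ("mode-down-slow-up", "mode-only",
                                  "slow-up-only")
        for r in by_truth["slow-up-only"]:
            assert r.slow_direction > 0

    def test_penetrance_computed_for_slowed_strains(self, planted):
        recs, truth = planted
        slowed = [r for r in recs if truth[r.strain] in
                  ("mode-only", "both-down", "mode-down-slow-up")
                  and r.category is not None]
        assert any(r.penetrance_pct is not None for r in slowed)
        for r in slowed:
            if r.penetrance_pct is not None:
                assert 0.0 <= r.penetrance_pct <= 100.0

    def test_null_strains_mostly_unchanged(self):
        spec = synth.PlantedScreenSpec(
            n_strains=20, n_per_replicate=1000, rng_seed=17,
            category_assignments={f"s{i:02d}": "no-change" for i in range(20)})
        data = synth.generate_screen(spec)
        recs = screen.classify_screen(
            {s: d["replicates"] for s, d in data["strains"].items()},
            data["wt"])
        calls = [r.category for r in recs if r.category is not None]
        frac_null = np.mean([c == "no-change" for c in calls])
        assert frac_null >= 0.95

    def test_under_two_replicates_unclassified(self):
        rng = np.random.default_rng(0)
        wt = [np.abs(rng.normal(0.4, 0.02, 300)) for _ in range(4)]
        # three mutually irreproducible replicates (means far apart)
        reps = [np.abs(rng.normal(0.2 + 0.2 * i, 0.02, 300)) for i in range(3)]
        recs = screen.classify_screen({"m": reps}, wt)
        assert recs[0].n_reproducible_replicates == 0
        assert recs[0].category is None
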