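import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from formula_nettarget import (
    BenchmarkConfig,
    GeneSetCollection,
    PriorModel,
    bh_adjust,
    compare_bcg_formula,
    enrich_gene_sets,
    generate_benchmark,
    hypergeom_tail,
    screen_bcg,
)

from tests.conftest import bh_adjust_stepup, hypergeom_tail_bruteforce


class TestHypergeomTail:
    def test_hand_derived_values(self):
        assert hypergeom_tail(10, 5, 4, 4) == pytest.approx(
            5 / 210, abs=1e-9
        )
        assert hypergeom_tail(20, 5, 5, 2) == pytest.approx(
            0.366099, abs=1e-6
        )

    def test_k_zero_is_one(self):
        assert hypergeom_tail(100, 10, 5, 0) == 1.0

    def test_matches_bruteforce_on_grid(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            N = int(rng.integers(1, 41))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom_tail(N, K, n, k) == pytest.approx(
                hypergeom_tail_bruteforce(N, K, n, k), abs=1e-12
            )

    def test_symmetry_in_K_and_n(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            N = int(rng.integers(2, 41))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom_tail(N, K, n, k) == pytest.approx(
                hypergeom_tail(N, n, K, k), rel=1e-12
            )

    def test_bound_violations_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(10, 11, 5, 1)
        with pytest.raises(ValueError):
            hypergeom_tail(10, 5, 11, 1)
        with pytest.raises(ValueError):
            hypergeom_tail(10, 5, 4, 5)


class TestBHAdjust:
    def test_worked_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert bh_adjust([0.005, 0.5]) == pytest.approx([0.01, 0.5])

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_stepup_oracle(self, pvals):
        np.testing.assert_allclose(
            bh_adjust(pvals), bh_adjust_stepup(pvals), atol=1e-12
        )

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=2,
            max_size=20,
        ),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_permutation_equivariance(self, pvals, rnd):
        idx = list(range(len(pvals)))
        rnd.shuffle(idx)
        base = bh_adjust(pvals)
        shuffled = bh_adjust([pvals[i] for i in idx])
        assert shuffled == pytest.approx([base[i] for i in idx])

    def test_sorted_input_gives_nondecreasing_output(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.random(30))
        adj = bh_adjust(p)
        assert all(a <= b + 1e-15 for a, b in zip(adj, adj[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEnrichGeneSets:
    def _collection(self):
        coll = GeneSetCollection()
        coll.add("S1", "d", {f"A{i}" for i in range(10)})
        coll.add("S2", "d", {f"B{i}" for i in range(10)})
        coll.add("S3", "d", {f"C{i}" for i in range(10)})
        return coll

    def test_self_enrichment_is_minimal(self):
        coll = self._collection()
        res = enrich_gene_sets({f"A{i}" for i in range(10)}, coll)
        by_name = {r.set_name: r for r in res}
        assert by_name["S1"].k == by_name["S1"].n == 10
        assert res[0].set_name == "S1"
        assert by_name["S1"].p_value < by_name["S2"].p_value

    def test_disjoint_query_gives_p_one(self):
        coll = self._collection()
        res = {r.set_name: r for r in enrich_gene_sets(
            {f"A{i}" for i in range(10)}, coll
        )}
        assert res["S2"].k == 0
        assert res["S2"].p_value == 1.0

    def test_composition_matches_per_set_tail(self):
        rng = np.random.default_rng(9)
        universe = [f"G{i}" for i in range(200)]
        coll = GeneSetCollection()
        for i in range(10):
            coll.add(f"S{i}", "d",
                     rng.choice(universe, size=25, replace=False))
        query = set(rng.choice(universe, size=20, replace=False))
        bg = set(universe)
        res = enrich_gene_sets(query, coll, background=bg)
        for r in res:
            assert r.p_value == pytest.approx(
                hypergeom_tail(r.N, r.K, r.n, r.k), rel=1e-12
            )

    def test_empty_effective_query_rejected(self):
        coll = self._collection()
        with pytest.raises(ValueError):
            enrich_gene_sets({"ZZZ"}, coll, background={"A1", "A2"})


class TestScreenBCG:
    def test_planted_compounds_recovered_exactly(self, benchmark):
        dataset, truth = benchmark
        screen = screen_bcg(
            dataset.profiles, dataset.syndromes, dataset.compounds,
            dataset.herbs, alpha=0.05, min_syndromes=1,
        )
        assert screen.selected_bcg == truth.bioactive_compounds
        assert screen.selection_rule["alpha"] == 0.05

    def test_alpha_one_selects_flagged_overlapping_compounds(self, benchmark):
        dataset, truth = benchmark
        screen = screen_bcg(
            dataset.profiles, dataset.syndromes, dataset.compounds,
            dataset.herbs, alpha=0.999999, min_syndromes=1,
        )
        # every flag-passing compound whose profile touches >= 1 syndrome gene
        jun = {h.herb_id for h in dataset.herbs if h.role == "JUN"}
        expected = sorted(
            p.compound_id
            for p in dataset.profiles
            for c in [next(c for c in dataset.compounds
                           if c.compound_id == p.compound_id)]
            if (c.quality_control_marker or set(c.herb_ids) & jun)
            and any(
                p.gene_set & dataset.syndromes.genes(s)
                for s in dataset.syndromes.names()
            )
        )
        assert screen.selected_bcg == expected

    def test_min_syndromes_zero_selects_all_flagged(self, benchmark):
        dataset, truth = benchmark
        screen = screen_bcg(
            dataset.profiles, dataset.syndromes, dataset.compounds,
            dataset.herbs, min_syndromes=0,
        )
        assert screen.selected_bcg == truth.bioactive_compounds

    def test_disjoint_profile_never_selected(self, benchmark):
        dataset, _ = benchmark
        from formula_nettarget import TargetProfile

        syn_genes = dataset.syndromes.all_genes()
        clean = tuple(f"ZZ{i}" for i in range(50))
        assert not (set(clean) & syn_genes)
        profiles = [TargetProfile("C001", clean, max_rank=100)]
        screen = screen_bcg(
            profiles, dataset.syndromes, dataset.compounds, dataset.herbs
        )
        assert screen.selected_bcg == []

    def test_invalid_alpha_rejected(self, benchmark):
        dataset, _ = benchmark
        with pytest.raises(ValueError):
            screen_bcg(
                dataset.profiles, dataset.syndromes, dataset.compounds,
                dataset.herbs, alpha=0.0,
            )


class TestCompareBCGFormula:
    def test_identity_comparison_has_empty_differences(self, benchmark):
        dataset, _ = benchmark
        prior = PriorModel.from_profiles(dataset.profiles)
        report = compare_bcg_formula(
            dataset.profiles, dataset.profiles, dataset.syndromes, prior
        )
        assert report.bcg_only == []
        assert report.formula_only == []

    def test_planted_syndrome_shared_by_bcg_and_formula(self, benchmark):
        dataset, truth = benchmark
        prior = PriorModel.from_profiles(dataset.profiles)
        bcg = [
            p for p in dataset.profiles
            if p.compound_id in set(truth.bioactive_compounds)
        ]
        report = compare_bcg_formula(
            bcg, dataset.profiles, dataset.syndromes, prior
        )
        assert set(report.per_set["set_name"]) == set(
            dataset.syndromes.names()
        )

    def test_empty_bcg_rejected(self, benchmark):
        dataset, _ = benchmark
        prior = PriorModel.from_profiles(dataset.profiles)
        with pytest.raises(ValueError):
            compare_bcg_formula(
                [], dataset.profiles, dataset.syndromes, prior
            )
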