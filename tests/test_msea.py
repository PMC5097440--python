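import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import mergenet as mg
from mergenet.io import ValidationError
from mergenet.msea import TailP


def chi_oracle(values, cutoffs, tail_probs, kappa=1.0):
    """Straight transcription of the statistic, independent of the package
    internals (plain python loops)."""
    m = len(values)
    total = 0.0
    for c, p in zip(cutoffs, tail_probs):
        observed = sum(1 for v in values if v >= c)
        expected = m * p
        total += (observed - expected) / (math.sqrt(expected) + kappa)
    return total


class TestQuantileScheme:
    def test_single_point_is_the_median(self):
        values = np.arange(1.0, 101.0)
        scheme = mg.build_quantile_scheme(values, n_points=1)
        assert scheme.cutoffs == pytest.approx([np.median(values)])

    def test_constant_values_collapse_to_one_cutoff(self):
        scheme = mg.build_quantile_scheme(np.full(50, 2.0), n_points=10)
        assert scheme.n == 1

    def test_ten_points_match_direct_quantiles(self):
        values = np.arange(1.0, 1001.0)
        scheme = mg.build_quantile_scheme(values, n_points=10)
        tails = np.geomspace(0.5, max(10 / 1000, 1e-4), 10)
        expected = np.unique(np.quantile(values, 1 - tails))
        assert scheme.n == 10
        assert np.all(np.diff(scheme.cutoffs) > 0)
        assert scheme.cutoffs == pytest.approx(expected)

    def test_invalid_n_points_rejected(self):
        with pytest.raises(ValueError):
            mg.build_quantile_scheme(np.arange(10.0), n_points=0)


class TestEnrichmentStatistic:
    def test_single_cutoff_formula(self):
        # m=16 member markers, one cutoff with background tail 0.25:
        # E = 4, O = 9 -> (9-4)/(sqrt(4)+1) = 5/3
        scheme = mg.QuantileScheme(np.array([2.0]))
        values = [2.5] * 9 + [0.5] * 7
        chi = mg.enrichment_statistic(values, scheme, [0.25])
        assert chi == pytest.approx(5 / 3)

    def test_additive_across_cutoffs(self):
        # (O,E) = (6,4) and (3,1): 2/3 + 2/2 = 5/3
        scheme = mg.QuantileScheme(np.array([1.0, 2.0]))
        values = [2.5] * 3 + [1.5] * 3 + [0.5] * 2
        chi = mg.enrichment_statistic(values, scheme, [0.5, 0.125])
        assert chi == pytest.approx(5 / 3)

    def test_zero_when_members_match_background(self):
        rng = np.random.default_rng(0)
        values = rng.random(200) * 5
        scheme = mg.build_quantile_scheme(values, 8)
        tails = mg.background_tail_fractions(values, scheme)
        assert mg.enrichment_statistic(values, scheme, tails) == pytest.approx(0.0)

    def test_empty_member_list_rejected(self):
        scheme = mg.QuantileScheme(np.array([1.0]))
        with pytest.raises(ValidationError):
            mg.enrichment_statistic([], scheme, [0.5])

    @given(seed=st.integers(0, 50))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        study = rng.random(300) * 6
        members = rng.choice(study, 40, replace=False)

        def chi_for(transform):
            values = transform(study)
            scheme = mg.build_quantile_scheme(values, 6)
            tails = mg.background_tail_fractions(values, scheme)
            return mg.enrichment_statistic(transform(members), scheme, tails)

        assert chi_for(lambda x: x) == pytest.approx(
            chi_for(lambda x: np.expm1(x)), abs=1e-9
        )

    def test_adding_markers_below_all_cutoffs_never_increases_chi(self):
        rng = np.random.default_rng(1)
        study = rng.random(200) * 5 + 1.0
        scheme = mg.build_quantile_scheme(study, 6)
        tails = mg.background_tail_fractions(study, scheme)
        members = list(rng.choice(study, 20, replace=False))
        before = mg.enrichment_statistic(members, scheme, tails)
        after = mg.enrichment_statistic(members + [0.0, 0.0], scheme, tails)
        assert after <= before


class TestNullDistributions:
    def test_exhaustive_gene_null_matches_enumeration_oracle(self, small_universe):
        mgmap, assoc = small_universe
        scheme = mg.build_quantile_scheme(assoc, 4)
        tails = mg.background_tail_fractions(assoc, scheme)
        null = mg.hierarchical_null(mgmap, assoc, 2, scheme, exhaustive=True)
        genes = mgmap.gene_markers
        oracle = []
        for pair in itertools.combinations(sorted(genes), 2):
            markers = sorted(set(genes[pair[0]]) | set(genes[pair[1]]))
            values = [assoc.series[m] for m in markers]
            oracle.append(chi_oracle(values, scheme.cutoffs, tails))
        assert null.size == math.comb(len(genes), 2)
        assert np.sort(null) == pytest.approx(np.sort(oracle))

    def test_identical_values_give_constant_null(self):
        mgmap = mg.MarkerGeneMap.from_pairs(
            [(f"G{i}", f"m{i}") for i in range(5)]
        )
        assoc = mg.MarkerAssociationTable.from_pairs(
            [(f"m{i}", 1.0) for i in range(5)]
        )
        scheme = mg.build_quantile_scheme(assoc, 3)
        null = mg.hierarchical_null(mgmap, assoc, 2, scheme, exhaustive=True)
        assert np.allclose(null, null[0])

    def test_same_seed_reproduces_null(self, small_universe):
        mgmap, assoc = small_universe
        scheme = mg.build_quantile_scheme(assoc, 4)
        kwargs = dict(nperm=150, seed=42, exhaustive=False)
        a = mg.hierarchical_null(mgmap, assoc, 3, scheme, **kwargs)
        b = mg.hierarchical_null(mgmap, assoc, 3, scheme, **kwargs)
        assert np.array_equal(a, b)

    def test_marker_null_of_full_study_is_constant(self):
        assoc = mg.MarkerAssociationTable.from_pairs(
            [("m1", 1.0), ("m2", 2.0), ("m3", 3.0)]
        )
        scheme = mg.build_quantile_scheme(assoc, 2)
        null = mg.marker_label_null(assoc, 3, scheme)
        assert null.size == 1

    def test_marker_null_exhaustive_matches_enumeration(self):
        assoc = mg.MarkerAssociationTable.from_pairs(
            [(f"m{i}", float(i)) for i in range(6)]
        )
        scheme = mg.build_quantile_scheme(assoc, 3)
        tails = mg.background_tail_fractions(assoc, scheme)
        null = mg.marker_label_null(assoc, 2, scheme)
        values = assoc.values
        oracle = [
            chi_oracle([values[i], values[j]], scheme.cutoffs, tails)
            for i, j in itertools.combinations(range(6), 2)
        ]
        assert np.sort(null) == pytest.approx(np.sort(oracle))


class TestNullTailP:
    def test_observation_below_all_null_gives_p_one(self):
        null = np.linspace(1.0, 2.0, 999)
        tp = mg.null_tail_p(0.0, null)
        assert tp.p_freq == pytest.approx(1.0)
        assert tp.p_final == pytest.approx(1.0)

    def test_observation_at_null_mean_gives_z_zero(self):
        rng = np.random.default_rng(0)
        null = rng.standard_normal(5000)
        tp = mg.null_tail_p(float(null.mean()), null)
        assert tp.z == pytest.approx(0.0, abs=1e-12)
        assert tp.p_norm == pytest.approx(0.5)

    def test_gaussian_tail_against_monte_carlo_oracle(self):
        # the fitted Gaussian must recover the closed-form standard normal
        # tail from a large simulated null
        rng = np.random.default_rng(123)
        null = rng.standard_normal(100_000)
        tp = mg.null_tail_p(3.0, null)
        assert tp.z == pytest.approx(3.0, abs=0.05)
        assert tp.p_norm == pytest.approx(stats.norm.sf(3.0), rel=0.2)

    def test_p_final_switches_to_gaussian_only_when_b_zero(self):
        null = np.linspace(0.0, 1.0, 999)
        beyond = mg.null_tail_p(2.0, null)
        assert beyond.p_final == beyond.p_norm
        inside = mg.null_tail_p(0.5, null)
        assert inside.p_final == inside.p_freq

    def test_degenerate_null_scores_only_its_own_constant(self):
        tp = mg.null_tail_p(1.0, np.full(100, 1.0))
        assert tp.p_final == 1.0
        with pytest.raises(ValidationError):
            mg.null_tail_p(2.0, np.full(100, 1.0))

    @given(obs=st.floats(-5, 5), seed=st.integers(0, 50))
    def test_p_freq_bounds(self, obs, seed):
        null = np.random.default_rng(seed).standard_normal(99)
        tp = mg.null_tail_p(obs, null)
        assert 1 / 100 <= tp.p_freq <= 1.0
        assert tp.p_final > 0.0


class TestRunMsea:
    def test_whole_universe_set_is_null(self, small_universe):
        mgmap, assoc = small_universe
        sets = mg.GeneSetCollection.from_dict({"ALL": mgmap.genes})
        res = mg.run_msea(sets, mgmap, assoc, mg.MseaParams(nperm=200, seed=0))
        assert len(res) == 1
        assert res[0].chi == pytest.approx(0.0, abs=1e-12)
        assert res[0].p_final == 1.0

    def test_unmapped_set_skipped(self, small_universe):
        mgmap, assoc = small_universe
        sets = mg.GeneSetCollection.from_dict(
            {"KNOWN": ["G1", "G2"], "GHOST": ["ZZ1", "ZZ2"]}
        )
        res = mg.run_msea(sets, mgmap, assoc, mg.MseaParams(nperm=200, seed=0))
        assert [r.set_id for r in res] == ["KNOWN"]

    def test_same_seed_is_deterministic(self, small_universe):
        mgmap, assoc = small_universe
        sets = mg.GeneSetCollection.from_dict({"S": ["G1", "G3", "G5"]})
        params = mg.MseaParams(nperm=300, seed=5, exhaustive_limit=1)
        a = mg.run_msea(sets, mgmap, assoc, params)
        b = mg.run_msea(sets, mgmap, assoc, params)
        assert a == b

    def test_supergene_membership_resolved_after_merging(self, small_universe):
        mgmap, assoc = small_universe
        merged = mg.merge_genes_sharing_markers(mgmap, 0.3)
        assert "G1;G6" in merged.genes  # share m2, Jaccard 1/3
        sets = mg.GeneSetCollection.from_dict({"S": ["G1"]})
        res = mg.run_msea(sets, merged, assoc, mg.MseaParams(nperm=100, seed=0))
        assert len(res) == 1 and res[0].n_genes == 1  # G1 found inside its supergene

    def test_bh_fdr_monotone_in_sorted_p(self, small_universe):
        mgmap, assoc = small_universe
        sets = mg.GeneSetCollection.from_dict(
            {f"S{i}": [g] for i, g in enumerate(mgmap.genes)}
        )
        res = mg.run_msea(sets, mgmap, assoc, mg.MseaParams(nperm=200, seed=0))
        fdrs = [r.fdr for r in res]  # results sorted by p_final
        assert all(a <= b + 1e-12 for a, b in zip(fdrs, fdrs[1:]))


class TestStoufferMeta:
    def test_single_study_identity(self):
        z, p = mg.stouffer_meta([2.5])
        assert z == pytest.approx(2.5)
        assert p == pytest.approx(stats.norm.sf(2.5))

    def test_three_equal_studies(self):
        z, _ = mg.stouffer_meta([2.0, 2.0, 2.0])
        assert z == pytest.approx(2 * math.sqrt(3))

    def test_opposite_studies_cancel(self):
        z, p = mg.stouffer_meta([3.0, -3.0])
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    @given(z0=st.floats(-3, 3), k=st.integers(1, 10))
    def test_k_identical_studies_scale_as_sqrt_k(self, z0, k):
        z, _ = mg.stouffer_meta([z0] * k)
        assert z == pytest.approx(z0 * math.sqrt(k), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mg.stouffer_meta([])

    def test_meta_msea_combines_shared_sets(self, small_universe):
        mgmap, assoc = small_universe
        sets = mg.GeneSetCollection.from_dict({"S": ["G1", "G3"]})
        res = mg.run_msea(sets, mgmap, assoc, mg.MseaParams(nperm=300, seed=1))
        meta = mg.meta_msea([res, res])
        z_single = stats.norm.isf(np.clip(res[0].p_final, 1e-300, 1 - 1e-16))
        assert meta[0].z_meta == pytest.approx(z_single * math.sqrt(2))
        assert 0 < meta[0].p_meta < 1


class TestMergeSignificantSets:
    def test_disjoint_sets_unchanged(self):
        sets = mg.GeneSetCollection.from_dict({"S1": "AB", "S2": "CD"})
        merged = mg.merge_significant_sets(sets, {"S1": 0.01, "S2": 0.01}, 0.05, 0.2)
        assert len(merged) == 2

    def test_overlapping_pair_merges(self):
        sets = mg.GeneSetCollection.from_dict({"S1": "ABC", "S2": "BCD"})
        merged = mg.merge_significant_sets(sets, {"S1": 0.01, "S2": 0.01}, 0.05, 0.2)
        assert merged["S1;S2"] == frozenset("ABCD")

    def test_chain_collapses_to_one_component(self):
        sets = mg.GeneSetCollection.from_dict(
            {"S1": "ABCD", "S2": "DEFG", "S3": "GHIJ"}
        )
        # pairwise Jaccard: S1-S2 = S2-S3 = 1/7 >= 0.1, S1-S3 = 0
        merged = mg.merge_significant_sets(
            sets, {s: 0.01 for s in sets.ids()}, 0.05, 0.1
        )
        assert list(merged.ids()) == ["S1;S2;S3"]

    def test_non_significant_sets_excluded(self):
        sets = mg.GeneSetCollection.from_dict({"S1": "AB", "S2": "AB"})
        merged = mg.merge_significant_sets(sets, {"S1": 0.01, "S2": 0.9}, 0.05, 0.2)
        assert list(merged.ids()) == ["S1"]
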