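"""Rank aggregation, abundance filters, shared sets and the G/Fisher test."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from soiltox.errors import ValidationError
from soiltox.model import OtuTable, UNCLASSIFIED
from soiltox.taxa import (
    RankProfile,
    aggregate_rank,
    dominant_by_difference,
    filter_min_proportion,
    fisher_exact_two_sided,
    shared_taxa,
    two_proportion_test,
)


def random_otu_table(rng, n_otus=8, n_samples=4):
    phyla = ["Proteobacteria", "Firmicutes", "Bacteroidetes", ""]
    classes = ["Alpha", "Bacilli", "", ""]
    genera = ["Devosia", "Bacillus", "", ""]
    return OtuTable(
        otu_ids=[f"OTU{i}" for i in range(n_otus)],
        lineages=[
            (rng.choice(phyla), rng.choice(classes), "", "", rng.choice(genera))
            for _ in range(n_otus)
        ],
        samples=[f"S{j}" for j in range(n_samples)],
        counts=rng.integers(1, 500, size=(n_otus, n_samples)),
    )


class TestAggregation:
    def test_single_phylum_collapses_to_column_sums(self):
        table = OtuTable(
            otu_ids=["a", "b", "c"],
            lineages=[("X",), ("X",), ("X",)],
            samples=["S1", "S2"],
            counts=np.array([[1, 2], [3, 4], [5, 6]]),
        )
        profile = aggregate_rank(table, "phylum")
        assert profile.taxa == ["X"]
        assert np.array_equal(profile.counts, [[9, 12]])

    def test_empty_slot_pools_into_unclassified(self, toy_otu_table):
        profile = aggregate_rank(toy_otu_table, "order")
        assert UNCLASSIFIED in profile.taxa
        row = profile.taxa.index(UNCLASSIFIED)
        assert np.array_equal(profile.counts[row], [25, 40])

    def test_unknown_rank_rejected(self, toy_otu_table):
        with pytest.raises(ValidationError):
            aggregate_rank(toy_otu_table, "species")

    @given(seed=st.integers(0, 2**31 - 1))
    def test_reads_conserved_at_every_rank(self, seed):
        rng = np.random.default_rng(seed)
        table = random_otu_table(rng)
        for rank in ("phylum", "class", "order", "family", "genus"):
            profile = aggregate_rank(table, rank)
            assert np.array_equal(profile.counts.sum(axis=0), table.library_sizes())


class TestMinProportionFilter:
    def test_below_threshold_everywhere_removed(self):
        profile = RankProfile(
            "genus", ["rare", "common"], ["S1", "S2"],
            np.array([[5, 5], [995, 995]]),
        )
        result = filter_min_proportion(profile, 0.01)
        assert result.retained.taxa == ["common"]
        assert result.removed_taxa == ["rare"]

    def test_exactly_one_percent_retained(self):
        # boundary inclusive: only strictly-lower abundances are eliminated
        profile = RankProfile(
            "genus", ["edge", "bulk"], ["S1"], np.array([[10], [990]])
        )
        result = filter_min_proportion(profile, 0.01)
        assert "edge" in result.retained.taxa

    def test_retained_proportions_not_renormalized(self):
        profile = RankProfile(
            "genus", ["a", "b", "c"], ["S1"], np.array([[500], [499], [1]])
        )
        result = filter_min_proportion(profile, 0.01)
        assert result.retained.proportions[0, 0] == pytest.approx(0.5)

    def test_bad_threshold_rejected(self):
        profile = RankProfile("genus", ["a"], ["S1"], np.array([[1]]))
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValidationError):
                filter_min_proportion(profile, bad)

    @given(seed=st.integers(0, 2**31 - 1))
    def test_retained_plus_removed_mass_conserved(self, seed):
        rng = np.random.default_rng(seed)
        table = random_otu_table(rng)
        profile = aggregate_rank(table, "genus")
        result = filter_min_proportion(profile, 0.05)
        total = result.retained.counts.sum(axis=0) + result.removed_mass
        assert np.array_equal(total, table.library_sizes())


class TestDominantByDifference:
    def test_identical_columns_empty(self):
        profile = RankProfile("genus", ["a", "b"], ["S1", "S2"], np.array([[5, 5], [5, 5]]))
        assert dominant_by_difference(profile, "S1", "S2").empty

    def test_simple_difference(self):
        profile = RankProfile(
            "genus", ["a", "b"], ["S1", "S2"], np.array([[10, 5], [90, 95]])
        )
        frame = dominant_by_difference(profile, "S1", "S2", min_diff=0.01)
        row = frame[frame.taxon == "a"].iloc[0]
        assert row["diff"] == pytest.approx(0.05)

    def test_unknown_sample_rejected(self):
        profile = RankProfile("genus", ["a"], ["S1"], np.array([[1]]))
        with pytest.raises(ValidationError):
            dominant_by_difference(profile, "S1", "nope")

    @given(seed=st.integers(0, 2**31 - 1))
    def test_membership_matches_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        table = random_otu_table(rng)
        profile = aggregate_rank(table, "genus")
        frame = dominant_by_difference(profile, "S0", "S1", min_diff=0.02)
        props = profile.proportions
        expected = {
            t
            for i, t in enumerate(profile.taxa)
            if abs(props[i, 0] - props[i, 1]) >= 0.02
        }
        assert set(frame.taxon) == expected
        diffs = frame["diff"].abs().to_numpy()
        assert np.all(np.diff(diffs) <= 1e-15)  # sorted descending


class TestSharedTaxa:
    def test_disjoint_supports_empty(self):
        profile = RankProfile(
            "genus", ["a", "b"], ["S1", "S2"], np.array([[100, 0], [0, 100]])
        )
        assert shared_taxa(profile) == set()

    def test_identical_columns_all_retained(self):
        profile = RankProfile(
            "genus", ["a", "b"], ["S1", "S2"], np.array([[60, 60], [40, 40]])
        )
        assert shared_taxa(profile, min_proportion=0.1) == {"a", "b"}

    @given(seed=st.integers(0, 2**31 - 1))
    def test_equals_intersection_of_per_sample_sets(self, seed):
        rng = np.random.default_rng(seed)
        table = random_otu_table(rng)
        profile = aggregate_rank(table, "genus")
        shared = shared_taxa(profile, min_proportion=0.05)
        props = profile.proportions
        per_sample = [
            {t for i, t in enumerate(profile.taxa) if props[i, j] >= 0.05}
            for j in range(len(profile.samples))
        ]
        assert shared == set.intersection(*per_sample)


def fisher_oracle(a, n1, b, n2):
    """Exact two-sided Fisher p via Fractions over math.comb (independent path)."""
    k = a + b
    lo, hi = max(0, k - n2), min(k, n1)
    probs = [
        Fraction(math.comb(n1, x) * math.comb(n2, k - x), math.comb(n1 + n2, k))
        for x in range(lo, hi + 1)
    ]
    observed = probs[a - lo]
    return float(sum(p for p in probs if p <= observed))


class TestTwoProportionTest:
    def test_identical_proportions(self):
        res = two_proportion_test(50, 100, 50, 100)
        assert res.diff == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)
        assert res.ci_low < 0 < res.ci_high

    def test_small_expected_takes_fisher_branch(self):
        res = two_proportion_test(0, 5, 5, 5)
        assert res.test_used == "fisher"
        assert res.p_value == pytest.approx(fisher_oracle(0, 5, 5, 5), abs=1e-12)

    def test_branch_switch_tracks_expected_cells(self):
        # expected cells all 50 -> G branch at the default threshold of 20
        res = two_proportion_test(40, 100, 60, 100)
        assert res.test_used == "g_yates"
        # forcing a huge threshold switches the same table to Fisher
        res2 = two_proportion_test(40, 100, 60, 100, fisher_threshold=1e9)
        assert res2.test_used == "fisher"

    def test_count_exceeding_total_rejected(self):
        with pytest.raises(ValidationError):
            two_proportion_test(6, 5, 0, 5)

    @given(
        n1=st.integers(1, 25),
        n2=st.integers(1, 25),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_symmetry(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        a = int(rng.integers(0, n1 + 1))
        b = int(rng.integers(0, n2 + 1))
        res_ab = two_proportion_test(a, n1, b, n2)
        res_ba = two_proportion_test(b, n2, a, n1)
        assert res_ab.p_value == pytest.approx(res_ba.p_value, abs=1e-12)
        assert res_ab.diff == pytest.approx(-res_ba.diff)
        assert res_ab.ci_low == pytest.approx(-res_ba.ci_high, abs=1e-12)
        assert res_ab.ci_high == pytest.approx(-res_ba.ci_low, abs=1e-12)
        assert res_ab.ci_low <= res_ab.diff <= res_ab.ci_high

    @given(
        n1=st.integers(1, 40),
        n2=st.integers(1, 40),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_fisher_matches_fraction_enumeration(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        a = int(rng.integers(0, n1 + 1))
        b = int(rng.integers(0, n2 + 1))
        assert fisher_exact_two_sided(a, n1, b, n2) == pytest.approx(
            fisher_oracle(a, n1, b, n2), abs=1e-12
        )

    def test_fisher_spot_check_against_scipy(self, rng):
        for _ in range(200):
            n1 = int(rng.integers(1, 60))
            n2 = int(rng.integers(1, 60))
            a = int(rng.integers(0, n1 + 1))
            b = int(rng.integers(0, n2 + 1))
            table = [[a, n1 - a], [b, n2 - b]]
            _, expected = stats.fisher_exact(table, alternative="two-sided")
            assert fisher_exact_two_sided(a, n1, b, n2) == pytest.approx(
                expected, abs=1e-9
            )

    def test_yates_g_converges_to_uncorrected_g(self):
        a, n1, b, n2 = 20000, 40000, 20600, 40000  # all cells >= 1e4
        res = two_proportion_test(a, n1, b, n2)
        assert res.test_used == "g_yates"
        table = np.array([[a, n1 - a], [b, n2 - b]])
        _, p_uncorrected, _, _ = stats.chi2_contingency(
            table, correction=False, lambda_="log-likelihood"
        )
        assert abs(res.p_value - p_uncorrected) < 1e-3
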