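"""Tukey HSD, compact letter display, Pearson correlation and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from soiltox.errors import (
    DegenerateDataError,
    InsufficientReplicationError,
    ValidationError,
)
from soiltox.group_stats import (
    compact_letter_display,
    pca_if,
    pearson_dose_correlation,
    tukey_hsd,
    tukey_pairwise_pvalues,
)
from soiltox.model import ActivityTable, TreatmentKey


def table_from_groups(groups, day=15, pc=False):
    table = ActivityTable("resp", "u")
    for dose, values in groups.items():
        for v in values:
            table.add(TreatmentKey(dose, day, pc), v)
    return table


def verify_letters(letters, significant, labels):
    """Brute-force check: shared-letter status == pairwise non-significance,
    and every letter class is a clique of mutual non-significance."""
    for i, a in enumerate(labels):
        assert letters[a], f"{a} got no letter"
        for j, b in enumerate(labels):
            if i == j:
                continue
            shares = bool(set(letters[a]) & set(letters[b]))
            assert shares == (not significant[i, j]), (a, b, letters)
    classes = {}
    for label, s in letters.items():
        for ch in s:
            classes.setdefault(ch, []).append(label)
    index = {l: i for i, l in enumerate(labels)}
    for members in classes.values():
        for a in members:
            for b in members:
                assert not significant[index[a], index[b]]


class TestTukey:
    def test_identical_groups_share_a_letter(self):
        g = tukey_hsd(table_from_groups({0.0: [1, 2, 3], 50.0: [1, 2, 3]}))
        assert g.letters["0"] == g.letters["50"] == "a"
        assert g.pairwise_p.loc["0", "50"] == pytest.approx(1.0)

    def test_close_pair_separates_from_distant_group(self):
        g = tukey_hsd(
            table_from_groups({0.0: [1, 2, 3], 1.0: [1.1, 2.1, 3.1], 50.0: [10, 11, 12]}),
            alpha=0.01,
        )
        assert set(g.letters["0"]) & set(g.letters["1"])
        assert not set(g.letters["0"]) & set(g.letters["50"])
        assert not set(g.letters["1"]) & set(g.letters["50"])

    def test_well_separated_groups_all_distinct(self):
        groups = {float(i): [100 * i + d for d in (0.0, 0.5, 1.0)] for i in range(5)}
        g = tukey_hsd(table_from_groups(groups), alpha=0.01)
        assert sorted(g.letters.values()) == ["a", "b", "c", "d", "e"]

    def test_matches_scipy_tukey_on_balanced_layouts(self, rng):
        for _ in range(20):
            k = rng.integers(3, 6)
            n = rng.integers(3, 7)
            samples = [rng.normal(rng.normal(0, 2), 1, size=n) for _ in range(k)]
            ours, _, _, _ = tukey_pairwise_pvalues(
                {str(i): s for i, s in enumerate(samples)}
            )
            reference = stats.tukey_hsd(*samples).pvalue
            assert np.allclose(ours.to_numpy(), reference, atol=1e-8)

    def test_permutation_invariance_and_range(self, rng):
        groups = {str(i): rng.normal(i, 1, 4).tolist() for i in range(4)}
        p1, _, _, _ = tukey_pairwise_pvalues(groups)
        order = ["2", "0", "3", "1"]
        p2, _, _, _ = tukey_pairwise_pvalues({k: groups[k] for k in order})
        assert np.allclose(p1.loc[order, order].to_numpy(), p2.to_numpy())
        assert ((p1.to_numpy() >= 0) & (p1.to_numpy() <= 1)).all()

    def test_insufficient_replication_rejected(self):
        with pytest.raises(InsufficientReplicationError):
            tukey_pairwise_pvalues({"a": [1.0], "b": [1.0, 2.0]})

    def test_zero_variance_unequal_means_all_significant(self):
        p, _, _, _ = tukey_pairwise_pvalues({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert p.loc["a", "b"] == 0.0
        p_eq, _, _, _ = tukey_pairwise_pvalues({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert p_eq.loc["a", "b"] == 1.0


class TestCompactLetterDisplay:
    def test_no_pair_significant_all_a(self):
        letters = compact_letter_display(np.zeros((4, 4), dtype=bool), list("wxyz"))
        assert all(s == "a" for s in letters.values())

    def test_all_pairs_significant_distinct_letters(self):
        sig = ~np.eye(5, dtype=bool)
        letters = compact_letter_display(sig, list("vwxyz"))
        assert sorted(letters.values()) == ["a", "b", "c", "d", "e"]

    def test_chain_case(self):
        # A != C, A ~ B, B ~ C  ->  A: a, B: ab, C: b
        sig = np.array(
            [[False, False, True], [False, False, False], [True, False, False]]
        )
        letters = compact_letter_display(sig, ["A", "B", "C"])
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_non_symmetric_rejected(self):
        sig = np.zeros((2, 2), dtype=bool)
        sig[0, 1] = True
        with pytest.raises(ValidationError):
            compact_letter_display(sig, ["a", "b"])

    @given(n=st.integers(2, 8), seed=st.integers(0, 2**31 - 1))
    def test_random_matrices_encode_exactly_the_relation(self, n, seed):
        rng = np.random.default_rng(seed)
        upper = rng.random((n, n)) < 0.4
        sig = np.triu(upper, 1)
        sig = sig | sig.T
        labels = [f"g{i}" for i in range(n)]
        letters = compact_letter_display(sig, labels)
        verify_letters(letters, sig, labels)


class TestPearson:
    def test_perfect_linearity(self):
        doses = [0.0, 0.1, 1.0, 10.0, 50.0]
        r, significant, p = pearson_dose_correlation(doses, [2 * d + 1 for d in doses])
        assert r == pytest.approx(1.0)
        assert significant

    def test_sign_convention(self):
        doses = [0.0, 1.0, 2.0, 3.0]
        r, _, _ = pearson_dose_correlation(doses, [-d for d in doses])
        assert r == pytest.approx(-1.0)

    def test_independent_noise_not_significant(self, rng):
        doses = np.repeat([0.0, 0.1, 1.0, 10.0, 50.0], 40)
        flags = []
        for _ in range(20):
            y = rng.normal(size=doses.size)
            _, significant, _ = pearson_dose_correlation(doses, y)
            flags.append(significant)
        assert np.mean(flags) < 0.3  # alpha = 0.05 under the null

    def test_constant_vector_undefined(self):
        with pytest.raises(DegenerateDataError):
            pearson_dose_correlation([0.0, 1.0, 2.0], [5.0, 5.0, 5.0])

    @given(
        a=st.floats(min_value=-5, max_value=5).filter(lambda a: abs(a) > 1e-3),
        b=st.floats(min_value=-5, max_value=5),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_affine_equivariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        r1, _, _ = pearson_dose_correlation(x, y)
        r2, _, _ = pearson_dose_correlation(x, a * y + b)
        assert r2 == pytest.approx(np.sign(a) * r1, abs=1e-9)
        assert -1.0 - 1e-12 <= r1 <= 1.0 + 1e-12


class TestPca:
    def test_rank_one_data_explained_by_pc1(self, rng):
        direction = np.array([1.0, 2.0, -1.0])
        cases = np.outer(rng.normal(size=6), direction)
        frame = pd.DataFrame(cases.T, index=["v1", "v2", "v3"])
        report = pca_if(frame, standardized=False)
        assert report.explained_pct[0] == pytest.approx(100.0)

    def test_duplicated_variables_have_equal_loadings(self, rng):
        x = rng.normal(size=(3, 8))
        frame = pd.DataFrame(np.vstack([x, x[1:2]]), index=["v1", "v2", "v3", "v2bis"])
        report = pca_if(frame, standardized=True)
        retained = report.explained_pct > 1e-9
        load = report.loadings.to_numpy()[:, retained]
        assert np.allclose(load[1], load[3], atol=1e-8)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.decomposition import PCA

        for standardized in (True, False):
            X = rng.normal(size=(15, 7))  # cases x variables
            frame = pd.DataFrame(X.T)  # responses x cells, as IF matrices are
            report = pca_if(frame, standardized=standardized)
            Z = X - X.mean(axis=0)
            if standardized:
                Z = Z / X.std(axis=0, ddof=1)
            reference = PCA().fit(Z)
            assert np.allclose(
                report.explained_pct, 100 * reference.explained_variance_ratio_, atol=1e-8
            )
            # back-projection reproduces the (centered, scaled) data
            reconstructed = report.scores.to_numpy() @ report.loadings.to_numpy().T
            assert np.allclose(reconstructed, Z, atol=1e-8)
            assert report.explained_pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_deterministic_sign_convention(self, rng):
        X = rng.normal(size=(10, 4))
        frame = pd.DataFrame(X.T)
        report = pca_if(frame)
        for comp in report.loadings.columns:
            col = report.loadings[comp].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_rank_zero_rejected(self):
        frame = pd.DataFrame(np.ones((3, 5)))
        with pytest.raises(DegenerateDataError):
            pca_if(frame, standardized=False)

    def test_missing_cases_dropped_and_reported(self, rng):
        X = rng.normal(size=(4, 6))
        X[0, 0] = np.nan
        frame = pd.DataFrame(X)  # 4 variables x 6 cases
        report = pca_if(frame, standardized=False)
        assert len(report.dropped_cases) == 1
        assert report.scores.shape[0] == 5
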