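"""Subset enumeration, missing-data handling and PC1 extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpca import (
    CompositePhenotype,
    PhenotypeSubset,
    correlation_matrix,
    count_combinations,
    enumerate_subsets,
    filter_samples_by_missingness,
    fit_cp,
    impute_iterative_lowrank,
    orient_cp,
    pc1,
    score_cp,
)
from conftest import make_panel


class TestEnumeration:
    @pytest.mark.parametrize("k,expected", [(2, 1), (3, 4), (5, 26), (12, 4083)])
    def test_count_closed_form(self, k, expected):
        assert count_combinations(k) == expected == 2**k - k - 1

    def test_count_rejects_small_panel(self):
        with pytest.raises(ValueError):
            count_combinations(1)

    @pytest.mark.parametrize("k", range(2, 9))
    def test_stream_matches_count_and_is_unique(self, k):
        names = [f"T{i}" for i in range(k)]
        subs = list(enumerate_subsets(names))
        assert len(subs) == count_combinations(k)
        assert len({s.member_traits for s in subs}) == len(subs)

    def test_stream_order_size_then_lexicographic(self):
        subs = [s.member_traits for s in enumerate_subsets(["A", "B", "C"])]
        assert subs == [("A", "B"), ("A", "C"), ("B", "C"), ("A", "B", "C")]

    def test_members_keep_canonical_panel_order(self):
        subs = list(enumerate_subsets(["Z", "A"]))
        assert subs[0].member_traits == ("Z", "A")

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            list(enumerate_subsets(["A", "A", "B"]))


class TestMissingness:
    def test_filter_30_percent_rule(self):
        # 21 traits: 7 missing (33.3%) removed, 6 missing (28.6%) retained
        vals = np.zeros((3, 21))
        vals[0, :7] = np.nan
        vals[1, :6] = np.nan
        panel = make_panel(vals)
        kept, removed = filter_samples_by_missingness(panel, 0.30)
        assert list(removed) == ["S0"]
        assert kept.n_samples == 2

    def test_complete_panel_untouched(self):
        panel = make_panel(np.random.default_rng(0).normal(size=(10, 4)))
        kept, removed = filter_samples_by_missingness(panel)
        assert removed.size == 0 and kept.n_samples == 10

    def test_impute_noop_without_missing(self):
        vals = np.random.default_rng(1).normal(size=(20, 3))
        panel = make_panel(vals)
        out = impute_iterative_lowrank(panel)
        assert np.array_equal(out.values, vals)

    def test_impute_recovers_rank1_structure(self):
        # rank-1 truth with ~10% of cells masked, at most one per row so
        # every masked cell is recoverable from its partner trait
        rng = np.random.default_rng(2)
        t1 = rng.normal(size=400)
        truth = np.column_stack([t1, 2 * t1])
        vals = truth.copy()
        mask = np.zeros_like(vals, dtype=bool)
        rows = rng.choice(400, size=80, replace=False)
        mask[rows, rng.integers(0, 2, 80)] = True
        vals[mask] = np.nan
        out = impute_iterative_lowrank(make_panel(vals), n_components=1,
                                       tol=1e-9, max_iter=500)
        assert out.meta["imputation_converged"]
        assert np.max(np.abs(out.values[mask] - truth[mask])) < 1e-3
        # observed cells untouched
        assert np.array_equal(out.values[~mask], truth[~mask])

    def test_impute_single_cell_matches_rank1_regression(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        y = 1.5 * x  # exactly rank-1 after standardization
        vals = np.column_stack([x, y])
        vals[0, 1] = np.nan
        out = impute_iterative_lowrank(make_panel(vals), n_components=1,
                                       tol=1e-10, max_iter=500)
        assert out.values[0, 1] == pytest.approx(1.5 * x[0], abs=1e-3)


class TestCorrelationAndPC1:
    def test_correlation_trivial_entries(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=500)
        panel = make_panel(np.column_stack([x, x, -x]))
        R = correlation_matrix(panel)
        assert R[0, 1] == pytest.approx(1.0)
        assert R[0, 2] == pytest.approx(-1.0)

    def test_correlation_rejects_constant_trait(self):
        panel = make_panel(np.column_stack([np.arange(5.0), np.ones(5)]),
                           names=["ok", "flat"])
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(panel)

    def test_independent_traits_near_zero_offdiag(self):
        rng = np.random.default_rng(5)
        R = correlation_matrix(make_panel(rng.normal(size=(10000, 4))))
        off = R[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_pc1_2x2_closed_form(self):
        loadings, lam = pc1([[1, 0.5], [0.5, 1]])
        assert lam == pytest.approx(1.5, abs=1e-12)
        assert loadings == pytest.approx(np.sqrt(0.5) * np.ones(2), abs=1e-12)

    def test_pc1_equicorrelated_closed_form(self):
        r = 0.4
        R = np.full((3, 3), r)
        np.fill_diagonal(R, 1.0)
        loadings, lam = pc1(R)
        assert lam == pytest.approx(1 + 2 * r, abs=1e-12)
        assert loadings == pytest.approx(np.ones(3) / np.sqrt(3), abs=1e-12)

    def test_pc1_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            pc1([[1.0, 0.2], [0.5, 1.0]])

    def test_pc1_identity_tie_is_basis_aligned(self):
        loadings, lam = pc1(np.eye(4))
        assert lam == pytest.approx(1.0)
        assert loadings == pytest.approx([1, 0, 0, 0])

    def test_pc1_sign_convention_first_loading_nonnegative(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            A = rng.normal(size=(40, 5))
            R = np.corrcoef(A, rowvar=False)
            loadings, _ = pc1(R)
            nz = loadings[loadings != 0]
            assert nz[0] > 0

    @given(st.floats(min_value=0.01, max_value=0.99))
    @settings(derandomize=True, max_examples=40)
    def test_pc1_2x2_eigenvalue_is_one_plus_r(self, r):
        _, lam = pc1([[1, r], [r, 1]])
        assert abs(lam - (1 + r)) < 1e-10

    def test_eigenvalue_bounds_across_subsets(self, small_cohort):
        panel = small_cohort.panel
        R = correlation_matrix(panel)
        for sub in enumerate_subsets(panel.trait_names):
            idx = [panel.trait_index(t) for t in sub.member_traits]
            loadings, lam = pc1(R[np.ix_(idx, idx)])
            assert 1 - 1e-10 <= lam <= sub.size + 1e-10
            assert np.linalg.norm(loadings) == pytest.approx(1.0, abs=1e-10)


class TestScoring:
    def _cp(self):
        return CompositePhenotype(
            PhenotypeSubset(("T0", "T1")),
            np.sqrt(0.5) * np.ones(2), 1.5, 1,
            np.zeros(2), np.ones(2),
        )

    def test_score_at_training_means_is_zero(self):
        cp = self._cp()
        panel = make_panel(np.zeros((3, 2)))
        assert score_cp(panel, cp) == pytest.approx(np.zeros(3))

    def test_score_standardized_unit_pair(self):
        cp = self._cp()
        panel = make_panel(np.ones((1, 2)))
        assert score_cp(panel, cp)[0] == pytest.approx(np.sqrt(2))

    def test_orientation_flip_negates_scores(self):
        cp = self._cp()
        panel = make_panel(np.random.default_rng(7).normal(size=(50, 2)))
        s = score_cp(panel, cp)
        cp.orientation = -1
        assert np.allclose(score_cp(panel, cp), -s)

    @pytest.mark.parametrize("cases,ctrls,expected", [
        ([2, 3], [0, 1], -1),
        ([0, 1], [2, 3], 1),
        ([1, 2], [1, 2], 1),  # tie -> +1
    ])
    def test_orient_cp_rule(self, cases, ctrls, expected):
        scores = np.array(ctrls + cases, float)
        status = np.array([0] * len(ctrls) + [1] * len(cases))
        assert orient_cp(scores, status) == expected

    def test_score_invariant_to_affine_trait_rescaling(self, small_cohort):
        panel = small_cohort.panel
        status = small_cohort.disease_status
        R = correlation_matrix(panel)
        sub = PhenotypeSubset(("A", "C", "E"))
        cp1 = fit_cp(panel, sub, R, status)
        s1 = score_cp(panel, cp1)
        rescaled = panel.copy()
        rescaled.values = panel.values * np.array([3.0, 1, 0.5, 1, 10.0]) + 7.0
        R2 = correlation_matrix(rescaled)
        cp2 = fit_cp(rescaled, sub, R2, status)
        s2 = score_cp(rescaled, cp2)
        assert np.allclose(s1, s2, atol=1e-8)

    def test_oriented_cp_controls_score_at_least_cases(self, small_cohort):
        panel = small_cohort.panel
        status = small_cohort.disease_status.astype(bool)
        R = correlation_matrix(panel)
        for sub in enumerate_subsets(panel.trait_names):
            cp = fit_cp(panel, sub, R, status)
            s = score_cp(panel, cp)
            assert s[~status].mean() >= s[status].mean()

    def test_cp_json_roundtrip(self, small_cohort):
        panel = small_cohort.panel
        R = correlation_matrix(panel)
        cp = fit_cp(panel, PhenotypeSubset(("A", "B")), R,
                    small_cohort.disease_status)
        back = CompositePhenotype.from_json(cp.to_json())
        assert np.allclose(score_cp(panel, back), score_cp(panel, cp))

    def test_score_rejects_missing_member_trait(self, small_cohort):
        panel = small_cohort.panel
        R = correlation_matrix(panel)
        cp = fit_cp(panel, PhenotypeSubset(("A", "B")), R)
        reduced = make_panel(panel.values[:, 2:], names=["C", "D", "E"])
        with pytest.raises(KeyError):
            score_cp(reduced, cp)
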