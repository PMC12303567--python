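"""Cell-to-strain assignment: distances, permutation null, doublets, consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sceqtl.assign import (
    assign_cells,
    consensus_profiles,
    expected_distance,
    flag_doublets,
    normalize_expression,
    relatedness,
)
from sceqtl.cross import CellAlleleCounts, GeneticMap, GenotypePanel
from scipy import sparse as sp


class TestExpectedDistance:
    def test_identical_vectors_have_zero_distance(self):
        assert expected_distance([1, 0, 1], [1, 0, 1]) == 0.0

    def test_opposite_hard_vectors_give_hamming_distance(self):
        assert expected_distance([1, 1], [0, 0]) == 2.0

    def test_half_probability_sites_contribute_half_each(self):
        # each g_c = 0.5 site contributes exactly 0.5 regardless of g_s
        assert expected_distance([0.5, 0.5], [0.2, 0.9]) == pytest.approx(1.0)

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            expected_distance([1, 0], [1, 0, 1])

    @given(
        st.lists(st.integers(0, 1), min_size=4, max_size=12),
        st.lists(st.integers(0, 1), min_size=4, max_size=12),
        st.lists(st.integers(0, 1), min_size=4, max_size=12),
    )
    @settings(max_examples=100, deadline=None)
    def test_metric_on_hard_genotypes(self, a, b, c):
        n = min(len(a), len(b), len(c))
        a, b, c = a[:n], b[:n], c[:n]
        dab = expected_distance(a, b)
        assert dab == expected_distance(b, a)
        assert (dab == 0) == (a == b)
        assert dab <= expected_distance(a, c) + expected_distance(c, b)


class TestRelatedness:
    def test_identical_vectors_are_fully_related(self):
        g = np.array([1, 0, 1, 1, 0], dtype=float)
        assert relatedness(g, g) == pytest.approx(1.0)

    def test_anticorrelated_vectors_score_one_with_negative_sign(self):
        g = np.array([1, 0, 1, 1, 0], dtype=float)
        r2, sign = relatedness(g, 1 - g, return_sign=True)
        assert r2 == pytest.approx(1.0)
        assert sign == -1

    def test_independent_vectors_score_near_zero(self):
        rng = np.random.default_rng(0)
        vals = [
            relatedness(rng.integers(0, 2, 1000), rng.integers(0, 2, 1000))
            for _ in range(50)
        ]
        assert abs(np.mean(vals)) < 0.01

    def test_constant_vector_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert relatedness([1, 1, 1], [1, 0, 1]) == 0.0

    def test_rounding_happens_before_comparison(self):
        soft = np.array([0.6, 0.4, 0.9, 0.1, 0.7])
        hard = np.array([1, 0, 1, 0, 1], dtype=float)
        assert relatedness(soft, hard) == pytest.approx(1.0)


def _toy_panel(n_strains=20, n_sites=60, seed=0):
    gmap = GeneticMap.regular(1, n_sites, 100, 1.0)
    rng = np.random.default_rng(seed)
    geno = rng.integers(0, 2, (n_strains, n_sites)).astype(float)
    ids = np.array([f"S{i}" for i in range(n_strains)], dtype=object)
    return GenotypePanel(geno, ids, gmap)


class TestAssignCells:
    def test_exact_copy_is_assigned_with_zero_distance(self):
        panel = _toy_panel()
        post = panel.genotypes[[3, 7, 12]]
        res = assign_cells(post, panel, n_null=30, seed=0)
        assert list(res["best_strain"]) == ["S3", "S7", "S12"]
        np.testing.assert_allclose(res["distance"], 0.0)
        assert res["assigned"].all()

    def test_cells_from_excluded_strains_are_rarely_assigned(self):
        gmap = GeneticMap.regular(2, 100, 100, 1.0)
        from sceqtl.cross import simulate_cross

        panel_all = simulate_cross(gmap, 120, 3)
        inside = GenotypePanel(
            panel_all.genotypes[:60], panel_all.strain_ids[:60], gmap
        )
        outside_cells = panel_all.genotypes[60:]
        res = assign_cells(outside_cells, inside, n_null=99, fdr_threshold=0.05, seed=1)
        assert res["assigned"].mean() <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 60)

    def test_rejects_tiny_panel_and_low_n_null(self):
        panel = _toy_panel(n_strains=1)
        with pytest.raises(ValueError):
            assign_cells(panel.genotypes, panel, n_null=30)
        panel = _toy_panel()
        with pytest.raises(ValueError):
            assign_cells(panel.genotypes[:2], panel, n_null=5)

    def test_null_is_deterministic_under_seed(self):
        panel = _toy_panel()
        post = panel.genotypes[[0, 1]]
        a = assign_cells(post, panel, n_null=30, seed=7)
        b = assign_cells(post, panel, n_null=30, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestDoublets:
    """The three-clause rule: high coverage, unassigned, dissimilar top two."""

    def _setup(self):
        # panel with two identical strains (0, 1) and otherwise random strains
        panel = _toy_panel(n_strains=10, n_sites=40, seed=2)
        panel.genotypes[1] = panel.genotypes[0]
        gmap = panel.gmap
        # coverage: cells 0-2 dense (40 sites), cell 3 sparse (4 sites)
        rm = np.zeros((4, 40)); by = np.zeros((4, 40))
        for c in range(3):
            rm[c] = panel.genotypes[c + 2]
            by[c] = 1 - rm[c]
        rm[3, :4] = 1
        counts = CellAlleleCounts(
            sp.csr_matrix(rm), sp.csr_matrix(by), list("abcd"), gmap
        )
        res = pd.DataFrame(
            {
                "cell": [0, 1, 2, 3],
                "best_strain": ["S2", "S3", "S0", "S4"],
                "second_strain": ["S5", "S6", "S1", "S5"],
                "distance": [0.0, 12.0, 11.0, 8.0],
                "relatedness": [1.0, 0.1, 0.1, 0.1],
                "p_value": [0.01, 0.6, 0.6, 0.6],
                "q_value": [0.01, 0.8, 0.8, 0.8],
                "assigned": [True, False, False, False],
                "doublet": [False] * 4,
            }
        )
        return counts, res, panel

    def test_three_clause_rule(self):
        counts, res, panel = self._setup()
        out = flag_doublets(counts, res, panel)
        assert not out.loc[0, "doublet"]  # clause 2 fails: assigned
        assert out.loc[1, "doublet"]  # dense + unassigned + dissimilar top two
        assert not out.loc[2, "doublet"]  # clause 3 fails: S0 and S1 identical
        assert not out.loc[3, "doublet"]  # clause 1 fails: below Q3 coverage

    def test_assigned_and_doublet_flags_are_exclusive(self):
        counts, res, panel = self._setup()
        out = flag_doublets(counts, res, panel)
        assert not (out["assigned"] & out["doublet"]).any()


class TestConsensus:
    def test_single_cell_consensus_is_that_cell(self):
        post = np.array([[0.2, 0.8, 0.6]])
        umi = np.array([[5, 1]])
        assignments = pd.DataFrame(
            {"cell": [0], "best_strain": ["S1"], "assigned": [True], "doublet": [False]}
        )
        strains, g, e = consensus_profiles(assignments, post, umi)
        np.testing.assert_array_equal(g, post)
        np.testing.assert_array_equal(e, umi.astype(float))

    def test_median_genotype_and_max_count_expression(self):
        post = np.array([[0.1, 0.2], [0.9, 0.6], [0.95, 0.7]])
        umi = np.array([[1, 1], [10, 0], [2, 2]])
        assignments = pd.DataFrame(
            {
                "cell": [0, 1, 2],
                "best_strain": ["S1"] * 3,
                "assigned": [True] * 3,
                "doublet": [False] * 3,
            }
        )
        strains, g, e = consensus_profiles(assignments, post, umi)
        np.testing.assert_allclose(g[0], [0.9, 0.6])
        np.testing.assert_array_equal(e[0], [10, 0])  # cell 1 has most UMIs

    def test_unassigned_cells_are_excluded(self):
        post = np.array([[0.0, 0.0], [1.0, 1.0]])
        umi = np.array([[1, 1], [1, 1]])
        assignments = pd.DataFrame(
            {
                "cell": [0, 1],
                "best_strain": ["S1", "S2"],
                "assigned": [True, False],
                "doublet": [False, False],
            }
        )
        strains, g, _ = consensus_profiles(assignments, post, umi)
        assert list(strains) == ["S1"]

    def test_no_assigned_cells_is_an_error(self):
        assignments = pd.DataFrame(
            {"cell": [0], "best_strain": ["S1"], "assigned": [False], "doublet": [False]}
        )
        with pytest.raises(ValueError):
            consensus_profiles(assignments, np.zeros((1, 2)), np.zeros((1, 2)))

    def test_consensus_improves_over_single_cells(self, small_world):
        # noisy posteriors from multiple cells: the median can only help
        panel = small_world["panel"]
        rng = np.random.default_rng(0)
        variable = [i for i in range(panel.n_strains)
                    if 0.2 < panel.genotypes[i].mean() < 0.8]
        truth = panel.genotypes[variable[0]]
        noisy = [np.clip(truth + rng.normal(0, 0.3, len(truth)), 0, 1) for _ in range(9)]
        meds = np.median(noisy, axis=0)
        r_single = np.mean([relatedness(c, truth) for c in noisy])
        assert relatedness(meds, truth) > r_single


class TestNormalizeExpression:
    def test_gene_standardization_then_cell_total_division(self):
        counts = np.array([[2.0, 0.0], [4.0, 2.0]])
        z = (counts - counts.mean(0)) / counts.std(0)
        expected = z / counts.sum(axis=1)[:, None]
        np.testing.assert_allclose(normalize_expression(counts), expected)

    def test_zero_variance_gene_becomes_zero_column(self):
        counts = np.array([[3.0, 1.0], [3.0, 5.0]])
        out = normalize_expression(counts)
        np.testing.assert_allclose(out[:, 0], 0.0)


class TestDenoiseHook:
    def test_low_rank_smooth_reconstructs_low_rank_signal(self):
        rng = np.random.default_rng(0)
        base = np.outer(rng.normal(0, 1, 40), rng.normal(0, 1, 15))
        noisy = base + rng.normal(0, 0.05, base.shape)
        from sceqtl.assign import low_rank_smooth

        smooth = low_rank_smooth(noisy, rank=1)
        assert np.abs(smooth - base).mean() < np.abs(noisy - base).mean() + 0.05

    def test_normalize_accepts_denoise_hook(self):
        from sceqtl.assign import low_rank_smooth

        counts = np.abs(np.random.default_rng(1).normal(2, 1, (20, 8)))
        out = normalize_expression(counts, denoise=lambda m: low_rank_smooth(m, 3))
        assert out.shape == counts.shape
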