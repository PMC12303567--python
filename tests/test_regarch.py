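"""Hotspots, cis/trans labels, locus alignment, rank and similarity statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sceqtl.cross import GeneticMap, GenotypePanel, simulate_cross
from sceqtl.regarch import (
    MatchParams,
    align_loci,
    cis_trans_effect_test,
    classify_cis_trans,
    find_hotspots,
    hotspot_overlap_odds,
    hotspot_qtl_rank_correlation,
    match_qtl_eqtl,
    model_similarity,
    rank_permutation_test,
)
from sceqtl.sparse import QTLModel


def _model(sites, betas, n=100):
    sites = np.asarray(sites, dtype=int)
    betas = np.asarray(betas, dtype=float)
    return QTLModel(sites, betas, 0.0, 1.0, 1.0, np.log(n), 0.5, n)


@pytest.fixture(scope="module")
def flat_map():
    # one chromosome, 1 site per kb, 1 cM per site
    return GeneticMap.regular(1, 200, 1000, 1.0)


class TestHotspots:
    def test_all_eqtl_in_one_window_is_the_unique_hotspot(self, flat_map):
        models = {f"g{i}": _model([3 + i % 4], [1.0]) for i in range(12)}
        table = find_hotspots(models, flat_map, window_bp=25_000)
        assert table["hotspot"].sum() == 1
        hot = table[table["hotspot"]].iloc[0]
        assert hot["start"] == 1
        assert hot["n_genes"] == 12

    def test_uniform_spread_flags_follow_degenerate_quartiles(self, flat_map):
        # one eQTL per window: constant occupied distribution, Q3 equals the
        # constant, so the ≥Q3 rule flags every occupied window
        models = {f"g{i}": _model([i * 25], [1.0]) for i in range(8)}
        table = find_hotspots(models, flat_map, window_bp=25_000)
        occupied = table["n_eqtl"] >= 1
        assert (table.loc[occupied, "hotspot"]).all()

    def test_windows_tile_without_overlap(self, flat_map):
        models = {"g": _model([0], [1.0])}
        table = find_hotspots(models, flat_map, window_bp=25_000)
        starts = table["start"].to_numpy()
        ends = table["end"].to_numpy()
        assert np.all(starts[1:] == ends[:-1] + 1)

    def test_flags_invariant_under_chromosome_relabelling(self):
        gmap_a = GeneticMap(["c1"] * 50, np.arange(1, 51) * 1000, np.arange(50.0))
        gmap_b = GeneticMap(["zz"] * 50, np.arange(1, 51) * 1000, np.arange(50.0))
        models = {f"g{i}": _model([2 * i % 10], [1.0]) for i in range(9)}
        ta = find_hotspots(models, gmap_a)
        tb = find_hotspots(models, gmap_b)
        np.testing.assert_array_equal(ta["hotspot"], tb["hotspot"])


class TestCisTrans:
    def _annotation(self):
        return pd.DataFrame(
            {
                "gene": ["gplus", "gminus"],
                "chrom": ["chr01", "chr01"],
                "start": [50_000, 120_000],
                "end": [52_000, 122_000],
                "strand": ["+", "-"],
            }
        )

    def _map(self):
        # sites: 0=48,900  1=49,500  2=52,150  3=121,850  4=122,150  5=150,000
        return GeneticMap(
            ["chr01"] * 6,
            [48_900, 49_500, 52_150, 121_850, 122_150, 150_000],
            np.arange(6.0),
        )

    def test_upstream_window_is_strand_aware(self):
        gmap = self._map()
        ann = self._annotation()
        # 49,500 is 500 bp upstream of gplus' TSS → cis;
        # 48,900 is 1,100 bp upstream → trans
        models = {"gplus": _model([1, 0], [1.0, 0.5])}
        labels = classify_cis_trans(models, ann, gmap)
        by_site = labels.set_index("site_idx")["label"]
        assert by_site.loc[1] == "cis"
        assert by_site.loc[0] == "trans"
        # minus-strand gene: 150 bp "downstream" of its end is at lower coords
        models = {"gminus": _model([3], [1.0])}  # 121,850 = start-150
        labels = classify_cis_trans(models, ann, gmap)
        assert labels["label"].iloc[0] == "cis"

    def test_different_chromosome_is_trans(self):
        gmap = GeneticMap(
            ["c1", "c2"], [100, 100], [0.0, 0.0]
        )
        ann = pd.DataFrame(
            {"gene": ["g"], "chrom": ["c1"], "start": [50], "end": [150], "strand": ["+"]}
        )
        labels = classify_cis_trans({"g": _model([1], [1.0])}, ann, gmap)
        assert labels["label"].iloc[0] == "trans"

    def test_missing_gene_warns_and_labels_trans(self, flat_map):
        with pytest.warns(UserWarning):
            labels = classify_cis_trans({"nope": _model([0], [1.0])}, self._annotation(), flat_map)
        assert (labels["label"] == "trans").all()

    def test_every_eqtl_gets_exactly_one_label(self, flat_map):
        ann = self._annotation()
        models = {"gplus": _model([0, 50, 100], [1.0, -0.5, 0.2])}
        labels = classify_cis_trans(models, ann, flat_map)
        assert len(labels) == 3
        assert set(labels["label"]) <= {"cis", "trans"}


def _brute_force_alignment(score, gamma):
    """Enumerate all monotone pairings; score = Σ pairs − γ·(unmatched rows)."""
    na, nb = score.shape
    best = -gamma * na
    rows = list(range(na))
    for k in range(1, min(na, nb) + 1):
        for rsub in itertools.combinations(range(na), k):
            for csub in itertools.combinations(range(nb), k):
                s = sum(score[i, j] for i, j in zip(rsub, csub))
                s -= gamma * (na - k)
                best = max(best, s)
    return best


class TestAlignment:
    @pytest.mark.parametrize("trial", range(30))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        na, nb = rng.integers(1, 7, 2)
        score = rng.random((na, nb))
        gamma = float(rng.uniform(0.1, 1.0))
        got, pairs = align_loci(score, gamma)
        assert got == pytest.approx(_brute_force_alignment(score, gamma), abs=1e-9)
        # pairs must be strictly monotone in both coordinates
        for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
            assert i2 > i1 and j2 > j1

    def test_identical_lists_pair_diagonally(self, flat_map):
        panel = GenotypePanel(
            np.random.default_rng(0).integers(0, 2, (20, 200)).astype(float),
            [f"S{i}" for i in range(20)],
            flat_map,
        )
        qtl = _model([10, 50, 90], [1.0, -1.0, 0.5])
        score = np.eye(3)
        total, pairs = align_loci(score, 0.5)
        assert pairs == [(0, 0), (1, 1), (2, 2)]
        assert total == pytest.approx(3.0)

    def test_distant_pair_prefers_gap(self):
        # one QTL 200 cM from the only eQTL (δ=10): log pair score −20 is
        # worth less than leaving the QTL unmatched at γ=0.5
        log_score = np.array([[-200 / 10]])
        total, pairs = align_loci(log_score, 0.5)
        assert pairs == []
        assert total == pytest.approx(-0.5)

    def test_distant_pair_unmatched_end_to_end(self):
        gmap = GeneticMap(["c1"] * 2, [1000, 2_001_000], [0.0, 200.0])
        panel = GenotypePanel(
            np.random.default_rng(0).integers(0, 2, (30, 2)).astype(float),
            [f"S{i}" for i in range(30)],
            gmap,
        )
        qtl = _model([0], [1.0])
        eqtl = _model([1], [1.0])
        y = np.random.default_rng(1).normal(0, 1, 30)
        res = match_qtl_eqtl(qtl, y, panel, eqtl, MatchParams(delta_cm=10.0, gamma=0.5))
        assert len(res.pairs) == 0
        assert list(res.unmatched_qtl) == [0]


class TestMatchQtlEqtl:
    def test_matched_and_unmatched_partition_the_qtl(self, flat_map):
        rng = np.random.default_rng(1)
        panel = GenotypePanel(
            rng.integers(0, 2, (60, 200)).astype(float),
            [f"S{i}" for i in range(60)],
            flat_map,
        )
        qtl = _model([20, 100, 180], [1.0, 0.8, -0.5])
        eqtl = _model([21, 99], [1.0, 0.7])
        y = panel.genotypes[:, 21] + rng.normal(0, 0.3, 60)
        res = match_qtl_eqtl(qtl, y, panel, eqtl)
        got = set(res.pairs["qtl_site"]) | set(res.unmatched_qtl)
        assert got == {20, 100, 180}

    def test_empty_eqtl_list_pays_full_gap_penalty(self, flat_map):
        rng = np.random.default_rng(2)
        panel = GenotypePanel(
            rng.integers(0, 2, (30, 200)).astype(float),
            [f"S{i}" for i in range(30)],
            flat_map,
        )
        qtl = _model([5, 60], [1.0, -1.0])
        eqtl = _model([], [])
        res = match_qtl_eqtl(qtl, np.zeros(30), panel, eqtl, MatchParams(gamma=0.5))
        assert res.total_score == pytest.approx(-1.0)
        assert set(res.unmatched_qtl) == {5, 60}


class TestRankPermutation:
    def test_top_ranked_matched_set_gives_zero_p(self):
        p = rank_permutation_test([10, 9], [1, 2, 3, 4, 5], n_perm=99, seed=0)
        assert p == 0.0
        p1 = rank_permutation_test([10, 9], [1, 2, 3, 4, 5], n_perm=99, seed=0, add_one=True)
        assert p1 == pytest.approx(1 / 100)

    def test_single_worse_matched_rank_gives_p_one(self):
        assert rank_permutation_test([1], [5], n_perm=99, seed=0) == 1.0

    def test_no_unmatched_returns_missing(self):
        assert np.isnan(rank_permutation_test([1, 2], [], n_perm=9, seed=0))

    def test_oversized_matched_set_rejected(self):
        with pytest.raises(ValueError):
            rank_permutation_test([1, 2, 3], [4, 5], n_perm=9, seed=0)

    def test_null_p_values_are_uniform(self):
        # a gene matches a few of many QTL; with the matched set a small
        # fraction of the pool the complement-subset null is calibrated
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(300):
            ranks = rng.permutation(60) + 1
            ps.append(
                rank_permutation_test(ranks[:3], ranks[3:], n_perm=199, seed=rng)
            )
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01


class TestModelSimilarity:
    def _panel(self, gmap, seed=0):
        return GenotypePanel(
            np.random.default_rng(seed).integers(0, 2, (40, gmap.n_sites)).astype(float),
            [f"S{i}" for i in range(40)],
            gmap,
        )

    def test_self_similarity_is_one(self, flat_map):
        panel = self._panel(flat_map)
        m = _model([10, 80, 150], [1.0, -0.4, 0.7])
        assert model_similarity(m, m, flat_map, panel) == pytest.approx(1.0)

    def test_disjoint_chromosomes_score_zero(self):
        gmap = GeneticMap(
            ["c1"] * 5 + ["c2"] * 5,
            list(np.arange(1, 6) * 1000) * 2,
            list(np.arange(5.0)) * 2,
        )
        panel = self._panel(gmap, 1)
        a = _model([0, 2], [1.0, 0.5])
        b = _model([6, 8], [1.0, 0.5])
        assert model_similarity(a, b, gmap, panel) == 0.0

    def test_shift_by_delta_gives_exp_minus_one(self):
        # flat allele frequencies and equal effects isolate the distance factor
        gmap = GeneticMap(["c1"] * 100, np.arange(1, 101) * 1000, np.arange(100.0))
        geno = np.tile([0.0, 1.0], (100, 50)).reshape(100, 100).T
        geno = np.tile(np.array([[0.0], [1.0]]), (50, 100))  # f = 0.5 at all sites
        panel = GenotypePanel(geno, [f"S{i}" for i in range(100)], gmap)
        a = _model([10, 40, 70], [1.0, 1.0, 1.0])
        b = _model([20, 50, 80], [1.0, 1.0, 1.0])  # every site shifted by 10 cM
        params = MatchParams(delta_cm=10.0, tau=1.0, phi=0.1, gamma=0.2)
        got = model_similarity(a, b, gmap, panel, params)
        assert got == pytest.approx(np.exp(-1.0), abs=1e-9)

    def test_empty_model_warns_and_scores_zero(self, flat_map):
        panel = self._panel(flat_map)
        with pytest.warns(UserWarning):
            assert model_similarity(_model([], []), _model([1], [1.0]), flat_map, panel) == 0.0


class TestRankCorrelationAndOdds:
    def _setup(self, concordant=True):
        gmap = GeneticMap(["c1"] * 120, np.arange(1, 121) * 5000, np.arange(120) * 1.0)
        # hotspot table with occupied windows of increasing gene counts
        sites = [0, 30, 60, 90, 110]
        models = {}
        gi = 0
        for w, s in enumerate(sites):
            for _ in range(w + 1):
                models[f"g{gi}"] = _model([s], [1.0])
                gi += 1
        table = find_hotspots(models, gmap, window_bp=25_000)
        effects = np.arange(1, 6) * (1.0 if concordant else 1.0)
        order = np.arange(5) if concordant else np.arange(5)[::-1]
        qtl = _model(list(np.array(sites)[order]), list(np.arange(1, 6) / 5))
        return qtl, table, gmap

    def test_concordant_ranks_give_rho_one(self):
        qtl, table, gmap = self._setup(concordant=True)
        rho, p = hotspot_qtl_rank_correlation(qtl, table, gmap)
        assert rho == pytest.approx(1.0)
        assert p < 0.05

    def test_discordant_ranks_give_rho_minus_one(self):
        qtl, table, gmap = self._setup(concordant=False)
        rho, _ = hotspot_qtl_rank_correlation(qtl, table, gmap)
        assert rho == pytest.approx(-1.0)

    def test_too_few_usable_pairs_rejected(self):
        gmap = GeneticMap(["c1"] * 10, np.arange(1, 11) * 1000, np.arange(10.0))
        table = find_hotspots({"g": _model([0], [1.0])}, gmap)
        with pytest.raises(ValueError):
            hotspot_qtl_rank_correlation(_model([0, 1], [1.0, 0.5]), table, gmap)

    def test_wilcoxon_helper_pairs_genes_with_both_classes(self):
        labels = pd.DataFrame(
            {
                "gene": ["a", "a", "a", "b", "b", "c"],
                "site_idx": [1, 2, 3, 4, 5, 6],
                "effect": [2.0, 0.5, -0.4, 1.5, -0.2, 3.0],
                "label": ["cis", "trans", "trans", "cis", "trans", "trans"],
            }
        )
        stat, p, per_gene = cis_trans_effect_test(labels)
        assert len(per_gene) == 2  # gene c has no cis-eQTL
        assert per_gene.loc[per_gene["gene"] == "a", "cis_mean"].iloc[0] == 2.0

    def test_odds_ratio_helper_counts_sites(self):
        gmap = GeneticMap(["c1"] * 100, np.arange(1, 101) * 1000, np.arange(100.0))
        models = {f"g{i}": _model([5], [1.0]) for i in range(10)}
        table = find_hotspots(models, gmap, window_bp=25_000)
        odds, p, tab = hotspot_overlap_odds([5, 6, 80], table, gmap)
        assert tab.sum() == 100
        assert odds > 1.0
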