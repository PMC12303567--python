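"""Post-mapping regulatory architecture: hotspots, cis/trans, QTL↔eQTL matching.

Hotspots are 25-kb genomic windows in the top quartile of both the number
of eQTL and the number of distinct regulated genes (quartiles over occupied
windows).  cis-eQTL lie between 1,000 bp upstream of the gene's
transcription start and 200 bp downstream of its end, strand-aware; all
other eQTL are trans.  QTL are paired with a gene's eQTL by a global
(Needleman–Wunsch) alignment over the two position-sorted locus lists,
with pair scores decaying exponentially in genetic distance and effect-size
difference, and a gap penalty per unmatched QTL.  Rank/permutation and
similarity statistics quantify how much trait variation flows through the
regulatory network.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import as_rng
from .cross import GeneticMap, GenotypePanel, _cis_window
from .sparse import QTLModel

__all__ = [
    "MatchParams",
    "MatchResult",
    "find_hotspots",
    "classify_cis_trans",
    "match_qtl_eqtl",
    "align_loci",
    "rank_permutation_test",
    "model_similarity",
    "hotspot_qtl_rank_correlation",
    "cis_trans_effect_test",
    "hotspot_overlap_odds",
]


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------


def find_hotspots(
    eqtl_models: dict, gmap: GeneticMap, window_bp: int = 25_000
) -> pd.DataFrame:
    """Tile 25-kb windows and flag hotspots of expression regulation.

    Windows tile each chromosome from position 1.  A window is a hotspot
    iff both its eQTL count and its distinct-regulated-gene count reach the
    third quartile of the respective distributions over occupied windows
    (windows with ≥1 eQTL).

    Returns a DataFrame: chrom, start, end, n_genes, n_eqtl, hotspot.
    """
    rows = []
    slices = gmap.chrom_slices()
    counts: dict = {}
    for gene, model in eqtl_models.items():
        for si in model.sites:
            c = gmap.chrom[si]
            w = int((gmap.pos_bp[si] - 1) // window_bp)
            key = (c, w)
            if key not in counts:
                counts[key] = {"n_eqtl": 0, "genes": set()}
            counts[key]["n_eqtl"] += 1
            counts[key]["genes"].add(gene)
    for c, sl in slices.items():
        n_windows = int((gmap.pos_bp[sl].max() - 1) // window_bp) + 1
        for w in range(n_windows):
            entry = counts.get((c, w), None)
            rows.append(
                {
                    "chrom": c,
                    "start": w * window_bp + 1,
                    "end": (w + 1) * window_bp,
                    "n_genes": 0 if entry is None else len(entry["genes"]),
                    "n_eqtl": 0 if entry is None else entry["n_eqtl"],
                }
            )
    table = pd.DataFrame(rows)
    occupied = table["n_eqtl"] >= 1
    if occupied.any():
        q3_genes = table.loc[occupied, "n_genes"].quantile(0.75)
        q3_eqtl = table.loc[occupied, "n_eqtl"].quantile(0.75)
        table["hotspot"] = (
            occupied & (table["n_genes"] >= q3_genes) & (table["n_eqtl"] >= q3_eqtl)
        )
    else:
        table["hotspot"] = False
    return table


# ---------------------------------------------------------------------------
# cis / trans
# ---------------------------------------------------------------------------


def classify_cis_trans(
    eqtl_models: dict, gene_annotation: pd.DataFrame, gmap: GeneticMap
) -> pd.DataFrame:
    """Label every eQTL cis or trans relative to its target gene.

    cis: the eQTL lies on the gene's chromosome within [TSS − 1000 bp,
    gene end + 200 bp] in strand-aware orientation.  Genes missing from the
    annotation get all-trans labels with a warning; every eQTL receives
    exactly one label.
    """
    ann = gene_annotation.set_index("gene")
    rows = []
    missing = set()
    for gene, model in eqtl_models.items():
        have = gene in ann.index
        if not have:
            missing.add(gene)
        for si, beta in zip(model.sites, model.beta):
            label = "trans"
            if have:
                g = ann.loc[gene]
                strand = g.get("strand", "+") or "+"
                lo, hi = _cis_window(int(g["start"]), int(g["end"]), strand)
                if gmap.chrom[si] == g["chrom"] and lo <= gmap.pos_bp[si] <= hi:
                    label = "cis"
            rows.append(
                {"gene": gene, "site_idx": int(si), "effect": float(beta), "label": label}
            )
    if missing:
        warnings.warn(
            f"{len(missing)} genes missing from the annotation; their eQTL "
            "were labelled trans"
        )
    return pd.DataFrame(rows, columns=["gene", "site_idx", "effect", "label"])


# ---------------------------------------------------------------------------
# QTL ↔ eQTL matching
# ---------------------------------------------------------------------------


@dataclass
class MatchParams:
    """Pair-score constants for the locus alignment.

    delta_cm: genetic-distance decay scale; tau: effect-size decay scale
    (pooled SD of the two effect lists when None); phi: allele-frequency
    decay scale (similarity score only); gamma: penalty per unmatched QTL.
    """

    delta_cm: float = 10.0
    tau: float | None = None
    phi: float = 0.1
    gamma: float = 0.5


@dataclass
class MatchResult:
    """Outcome of the QTL↔eQTL alignment for one gene."""

    pairs: pd.DataFrame  # qtl_site, eqtl_site, score
    unmatched_qtl: np.ndarray
    total_score: float
    p_value: float | None = None


def _locus_order(sites, gmap: GeneticMap):
    """Sort site indices by (chromosome block, genetic position)."""
    sites = np.asarray(sites, dtype=int)
    chrom_rank = {c: i for i, c in enumerate(gmap.chrom_slices())}
    blocks = [chrom_rank[gmap.chrom[s]] for s in sites]
    cms = [gmap.pos_cm[s] for s in sites]
    return sites[np.lexsort((sites, cms, blocks))]


def _pair_score_matrix(
    sites_a, eff_a, sites_b, eff_b, gmap, params: MatchParams, freqs=None
) -> np.ndarray:
    tau = params.tau
    if tau is None:
        pooled = np.concatenate([np.abs(eff_a), np.abs(eff_b)])
        tau = float(pooled.std()) or 1.0
    S = np.zeros((len(sites_a), len(sites_b)))
    for i, (sa, ba) in enumerate(zip(sites_a, eff_a)):
        for j, (sb, bb) in enumerate(zip(sites_b, eff_b)):
            if gmap.chrom[sa] != gmap.chrom[sb]:
                continue
            d = abs(gmap.pos_cm[sa] - gmap.pos_cm[sb])
            s = np.exp(-d / params.delta_cm) * np.exp(-abs(ba - bb) / tau)
            if freqs is not None:
                s *= np.exp(-abs(freqs[sa] - freqs[sb]) / params.phi)
            S[i, j] = s
    return S


def align_loci(score: np.ndarray, gamma: float) -> tuple:
    """Global monotone alignment of two ordered locus lists.

    Needleman–Wunsch over rows (QTL) and columns (eQTL): pairing row i with
    column j earns ``score[i, j]``, skipping a row costs ``gamma``, skipping
    a column is free.  Returns ``(total, pairs)`` with pairs as (i, j)
    index tuples.
    """
    na, nb = score.shape
    F = np.zeros((na + 1, nb + 1))
    for i in range(1, na + 1):
        F[i, 0] = F[i - 1, 0] - gamma
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            F[i, j] = max(
                F[i - 1, j - 1] + score[i - 1, j - 1],
                F[i - 1, j] - gamma,
                F[i, j - 1],
            )
    pairs = []
    i, j = na, nb
    while i > 0 and j > 0:
        if np.isclose(F[i, j], F[i - 1, j - 1] + score[i - 1, j - 1]):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif np.isclose(F[i, j], F[i, j - 1]):
            j -= 1
        else:
            i -= 1
    pairs.reverse()
    return float(F[na, nb]), pairs


def match_qtl_eqtl(
    qtl_model: QTLModel,
    gene_expression,
    panel: GenotypePanel,
    eqtl_model: QTLModel,
    params: MatchParams | None = None,
) -> MatchResult:
    """Match a trait's QTL to one gene's eQTL by global alignment.

    The QTL's predicted effects on the gene are refit by multiple
    regression of the gene's expression on the genotypes at the QTL sites;
    pair scores decay exponentially with genetic distance and with the
    difference between that predicted effect and the eQTL effect; pairs
    never cross chromosomes.  The alignment maximizes the total log pair
    score minus γ per unmatched QTL, so a pair only forms when its score
    exceeds e^{-γ}; ``pairs['score']`` reports the multiplicative scores.
    """
    params = params or MatchParams()
    gmap = panel.gmap
    y = np.asarray(gene_expression, dtype=float).ravel()
    q_sites = _locus_order(qtl_model.sites, gmap)
    if len(q_sites) == 0:
        raise ValueError("QTL model is empty")
    # predicted expression effect of each QTL: joint OLS refit
    Xq = panel.genotypes[:, q_sites]
    Xq = (Xq - Xq.mean(axis=0)) / np.where(Xq.std(axis=0) > 0, Xq.std(axis=0), 1.0)
    A = np.column_stack([np.ones(len(y)), Xq])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    q_eff = coef[1:]

    e_order = _locus_order(eqtl_model.sites, gmap) if eqtl_model.size else np.empty(0, int)
    site_to_eff = dict(zip(eqtl_model.sites, eqtl_model.beta))
    e_eff = np.array([site_to_eff[s] for s in e_order])

    if len(e_order) == 0:
        return MatchResult(
            pairs=pd.DataFrame(columns=["qtl_site", "eqtl_site", "score"]),
            unmatched_qtl=q_sites,
            total_score=-params.gamma * len(q_sites),
        )
    S = _pair_score_matrix(q_sites, q_eff, e_order, e_eff, gmap, params)
    # align on the log scale: a pair whose score decays below e^{-γ} is
    # worth less than leaving the QTL unmatched
    with np.errstate(divide="ignore"):
        log_S = np.where(S > 0, np.log(np.where(S > 0, S, 1.0)), -1e18)
    total, idx_pairs = align_loci(log_S, params.gamma)
    pairs = pd.DataFrame(
        [
            {
                "qtl_site": int(q_sites[i]),
                "eqtl_site": int(e_order[j]),
                "score": float(S[i, j]),
            }
            for i, j in idx_pairs
        ],
        columns=["qtl_site", "eqtl_site", "score"],
    )
    matched = set(pairs["qtl_site"]) if len(pairs) else set()
    unmatched = np.array([s for s in q_sites if s not in matched], dtype=int)
    return MatchResult(pairs=pairs, unmatched_qtl=unmatched, total_score=total)


def rank_permutation_test(
    matched_ranks,
    unmatched_ranks,
    n_perm: int = 999,
    seed=0,
    add_one: bool = False,
) -> float:
    """Permutation p-value for matched QTL outranking unmatched QTL.

    Ranks come from the effect-size ordering of the full QTL model (larger
    rank = larger |effect|).  p is the proportion of ``n_perm`` random
    same-size subsets of the unmatched ranks whose average rank exceeds the
    matched average; the add-one convention is available as an option.
    Returns NaN when there are no unmatched QTL.
    """
    matched = np.asarray(matched_ranks, dtype=float)
    unmatched = np.asarray(unmatched_ranks, dtype=float)
    if len(unmatched) == 0:
        return float("nan")
    if len(matched) > len(unmatched):
        raise ValueError("subset size exceeds the number of unmatched QTL")
    rng = as_rng(seed)
    obs = matched.mean()
    m = len(matched)
    # vectorized subsets without replacement: top-m of a random ordering
    keys = rng.random((n_perm, len(unmatched)))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    means = unmatched[idx].mean(axis=1)
    # ties at half weight (mid-p): integer ranks tie with positive
    # probability, and counting ties as either 0 or 1 breaks the uniform
    # null distribution this p-value is calibrated against
    hits = float((means > obs).sum()) + 0.5 * float((means == obs).sum())
    if add_one:
        return (hits + 1) / (n_perm + 1)
    return hits / n_perm


def model_similarity(
    model_a: QTLModel,
    model_b: QTLModel,
    gmap: GeneticMap,
    panel: GenotypePanel,
    params: MatchParams | None = None,
) -> float:
    """Similarity of two sparse locus models on a [0, 1] scale.

    The same global alignment scores pairs by genetic distance, effect-size
    difference and panel allele-frequency agreement; the alignment score is
    normalized by the larger self-score, so self-similarity is 1 and
    disjoint cross-chromosome models score 0.
    """
    params = params or MatchParams()
    if model_a.size == 0 or model_b.size == 0:
        warnings.warn("empty model; similarity is 0")
        return 0.0
    freqs = panel.genotypes.mean(axis=0)
    tau = params.tau
    if tau is None:
        pooled = np.concatenate([np.abs(model_a.beta), np.abs(model_b.beta)])
        tau = float(pooled.std()) or 1.0
        params = MatchParams(params.delta_cm, tau, params.phi, params.gamma)

    def ordered(model):
        order = _locus_order(model.sites, gmap)
        eff = dict(zip(model.sites, model.beta))
        return order, np.array([eff[s] for s in order])

    sa, ea = ordered(model_a)
    sb, eb = ordered(model_b)
    S_ab = _pair_score_matrix(sa, ea, sb, eb, gmap, params, freqs)
    S_aa = _pair_score_matrix(sa, ea, sa, ea, gmap, params, freqs)
    S_bb = _pair_score_matrix(sb, eb, sb, eb, gmap, params, freqs)
    cross, _ = align_loci(S_ab, params.gamma)
    self_a, _ = align_loci(S_aa, params.gamma)
    self_b, _ = align_loci(S_bb, params.gamma)
    denom = max(self_a, self_b)
    if denom <= 0:
        return 0.0
    return float(np.clip(cross / denom, 0.0, 1.0))


# ---------------------------------------------------------------------------
# rank correlation and contingency helpers
# ---------------------------------------------------------------------------


def _exact_spearman_p(x, y) -> float:
    """Exact permutation p-value for Spearman rho (two-sided), tiny n."""
    obs = abs(stats.spearmanr(x, y).statistic)
    n = len(x)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho = stats.spearmanr(x, [y[i] for i in perm]).statistic
        total += 1
        if abs(rho) >= obs - 1e-12:
            count += 1
    return count / total


def hotspot_qtl_rank_correlation(
    qtl_model: QTLModel,
    hotspot_table: pd.DataFrame,
    gmap: GeneticMap,
    window_bp: int = 25_000,
) -> tuple:
    """Spearman correlation between QTL effect ranks and hotspot gene counts.

    Each QTL maps to its containing window; QTL in windows with zero eQTL
    are excluded.  Returns (rho, p); p uses the large-sample approximation,
    or exact permutation below 10 usable pairs.
    """
    win = hotspot_table.set_index(
        ["chrom", hotspot_table["start"].floordiv(window_bp)]
    )
    effects, gene_counts = [], []
    for si, beta in zip(qtl_model.sites, qtl_model.beta):
        key = (gmap.chrom[si], int((gmap.pos_bp[si] - 1) // window_bp))
        if key not in win.index:
            continue
        row = win.loc[key]
        if int(np.atleast_1d(row["n_eqtl"])[0]) == 0:
            continue
        effects.append(abs(beta))
        gene_counts.append(int(np.atleast_1d(row["n_genes"])[0]))
    if len(effects) < 3:
        raise ValueError("fewer than 3 QTL fall in occupied windows")
    rho = stats.spearmanr(effects, gene_counts).statistic
    if len(effects) < 10:
        p = _exact_spearman_p(effects, gene_counts)
    else:
        p = stats.spearmanr(effects, gene_counts).pvalue
    return float(rho), float(p)


def cis_trans_effect_test(labels: pd.DataFrame) -> tuple:
    """Paired comparison of per-gene mean |effect| of cis- vs trans-eQTL.

    Uses the Wilcoxon signed-rank test across genes that have both classes.
    Returns (statistic, p, per-gene DataFrame).
    """
    rows = []
    for gene, grp in labels.groupby("gene"):
        cis = grp.loc[grp["label"] == "cis", "effect"].abs()
        trans = grp.loc[grp["label"] == "trans", "effect"].abs()
        if len(cis) and len(trans):
            rows.append(
                {"gene": gene, "cis_mean": cis.mean(), "trans_mean": trans.mean()}
            )
    per_gene = pd.DataFrame(rows, columns=["gene", "cis_mean", "trans_mean"])
    if len(per_gene) < 1:
        return float("nan"), float("nan"), per_gene
    diff = per_gene["cis_mean"] - per_gene["trans_mean"]
    if np.allclose(diff, 0):
        return 0.0, 1.0, per_gene
    res = stats.wilcoxon(per_gene["cis_mean"], per_gene["trans_mean"])
    return float(res.statistic), float(res.pvalue), per_gene


def hotspot_overlap_odds(
    qtl_sites,
    hotspot_table: pd.DataFrame,
    gmap: GeneticMap,
    window_bp: int = 25_000,
) -> tuple:
    """2×2 odds ratio + chi-square for QTL lying inside eQTL hotspots.

    Contingency: all map sites × {QTL, non-QTL} × {in hotspot, outside}.
    Returns (odds_ratio, chi2_p, table).
    """
    hot = set()
    for _, row in hotspot_table[hotspot_table["hotspot"]].iterrows():
        hot.add((row["chrom"], int((row["start"] - 1) // window_bp)))
    qtl = set(int(s) for s in np.asarray(qtl_sites, dtype=int))
    tab = np.zeros((2, 2))
    for si in range(gmap.n_sites):
        in_hot = (gmap.chrom[si], int((gmap.pos_bp[si] - 1) // window_bp)) in hot
        is_qtl = si in qtl
        tab[0 if is_qtl else 1, 0 if in_hot else 1] += 1
    a, b, c, d = tab.ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    chi2, p = stats.chi2_contingency(tab)[:2] if tab.min() >= 0 else (np.nan, np.nan)
    return float(odds), float(p), tab
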