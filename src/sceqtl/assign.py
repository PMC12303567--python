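"""Assigning cells to reference strains, doublet flagging, consensus profiles.

A cell's posterior genotype g_c is compared with every strain genotype g_s
by the expected distance Σ_i g_c + g_s − 2·g_c·g_s (the expected Hamming
distance when both vectors are read as independent Bernoulli probabilities
of the RM allele).  The best match is accepted only if it beats the best
match against randomly generated strain panels; site-wise shuffling of the
real panel preserves per-site allele frequencies while destroying linkage,
so the null distance scale stays realistic.  Benjamini–Hochberg controls
the false-assignment rate across cells.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._utils import as_rng
from .cross import CellAlleleCounts, GenotypePanel

__all__ = [
    "expected_distance",
    "relatedness",
    "assign_cells",
    "flag_doublets",
    "consensus_profiles",
    "normalize_expression",
]


def expected_distance(g_c, g_s):
    """Expected genotype distance Σ (g_c + g_s − 2 g_c g_s).

    Symmetric; equals the Hamming distance on hard {0,1} vectors.  Inputs
    must share length and lie in [0, 1].
    """
    g_c = np.asarray(g_c, dtype=float)
    g_s = np.asarray(g_s, dtype=float)
    if g_c.shape != g_s.shape:
        raise ValueError("genotype vectors differ in length")
    if np.any((g_c < 0) | (g_c > 1)) or np.any((g_s < 0) | (g_s > 1)):
        raise ValueError("genotype entries must lie in [0, 1]")
    return float(np.sum(g_c + g_s - 2.0 * g_c * g_s))


def _round_genotype(g):
    """Round at 0.5, ties to RM (1)."""
    return (np.asarray(g, dtype=float) >= 0.5).astype(float)


def relatedness(g_c, g_s, return_sign: bool = False):
    """Adjusted R² between rounded genotype vectors.

    Genotypes are rounded at 0.5 (ties → RM) before the simple-regression
    R², which is then adjusted for degrees of freedom:
    1 − (1 − R²)(n − 1)/(n − 2).  R² is sign-blind, so the slope sign is
    available via ``return_sign``.  Zero variance in either vector yields 0
    with a warning.
    """
    a = _round_genotype(g_c)
    b = _round_genotype(g_s)
    if a.shape != b.shape:
        raise ValueError("genotype vectors differ in length")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 sites")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        warnings.warn("zero variance in a genotype vector; relatedness set to 0")
        return (0.0, 0) if return_sign else 0.0
    r = np.corrcoef(a, b)[0, 1]
    r2 = r * r
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    if return_sign:
        return float(adj), int(np.sign(r))
    return float(adj)


def _distance_matrix(post: np.ndarray, panel_geno: np.ndarray) -> np.ndarray:
    """Expected distance between every cell and every strain (cells × strains)."""
    sc = post.sum(axis=1)  # Σ g_c
    ss = panel_geno.sum(axis=1)  # Σ g_s
    cross = post @ panel_geno.T
    return sc[:, None] + ss[None, :] - 2.0 * cross


def assign_cells(
    posteriors: np.ndarray,
    panel: GenotypePanel,
    n_null: int = 100,
    fdr_threshold: float = 0.05,
    seed=0,
) -> pd.DataFrame:
    """Assign each cell to its best-matching panel strain with a permutation null.

    Per cell the best match minimizes the expected distance.  The null
    distribution of the best-match distance comes from ``n_null`` randomly
    generated panels of the same size: fresh segregants simulated on the
    panel's genetic map, so the null strains carry realistic allele
    frequencies *and* linkage but cannot contain the cell's own strain.
    (Site-wise shuffling of the real panel would destroy linkage and make
    any real segregant beat the null, voiding false-assignment control.)
    p = (1 + #null best ≤ observed)/(1 + n_null), BH-adjusted across
    cells; a cell is assigned iff q < ``fdr_threshold``.

    Returns a DataFrame with one row per cell: best/second strain, expected
    distance, relatedness to the best strain, p, q and the assigned flag.
    """
    post = np.asarray(posteriors, dtype=float)
    if panel.n_strains < 2:
        raise ValueError("panel must contain at least 2 strains")
    if post.shape[1] != panel.n_sites:
        raise ValueError("posterior/panel site sets differ")
    if n_null < 19:
        raise ValueError("n_null must be ≥ 19")
    rng = as_rng(seed)
    G = panel.genotypes
    n_cells = post.shape[0]

    dist = _distance_matrix(post, G)
    order = np.argsort(dist, axis=1)
    best = order[:, 0]
    second = order[:, 1]
    best_dist = dist[np.arange(n_cells), best]

    from .cross import simulate_cross  # deferred: cross imports nothing from here

    null_better = np.zeros(n_cells, dtype=np.int64)
    for _ in range(n_null):
        null_panel = simulate_cross(panel.gmap, panel.n_strains, rng)
        null_best = _distance_matrix(post, null_panel.genotypes).min(axis=1)
        null_better += null_best <= best_dist
    p = (1.0 + null_better) / (1.0 + n_null)
    q = _bh_adjust(p)

    rel = np.array(
        [relatedness(post[i], G[best[i]]) for i in range(n_cells)]
    )
    return pd.DataFrame(
        {
            "cell": np.arange(n_cells),
            "best_strain": panel.strain_ids[best],
            "second_strain": panel.strain_ids[second],
            "distance": best_dist,
            "relatedness": rel,
            "p_value": p,
            "q_value": q,
            "assigned": q < fdr_threshold,
            "doublet": False,
        }
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def flag_doublets(
    counts: CellAlleleCounts,
    assignments: pd.DataFrame,
    panel: GenotypePanel,
    r2_threshold: float = 0.1,
) -> pd.DataFrame:
    """Flag doublet barcodes, updating the ``doublet`` column in place.

    A barcode is a doublet iff, in order: (1) its covered-site count is at
    or above the third quartile across cells, (2) it has no significant
    assignment, and (3) its two best-matching strains share genotype
    R² < ``r2_threshold`` (a droplet holding two unrelated strains looks
    like neither).  Assigned and doublet flags are mutually exclusive by
    clause 2.
    """
    cov = counts.coverage()
    q3 = np.quantile(cov, 0.75)
    strain_index = {s: i for i, s in enumerate(panel.strain_ids)}
    flags = np.zeros(len(assignments), dtype=bool)
    for i, row in assignments.iterrows():
        if cov[int(row["cell"])] < q3:
            continue
        if row["assigned"]:
            continue
        g1 = panel.genotypes[strain_index[row["best_strain"]]]
        g2 = panel.genotypes[strain_index[row["second_strain"]]]
        if relatedness(g1, g2) < r2_threshold:
            flags[i] = True
    out = assignments.copy()
    out["doublet"] = flags
    return out


def consensus_profiles(
    assignments: pd.DataFrame,
    posteriors: np.ndarray,
    umi: np.ndarray,
) -> tuple:
    """Per-strain consensus genotype and expression from assigned cells.

    Consensus genotype is the per-site median of the assigned cells'
    posteriors (robust to outlier cells); consensus expression is the UMI
    profile of the assigned cell with the largest total UMI count (the
    best-covered representative, which averages out cell-cycle phase less
    than a mean would distort counts).  Strains with zero assigned cells
    are excluded.

    Returns ``(strain_ids, consensus_genotypes, consensus_expression)``.
    """
    post = np.asarray(posteriors, dtype=float)
    umi = np.asarray(umi)
    ok = assignments[assignments["assigned"] & ~assignments["doublet"]]
    strains, genos, exprs = [], [], []
    for strain, grp in ok.groupby("best_strain", sort=True):
        cells = grp["cell"].to_numpy(int)
        strains.append(strain)
        genos.append(np.median(post[cells], axis=0))
        totals = umi[cells].sum(axis=1)
        exprs.append(umi[cells[np.argmax(totals)]])
    if not strains:
        raise ValueError("no strain has an assigned cell")
    return (
        np.asarray(strains, dtype=object),
        np.vstack(genos),
        np.vstack(exprs).astype(float),
    )


def low_rank_smooth(counts: np.ndarray, rank: int = 20) -> np.ndarray:
    """Truncated-SVD reconstruction of an expression matrix.

    A simple denoising pre-transform: keep the top ``rank`` singular
    components of the centered matrix.  Usable as the ``denoise`` hook of
    :func:`normalize_expression`; heavier learned denoisers can be plugged
    into the same hook.
    """
    counts = np.asarray(counts, dtype=float)
    rank = min(rank, min(counts.shape))
    mu = counts.mean(axis=0)
    U, s, Vt = np.linalg.svd(counts - mu, full_matrices=False)
    return mu + (U[:, :rank] * s[:rank]) @ Vt[:rank]


def normalize_expression(counts: np.ndarray, denoise=None) -> np.ndarray:
    """Standardize each gene, then divide by the cell's total raw count.

    The per-gene z-score makes genes comparable; the subsequent division by
    the cell total controls for molecule-count (library size) differences
    across cells.  Zero-variance genes come out as zero columns.  An
    optional ``denoise`` callable (e.g. :func:`low_rank_smooth`) is applied
    to the raw counts first; cell totals still come from the raw counts.
    """
    counts = np.asarray(counts, dtype=float)
    raw_totals = counts.sum(axis=1)
    if denoise is not None:
        counts = np.asarray(denoise(counts), dtype=float)
    totals = raw_totals
    if np.any(totals <= 0):
        warnings.warn("cells with zero total count; their normalized profile is 0")
        totals = np.where(totals > 0, totals, 1.0)
    mu = counts.mean(axis=0)
    sd = counts.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (counts - mu) / sd
    return z / totals[:, None]
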