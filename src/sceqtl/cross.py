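"""Synthetic haploid F2 crosses with planted genetic architectures.

Emulates a BY×RM-style yeast cross: haploid segregants are mosaics of the
two parental genomes, recombination follows a Poisson (Haldane, no
interference) process on the genetic map, and each segregant carries a
fitness value plus a per-gene mean expression profile generated from a
planted additive architecture (fitness QTL, cis-/trans-eQTL, hotspots).
A single-cell observation layer then produces sparse allele counts
(low breadth of coverage, sequencing/RT errors, index swapping, doublets)
and negative-binomial UMI counts, with full ground truth for every cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse as sp

from ._utils import as_rng

__all__ = [
    "GeneticMap",
    "GenotypePanel",
    "CellAlleleCounts",
    "ArchitectureSpec",
    "TrueArchitecture",
    "ObservationParams",
    "simulate_cross",
    "plant_architecture",
    "simulate_cells",
]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMap:
    """Per-site genomic coordinates: chromosome, bp position, cM position.

    Sites are sorted by (chromosome, physical position); genetic position is
    non-decreasing within a chromosome and physical positions are unique per
    chromosome.  Physical coordinates are 1-based inclusive.
    """

    chrom: np.ndarray  # str per site
    pos_bp: np.ndarray  # int per site
    pos_cm: np.ndarray  # float per site
    site_id: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        chrom = np.asarray(self.chrom, dtype=object)
        pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        pos_cm = np.asarray(self.pos_cm, dtype=float)
        if not (len(chrom) == len(pos_bp) == len(pos_cm)):
            raise ValueError("chrom, pos_bp and pos_cm must have equal length")
        if len(chrom) == 0:
            raise ValueError("genetic map is empty")
        if np.any(pos_cm < 0):
            raise ValueError("genetic positions must be non-negative")
        # sites must arrive sorted by (chromosome block, physical position)
        seen: dict = {}
        order = []
        for c in chrom:
            if c not in seen:
                seen[c] = len(seen)
            order.append(seen[c])
        order = np.asarray(order)
        if np.any(np.diff(order) < 0):
            raise ValueError("sites must be grouped by chromosome")
        for c, sl in _chrom_slices(chrom).items():
            if np.any(np.diff(pos_bp[sl]) <= 0):
                raise ValueError(f"physical positions not strictly increasing on {c}")
            if np.any(np.diff(pos_cm[sl]) < 0):
                raise ValueError(f"genetic positions decrease on {c}")
        sid = self.site_id
        if sid is None:
            sid = np.array([f"{c}:{p}" for c, p in zip(chrom, pos_bp)], dtype=object)
        else:
            sid = np.asarray(sid, dtype=object)
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos_bp", pos_bp)
        object.__setattr__(self, "pos_cm", pos_cm)
        object.__setattr__(self, "site_id", sid)

    @property
    def n_sites(self) -> int:
        return len(self.chrom)

    def chrom_slices(self) -> dict:
        """Contiguous slice per chromosome, in map order."""
        return _chrom_slices(self.chrom)

    def interval_morgans(self) -> dict:
        """Adjacent-site genetic distances (Morgans) per chromosome."""
        return {
            c: np.diff(self.pos_cm[sl]) / 100.0 for c, sl in self.chrom_slices().items()
        }

    @classmethod
    def regular(
        cls,
        n_chrom: int,
        sites_per_chrom: int,
        bp_spacing: int = 500,
        cm_per_interval: float = 0.25,
    ) -> "GeneticMap":
        """Evenly spaced map, handy for simulations and tests."""
        chrom = np.repeat(
            [f"chr{i + 1:02d}" for i in range(n_chrom)], sites_per_chrom
        ).astype(object)
        pos_bp = np.tile(np.arange(sites_per_chrom) * bp_spacing + 1, n_chrom)
        pos_cm = np.tile(np.arange(sites_per_chrom) * cm_per_interval, n_chrom)
        return cls(chrom, pos_bp, pos_cm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.site_id,
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "pos_cm": self.pos_cm,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        return cls(
            df["chrom"].to_numpy(object),
            df["pos_bp"].to_numpy(np.int64),
            df["pos_cm"].to_numpy(float),
            site_id=df["site"].to_numpy(object) if "site" in df else None,
        )


def _chrom_slices(chrom: np.ndarray) -> dict:
    out: dict = {}
    start = 0
    for i in range(1, len(chrom) + 1):
        if i == len(chrom) or chrom[i] != chrom[start]:
            out[chrom[start]] = slice(start, i)
            start = i
    return out


@dataclass
class GenotypePanel:
    """Strain × site RM-allele frequencies in [0, 1] with map coordinates."""

    genotypes: np.ndarray  # (n_strains, n_sites) float
    strain_ids: np.ndarray  # str
    gmap: GeneticMap

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.strain_ids = np.asarray(self.strain_ids, dtype=object)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D")
        if self.genotypes.shape[0] != len(self.strain_ids):
            raise ValueError("strain_ids length mismatch")
        if self.genotypes.shape[1] != self.gmap.n_sites:
            raise ValueError("site dimension does not match the map")
        if np.any(self.genotypes < 0) or np.any(self.genotypes > 1):
            raise ValueError("genotype frequencies must lie in [0, 1]")

    @property
    def n_strains(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.genotypes, index=self.strain_ids, columns=self.gmap.site_id
        )


@dataclass
class CellAlleleCounts:
    """Sparse per-cell, per-site RM/BY read counts (HMM emissions)."""

    rm: sp.csr_matrix  # (n_cells, n_sites)
    by: sp.csr_matrix
    barcodes: np.ndarray
    gmap: GeneticMap

    def __post_init__(self):
        self.rm = sp.csr_matrix(self.rm)
        self.by = sp.csr_matrix(self.by)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.rm.shape != self.by.shape:
            raise ValueError("rm/by count shapes differ")
        if self.rm.shape[0] != len(self.barcodes):
            raise ValueError("barcode length mismatch")
        if self.rm.shape[1] != self.gmap.n_sites:
            raise ValueError("site dimension does not match the map")

    @property
    def n_cells(self) -> int:
        return self.rm.shape[0]

    def coverage(self) -> np.ndarray:
        """Number of sites with at least one read, per cell."""
        return np.asarray(((self.rm + self.by) > 0).sum(axis=1)).ravel()

    def to_triplets(self) -> pd.DataFrame:
        cov = (self.rm + self.by).tocoo()
        rm = self.rm.toarray()
        by = self.by.toarray()
        rows, cols = cov.row, cov.col
        return pd.DataFrame(
            {
                "barcode": self.barcodes[rows],
                "site": self.gmap.site_id[cols],
                "rm_count": rm[rows, cols].astype(int),
                "by_count": by[rows, cols].astype(int),
            }
        )


# ---------------------------------------------------------------------------
# planted architecture
# ---------------------------------------------------------------------------


@dataclass
class ArchitectureSpec:
    """What to plant: counts and effect/noise scales for QTL and eQTL.

    Fitness: `n_qtl` additive loci with N(0, qtl_effect_sd²) effects; the
    residual SD is set so the realised narrow-sense heritability equals
    `fitness_h2` in expectation.  Expression: `n_genes` genes laid out along
    the genome; `cis_fraction` of them get one cis-eQTL; trans-eQTL are drawn
    either from `n_hotspots` shared hotspot loci (clustered regulation) or
    uniformly.  Per-gene expression noise is set from `expression_h2`.
    """

    n_genes: int = 200
    n_qtl: int = 10
    qtl_effect_sd: float = 1.0
    fitness_h2: float = 0.5
    cis_fraction: float = 0.15
    trans_per_gene: float = 2.0
    n_hotspots: int = 3
    hotspot_gene_fraction: float = 0.5
    cis_effect_sd: float = 1.0
    trans_effect_sd: float = 0.5
    expression_h2: float = 0.4
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    gene_length_bp: int = 1000


@dataclass
class TrueArchitecture:
    """Ground truth of a planted architecture, for recovery tests."""

    fitness_qtl: pd.DataFrame  # site_idx, effect
    eqtl: pd.DataFrame  # gene, site_idx, effect, label
    hotspots: pd.DataFrame  # chrom, start_bp, end_bp, site_idx
    genes: pd.DataFrame  # gene, chrom, start, end, strand, baseline
    fitness_h2: float
    expression_h2: float

    def to_json(self) -> str:
        payload = {
            "fitness_qtl": self.fitness_qtl.to_dict(orient="list"),
            "eqtl": self.eqtl.to_dict(orient="list"),
            "hotspots": self.hotspots.to_dict(orient="list"),
            "genes": self.genes.to_dict(orient="list"),
            "fitness_h2": self.fitness_h2,
            "expression_h2": self.expression_h2,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TrueArchitecture":
        d = json.loads(text)
        return cls(
            pd.DataFrame(d["fitness_qtl"]),
            pd.DataFrame(d["eqtl"]),
            pd.DataFrame(d["hotspots"]),
            pd.DataFrame(d["genes"]),
            d["fitness_h2"],
            d["expression_h2"],
        )


@dataclass
class ObservationParams:
    """Single-cell observation layer parameters.

    Defaults mirror the dataset this package emulates: mean breadth of
    coverage 0.03 (fraction of polymorphic sites with ≥1 read per cell),
    4.83 cell barcodes per segregant on average, and a 10% doublet rate.
    """

    breadth: float = 0.03
    error_rate: float = 0.002
    swap_rate: float = 0.0
    mean_cells_per_strain: float = 4.83
    doublet_rate: float = 0.10
    mean_library_size: float = 5000.0
    library_size_cv: float = 0.5
    nb_dispersion: float = 0.5  # NB shape: var = mu + mu^2 / dispersion^-1 ... see note
    reads_per_covered_site: float = 1.0

    def validate(self) -> None:
        for name in ("breadth", "error_rate", "swap_rate", "doublet_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mean_library_size <= 0:
            raise ValueError("library sizes must be positive")
        if self.mean_cells_per_strain <= 0:
            raise ValueError("mean_cells_per_strain must be positive")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def simulate_cross(gmap: GeneticMap, n_segregants: int, seed) -> GenotypePanel:
    """Simulate haploid F2 segregants as parental mosaics.

    Crossovers follow a Poisson process on the genetic map (Haldane map
    function, no interference): the allele switches between adjacent sites
    with probability r = ½(1 − exp(−2d)) for genetic distance d Morgans.
    Chromosomes assort independently; the first allele of each chromosome is
    RM with probability ½, so the marginal RM frequency is ½ at every site.
    """
    if n_segregants < 1:
        raise ValueError("n_segregants must be ≥ 1")
    rng = as_rng(seed)
    n = gmap.n_sites
    geno = np.empty((n_segregants, n), dtype=float)
    for c, sl in gmap.chrom_slices().items():
        d = np.diff(gmap.pos_cm[sl]) / 100.0
        r = 0.5 * (1.0 - np.exp(-2.0 * d))
        m = sl.stop - sl.start
        start = rng.integers(0, 2, size=n_segregants)
        switches = rng.random((n_segregants, m - 1)) < r[None, :]
        # cumulative XOR of switch indicators gives the mosaic
        states = np.empty((n_segregants, m), dtype=np.int64)
        states[:, 0] = start
        if m > 1:
            states[:, 1:] = (
                start[:, None] + np.cumsum(switches.astype(np.int64), axis=1)
            ) % 2
        geno[:, sl] = states
    ids = np.array([f"S{i:05d}" for i in range(n_segregants)], dtype=object)
    return GenotypePanel(geno, ids, gmap)


def _cis_window(start: int, end: int, strand: str) -> tuple:
    """Genomic window [TSS−1000, gene end+200] in strand-aware orientation."""
    if strand == "-":
        return start - 200, end + 1000
    return start - 1000, end + 200


def plant_architecture(
    panel: GenotypePanel, spec: ArchitectureSpec, seed
) -> tuple:
    """Plant fitness QTL and cis/trans eQTL on a panel.

    Returns (TrueArchitecture, fitness vector, strain × gene mean-expression
    matrix).  Fitness is Σ β_q·g_q plus Gaussian noise scaled to the target
    heritability; each gene's mean expression is a baseline plus its planted
    additive effects plus noise scaled to the target per-gene heritability.
    """
    rng = as_rng(seed)
    gmap = panel.gmap
    n_sites = gmap.n_sites
    if spec.n_qtl > n_sites:
        raise ValueError("requested more QTL than available sites")

    # --- gene table: genes tiled along chromosomes near sites
    genes = []
    site_choices = rng.choice(n_sites, size=spec.n_genes, replace=spec.n_genes > n_sites)
    site_choices.sort()
    for g, si in enumerate(site_choices):
        start = int(gmap.pos_bp[si])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            {
                "gene": f"G{g:04d}",
                "chrom": gmap.chrom[si],
                "start": start,
                "end": start + spec.gene_length_bp - 1,
                "strand": strand,
                "baseline": float(
                    np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sd))
                ),
                "_site": int(si),
            }
        )
    gene_df = pd.DataFrame(genes)

    # --- fitness QTL
    qtl_sites = np.sort(rng.choice(n_sites, size=spec.n_qtl, replace=False))
    qtl_eff = rng.normal(0.0, spec.qtl_effect_sd, size=spec.n_qtl)
    # guarantee effects clear of zero so every planted QTL is detectable in principle
    qtl_eff += np.sign(qtl_eff) * 0.1 * spec.qtl_effect_sd
    G = panel.genotypes
    genetic = G[:, qtl_sites] @ qtl_eff
    vg = np.var(genetic)
    if spec.fitness_h2 >= 1.0 or vg == 0:
        noise_sd = 0.0
    else:
        noise_sd = float(np.sqrt(vg * (1.0 - spec.fitness_h2) / spec.fitness_h2))
    fitness = genetic + rng.normal(0.0, noise_sd, size=panel.n_strains)

    # --- hotspot loci: trans regulators shared by many genes
    hot_sites = (
        np.sort(rng.choice(n_sites, size=spec.n_hotspots, replace=False))
        if spec.n_hotspots > 0
        else np.array([], dtype=int)
    )
    hotspots = pd.DataFrame(
        {
            "chrom": gmap.chrom[hot_sites],
            "start_bp": gmap.pos_bp[hot_sites],
            "end_bp": gmap.pos_bp[hot_sites],
            "site_idx": hot_sites,
        }
    )

    # --- per-gene eQTL
    eqtl_rows = []
    expr_mean = np.empty((panel.n_strains, spec.n_genes))
    pos_bp = gmap.pos_bp
    chrom = gmap.chrom
    for g in range(spec.n_genes):
        row = gene_df.iloc[g]
        effects: list = []
        # cis-eQTL: a site inside the gene's cis window on its chromosome
        if rng.random() < spec.cis_fraction:
            lo, hi = _cis_window(row["start"], row["end"], row["strand"])
            cand = np.flatnonzero(
                (chrom == row["chrom"]) & (pos_bp >= lo) & (pos_bp <= hi)
            )
            if len(cand):
                si = int(rng.choice(cand))
                beta = float(rng.normal(0, spec.cis_effect_sd))
                beta += np.sign(beta) * 0.5 * spec.cis_effect_sd
                effects.append((si, beta, "cis"))
        # trans-eQTL: hotspot loci for a fraction of genes, then random extras
        if len(hot_sites) and rng.random() < spec.hotspot_gene_fraction:
            si = int(rng.choice(hot_sites))
            beta = float(rng.normal(0, spec.trans_effect_sd))
            beta += np.sign(beta) * 0.5 * spec.trans_effect_sd
            effects.append((si, beta, "trans"))
        n_extra = rng.poisson(spec.trans_per_gene)
        for si in rng.choice(n_sites, size=n_extra, replace=False):
            lo, hi = _cis_window(row["start"], row["end"], row["strand"])
            if chrom[si] == row["chrom"] and lo <= pos_bp[si] <= hi:
                continue  # would be cis by position; skip to keep labels honest
            beta = float(rng.normal(0, spec.trans_effect_sd))
            effects.append((int(si), beta, "trans"))
        genetic_g = np.zeros(panel.n_strains)
        for si, beta, lab in effects:
            eqtl_rows.append(
                {"gene": row["gene"], "site_idx": si, "effect": beta, "label": lab}
            )
            genetic_g += beta * G[:, si]
        vg_g = np.var(genetic_g)
        if effects and vg_g > 0 and spec.expression_h2 < 1.0:
            sd_g = np.sqrt(vg_g * (1.0 - spec.expression_h2) / spec.expression_h2)
        elif effects and spec.expression_h2 >= 1.0:
            sd_g = 0.0
        else:
            sd_g = 0.3  # pure environmental variation for genes with no eQTL
        expr_mean[:, g] = (
            row["baseline"] + genetic_g + rng.normal(0.0, sd_g, size=panel.n_strains)
        )
    # mean expression feeds a count model downstream; keep it positive
    expr_mean = np.clip(expr_mean, 0.05, None)

    arch = TrueArchitecture(
        fitness_qtl=pd.DataFrame({"site_idx": qtl_sites, "effect": qtl_eff}),
        eqtl=pd.DataFrame(eqtl_rows, columns=["gene", "site_idx", "effect", "label"]),
        hotspots=hotspots,
        genes=gene_df.drop(columns="_site"),
        fitness_h2=spec.fitness_h2,
        expression_h2=spec.expression_h2,
    )
    return arch, fitness, expr_mean


def simulate_cells(
    panel: GenotypePanel,
    expr_mean: np.ndarray,
    obs: ObservationParams,
    seed,
) -> tuple:
    """Generate the single-cell observation layer.

    Returns (CellAlleleCounts, UMI count matrix (cells × genes),
    truth DataFrame with the source strain(s) and doublet flag per barcode).

    Each barcode covers a Bernoulli(breadth) subset of sites; every read
    reports the cell's true allele through an error/swap channel:
    P(read = RM | state) = (1−s)·[state=RM ? 1−ε : ε] + s·f_site, where
    f_site is the pooled RM frequency.  UMI counts are negative-binomial
    around the strain's mean profile scaled by a lognormal per-cell library
    size.  A `doublet_rate` fraction of barcodes mixes two distinct strains.
    """
    obs.validate()
    rng = as_rng(seed)
    n_strains, n_sites = panel.genotypes.shape
    n_genes = expr_mean.shape[1]
    if expr_mean.shape[0] != n_strains:
        raise ValueError("expression means must be strain × gene")

    # how many barcodes per strain
    n_cells_per = rng.poisson(obs.mean_cells_per_strain, size=n_strains)
    strain_of = np.repeat(np.arange(n_strains), n_cells_per)
    n_cells = len(strain_of)
    if n_cells == 0:
        raise ValueError("no cells drawn; increase mean_cells_per_strain")
    rng.shuffle(strain_of)
    is_doublet = rng.random(n_cells) < obs.doublet_rate
    partner = np.full(n_cells, -1)
    for i in np.flatnonzero(is_doublet):
        p = int(rng.integers(0, n_strains))
        while p == strain_of[i]:
            p = int(rng.integers(0, n_strains))
        partner[i] = p

    pool_freq = panel.genotypes.mean(axis=0)

    rows, cols, rm_dat, by_dat = [], [], [], []
    umi = np.empty((n_cells, n_genes), dtype=np.int64)
    lib_sigma = np.sqrt(np.log1p(obs.library_size_cv**2))
    lib_mu = np.log(obs.mean_library_size) - 0.5 * lib_sigma**2
    disp = obs.nb_dispersion  # gamma shape; var = mu + mu²/disp

    for i in range(n_cells):
        s1 = strain_of[i]
        if is_doublet[i]:
            # a droplet with two cells yields twice the material: union of
            # two independent coverage draws, reads from either cell
            b2 = 1.0 - (1.0 - obs.breadth) ** 2
            covered = np.flatnonzero(rng.random(n_sites) < b2)
            pick = rng.random(len(covered)) < 0.5
            alleles = np.where(
                pick,
                panel.genotypes[s1, covered],
                panel.genotypes[partner[i], covered],
            )
        else:
            covered = np.flatnonzero(rng.random(n_sites) < obs.breadth)
            alleles = panel.genotypes[s1, covered]
        if obs.reads_per_covered_site <= 1.0:
            depth = np.ones(len(covered), dtype=np.int64)
        else:
            depth = 1 + rng.poisson(obs.reads_per_covered_site - 1.0, size=len(covered))
        p_rm = (1.0 - obs.swap_rate) * np.where(
            alleles > 0.5, 1.0 - obs.error_rate, obs.error_rate
        ) + obs.swap_rate * pool_freq[covered]
        rm_reads = rng.binomial(depth, p_rm)
        by_reads = depth - rm_reads
        rows.extend([i] * len(covered))
        cols.extend(covered.tolist())
        rm_dat.extend(rm_reads.tolist())
        by_dat.extend(by_reads.tolist())

        # expression
        mu_prof = expr_mean[s1]
        lib = np.exp(rng.normal(lib_mu, lib_sigma))
        if is_doublet[i]:
            mu_prof = 0.5 * (mu_prof + expr_mean[partner[i]])
            lib += np.exp(rng.normal(lib_mu, lib_sigma))
        mu = mu_prof / mu_prof.sum() * lib
        lam = rng.gamma(disp, mu / disp)
        umi[i] = rng.poisson(lam)

    barcodes = np.array([f"BC{i:06d}" for i in range(n_cells)], dtype=object)
    shape = (n_cells, n_sites)
    # explicit zeros are kept: a covered site with all reads on one allele
    # still has depth ≥ 1, so coverage = (rm + by) > 0 stays correct
    counts = CellAlleleCounts(
        sp.csr_matrix((rm_dat, (rows, cols)), shape=shape, dtype=np.int64),
        sp.csr_matrix((by_dat, (rows, cols)), shape=shape, dtype=np.int64),
        barcodes,
        panel.gmap,
    )
    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "strain": panel.strain_ids[strain_of],
            "partner_strain": [
                panel.strain_ids[p] if p >= 0 else "" for p in partner
            ],
            "is_doublet": is_doublet,
        }
    )
    return counts, umi, truth
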