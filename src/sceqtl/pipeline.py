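"""End-to-end pipeline: configuration, stage orchestration, manifests.

Stage order mirrors the analysis: simulate (optional) → genotype → assign
→ partition → herit → map-qtl → map-eqtl → hotspots → cistrans → match.
Every stage reads only the previous stages' serialized outputs, so the
pipeline is re-entrant: deleting one stage's outputs and re-running
regenerates that stage and its descendants, and nothing upstream.

All randomness derives from one global seed through a (seed, stage)
generator hierarchy, so two runs with the same config are bit-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assign as assign_mod
from . import io as io_mod
from ._utils import stage_rng
from .cross import (
    ArchitectureSpec,
    GeneticMap,
    ObservationParams,
    plant_architecture,
    simulate_cells,
    simulate_cross,
)
from .hmm import GenotypeHMM, HMMParams
from .regarch import (
    MatchParams,
    cis_trans_effect_test,
    classify_cis_trans,
    find_hotspots,
    match_qtl_eqtl,
    rank_permutation_test,
)
from .reml import expression_heritability, partition_fitness
from .sparse import SparseFitConfig, map_eqtl, map_qtl

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "STAGES", "DEFAULT_CONFIG"]


class ConfigError(ValueError):
    """Invalid run configuration (unknown key or bad value)."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "run",
    # bundled desk-scale fixture: 100 strains × 500 sites × ~500 cells ×
    # 200 genes.  Sites are scaled down ~80× relative to a full cross, so
    # per-site breadth is scaled up to preserve the number of covered
    # sites per cell (~100), and the map keeps a genome-like total length
    # (1,000 cM) so strains remain distinguishable.
    "sim": {
        "n_chrom": 5,
        "sites_per_chrom": 100,
        "bp_spacing": 2000,
        "cm_per_interval": 2.0,
        "n_segregants": 100,
        "n_genes": 200,
        "n_qtl": 8,
        "qtl_effect_sd": 1.0,
        "fitness_h2": 0.5,
        "cis_fraction": 0.15,
        "trans_per_gene": 2.0,
        "n_hotspots": 3,
        "hotspot_gene_fraction": 0.5,
        "expression_h2": 0.4,
        "breadth": 0.2,
        "error_rate": 0.002,
        "swap_rate": 0.0,
        "mean_cells_per_strain": 4.83,
        "doublet_rate": 0.10,
        "mean_library_size": 5000.0,
    },
    "hmm": {
        "epsilon_init": 0.01,
        "swap_init": 0.01,
        "rec_scale_init": 1.0,
        "tol": 1.0e-6,
        "max_iter": 200,
        "estimate_params": True,
    },
    "assign": {"n_null": 100, "fdr_threshold": 0.05, "doublet_r2": 0.1},
    "qtl": {"n_folds": 10, "max_k": None, "refine": True},
    "eqtl": {"max_k": None},
    "hotspot": {"window_bp": 25000},
    "match": {
        "delta_cm": 10.0,
        "tau": None,
        "phi": 0.1,
        "gamma": 0.5,
        "n_perm": 999,
    },
}

STAGES = [
    "simulate",
    "genotype",
    "assign",
    "partition",
    "herit",
    "map-qtl",
    "map-eqtl",
    "hotspots",
    "cistrans",
    "match",
]


class RunConfig:
    """Validated pipeline configuration; every parameter has a default.

    Unknown keys are errors, not warnings; the config round-trips through
    YAML losslessly.
    """

    def __init__(self, overrides: dict | None = None):
        self.data = copy.deepcopy(DEFAULT_CONFIG)
        if overrides:
            _merge(self.data, overrides, path="")

    def __getitem__(self, key):
        return self.data[key]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        overrides = yaml.safe_load(text) or {}
        if not isinstance(overrides, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls(overrides)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.data, sort_keys=True))


def _merge(base: dict, overrides: dict, path: str) -> None:
    for key, val in overrides.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{here} must be a mapping")
            _merge(base[key], val, here)
        else:
            base[key] = val


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stage implementations (each reads/writes only serialized artifacts)
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    s = cfg["sim"]
    gmap = GeneticMap.regular(
        s["n_chrom"], s["sites_per_chrom"], s["bp_spacing"], s["cm_per_interval"]
    )
    panel = simulate_cross(gmap, s["n_segregants"], stage_rng(cfg["seed"], "simulate", "cross"))
    arch_spec = ArchitectureSpec(
        n_genes=s["n_genes"],
        n_qtl=s["n_qtl"],
        qtl_effect_sd=s["qtl_effect_sd"],
        fitness_h2=s["fitness_h2"],
        cis_fraction=s["cis_fraction"],
        trans_per_gene=s["trans_per_gene"],
        n_hotspots=s["n_hotspots"],
        hotspot_gene_fraction=s["hotspot_gene_fraction"],
        expression_h2=s["expression_h2"],
    )
    arch, fitness, expr_mean = plant_architecture(
        panel, arch_spec, stage_rng(cfg["seed"], "simulate", "architecture")
    )
    obs = ObservationParams(
        breadth=s["breadth"],
        error_rate=s["error_rate"],
        swap_rate=s["swap_rate"],
        mean_cells_per_strain=s["mean_cells_per_strain"],
        doublet_rate=s["doublet_rate"],
        mean_library_size=s["mean_library_size"],
    )
    counts, umi, truth = simulate_cells(
        panel, expr_mean, obs, stage_rng(cfg["seed"], "simulate", "cells")
    )
    io_mod.write_genetic_map(gmap, out / "map.tsv")
    io_mod.write_panel(panel, out / "panel.tsv")
    io_mod.write_allele_counts(counts, out / "counts.tsv", out / "barcodes.tsv")
    io_mod.write_expression_mtx(
        umi, counts.barcodes, arch.genes["gene"], out / "expression"
    )
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    io_mod.write_fitness(
        pd.Series(fitness, index=panel.strain_ids), out / "fitness.tsv"
    )
    io_mod.write_gene_annotation(arch.genes, out / "genes.tsv")
    io_mod.write_architecture(arch, out / "architecture.json")


def _stage_genotype(cfg: RunConfig, out: Path) -> None:
    sim = out.parent / "simulate"
    gmap = io_mod.read_genetic_map(sim / "map.tsv")
    barcodes = io_mod.read_barcodes(sim / "barcodes.tsv")
    counts = io_mod.read_allele_counts(sim / "counts.tsv", gmap, barcodes)
    panel = io_mod.read_panel(sim / "panel.tsv", gmap)
    h = cfg["hmm"]
    model = GenotypeHMM(counts)
    start = HMMParams(h["epsilon_init"], h["swap_init"], h["rec_scale_init"])
    if h["estimate_params"]:
        res = model.fit(start, panel=panel, max_iter=h["max_iter"], tol=h["tol"])
        params = res.params
        fit_info = {
            "loglik": float(res.loglik_path[-1]),
            "n_iter": res.n_iter,
            "converged": bool(res.converged),
        }
    else:
        from .hmm import pooled_frequencies

        params = start
        params.pool_freq = pooled_frequencies(counts)
        fit_info = {}
    post, loglik = model.posteriors(params)
    (out / "hmm_params.json").write_text(
        json.dumps(
            {
                "epsilon": params.epsilon,
                "swap": params.swap,
                "rec_scale": params.rec_scale,
                "pi_rm": params.pi_rm,
                "pool_freq": [float(f) for f in params.freqs(gmap.n_sites)],
                **fit_info,
            },
            indent=1,
        )
    )
    io_mod.write_matrix_tsv(
        post, counts.barcodes, gmap.site_id, out / "posteriors.tsv", "barcode"
    )


def _stage_assign(cfg: RunConfig, out: Path) -> None:
    base = out.parent
    sim = base / "simulate"
    gmap = io_mod.read_genetic_map(sim / "map.tsv")
    panel = io_mod.read_panel(sim / "panel.tsv", gmap)
    post_df = io_mod.read_matrix_tsv(base / "genotype" / "posteriors.tsv")
    barcodes = io_mod.read_barcodes(sim / "barcodes.tsv")
    counts = io_mod.read_allele_counts(sim / "counts.tsv", gmap, barcodes)
    umi, bc2, genes = io_mod.read_expression_mtx(sim / "expression")
    a = cfg["assign"]
    result = assign_mod.assign_cells(
        post_df.to_numpy(float),
        panel,
        n_null=a["n_null"],
        fdr_threshold=a["fdr_threshold"],
        seed=stage_rng(cfg["seed"], "assign", "null"),
    )
    result = assign_mod.flag_doublets(counts, result, panel, a["doublet_r2"])
    result.insert(0, "barcode", post_df.index.to_numpy(object))
    result.to_csv(out / "assignments.tsv", sep="\t", index=False)
    strains, cons_g, cons_e = assign_mod.consensus_profiles(
        result, post_df.to_numpy(float), umi
    )
    io_mod.write_matrix_tsv(cons_g, strains, gmap.site_id, out / "consensus_genotype.tsv", "strain")
    io_mod.write_matrix_tsv(cons_e, strains, genes, out / "consensus_expression.tsv", "strain")


def _consensus(base: Path):
    cons_g = io_mod.read_matrix_tsv(base / "assign" / "consensus_genotype.tsv")
    cons_e = io_mod.read_matrix_tsv(base / "assign" / "consensus_expression.tsv")
    fitness = io_mod.read_fitness(base / "simulate" / "fitness.tsv")
    y = fitness.loc[cons_g.index].to_numpy(float)
    return cons_g, cons_e, y


def _stage_partition(cfg: RunConfig, out: Path) -> None:
    cons_g, cons_e, y = _consensus(out.parent)
    W_e = assign_mod.normalize_expression(cons_e.to_numpy(float))
    part = partition_fitness(y, cons_g.to_numpy(float), W_e)
    (out / "partition.json").write_text(json.dumps(part.as_dict() | {"n": part.n}, indent=1))


def _stage_herit(cfg: RunConfig, out: Path) -> None:
    cons_g, cons_e, _ = _consensus(out.parent)
    E = assign_mod.normalize_expression(cons_e.to_numpy(float))
    overall, pca, per_gene = expression_heritability(
        E, cons_g.to_numpy(float), per_gene=False
    )
    (out / "herit.json").write_text(
        json.dumps(
            {
                "overall": overall,
                "k": pca.k,
                "pc1_variance_fraction": float(pca.cumulative_fraction[0]),
            },
            indent=1,
        )
    )


def _qtl_config(cfg: RunConfig) -> SparseFitConfig:
    q = cfg["qtl"]
    return SparseFitConfig(
        n_folds=q["n_folds"],
        max_k=q["max_k"],
        refine=q["refine"],
        seed=int(stage_rng(cfg["seed"], "qtl", "cv").integers(2**31)),
    )


def _stage_map_qtl(cfg: RunConfig, out: Path) -> None:
    cons_g, _, y = _consensus(out.parent)
    model = map_qtl(cons_g.to_numpy(float), y, _qtl_config(cfg))
    io_mod.write_qtl_model(model, out / "qtl_model.json")


def _stage_map_eqtl(cfg: RunConfig, out: Path) -> None:
    cons_g, cons_e, _ = _consensus(out.parent)
    E = assign_mod.normalize_expression(cons_e.to_numpy(float))
    config = SparseFitConfig(max_k=cfg["eqtl"]["max_k"])
    models = map_eqtl(cons_g.to_numpy(float), E, list(cons_e.columns), config)
    gene_dir = out / "genes"
    gene_dir.mkdir(exist_ok=True)
    summary = []
    for name, m in models.items():
        io_mod.write_qtl_model(m, gene_dir / f"{name}.json")
        summary.append(
            {
                "gene": name,
                "n_eqtl": m.size,
                "r2": m.r2,
                "sites": ",".join(str(s) for s in m.sites),
                "betas": ",".join(f"{b:.6g}" for b in m.beta),
            }
        )
    pd.DataFrame(summary, columns=["gene", "n_eqtl", "r2", "sites", "betas"]).to_csv(
        out / "eqtl_summary.tsv", sep="\t", index=False
    )


def _load_eqtl_models(base: Path) -> dict:
    gene_dir = base / "map-eqtl" / "genes"
    return {
        p.stem: io_mod.read_qtl_model(p) for p in sorted(gene_dir.glob("*.json"))
    }


def _stage_hotspots(cfg: RunConfig, out: Path) -> None:
    base = out.parent
    gmap = io_mod.read_genetic_map(base / "simulate" / "map.tsv")
    models = _load_eqtl_models(base)
    table = find_hotspots(models, gmap, cfg["hotspot"]["window_bp"])
    table.to_csv(out / "hotspots.tsv", sep="\t", index=False)


def _stage_cistrans(cfg: RunConfig, out: Path) -> None:
    base = out.parent
    gmap = io_mod.read_genetic_map(base / "simulate" / "map.tsv")
    genes = io_mod.read_gene_annotation(base / "simulate" / "genes.tsv")
    models = _load_eqtl_models(base)
    labels = classify_cis_trans(models, genes, gmap)
    labels.to_csv(out / "cistrans.tsv", sep="\t", index=False)
    stat, p, per_gene = cis_trans_effect_test(labels)
    (out / "cis_trans_test.json").write_text(
        json.dumps({"statistic": stat, "p_value": p, "n_genes": len(per_gene)}, indent=1)
    )


def _stage_match(cfg: RunConfig, out: Path) -> None:
    base = out.parent
    gmap = io_mod.read_genetic_map(base / "simulate" / "map.tsv")
    panel_df = io_mod.read_matrix_tsv(base / "assign" / "consensus_genotype.tsv")
    from .cross import GenotypePanel

    panel = GenotypePanel(
        np.clip(panel_df.to_numpy(float), 0, 1), panel_df.index.to_numpy(object), gmap
    )
    cons_e = io_mod.read_matrix_tsv(base / "assign" / "consensus_expression.tsv")
    E = assign_mod.normalize_expression(cons_e.to_numpy(float))
    qtl_model = io_mod.read_qtl_model(base / "map-qtl" / "qtl_model.json")
    models = _load_eqtl_models(base)
    m = cfg["match"]
    params = MatchParams(m["delta_cm"], m["tau"], m["phi"], m["gamma"])
    # QTL ranks: larger |effect| = larger rank
    ranks = {
        int(s): r + 1
        for r, s in enumerate(
            qtl_model.sites[np.argsort(np.abs(qtl_model.beta))]
        )
    }
    rows = []
    rng_seed = int(stage_rng(cfg["seed"], "match", "perm").integers(2**31))
    gene_names = list(cons_e.columns)
    for gi, name in enumerate(gene_names):
        model = models.get(name)
        if model is None or qtl_model.size == 0:
            continue
        res = match_qtl_eqtl(qtl_model, E[:, gi], panel, model, params)
        matched = sorted(set(int(s) for s in res.pairs["qtl_site"])) if len(res.pairs) else []
        unmatched = [int(s) for s in res.unmatched_qtl]
        if matched and unmatched and len(matched) <= len(unmatched):
            p = rank_permutation_test(
                [ranks[s] for s in matched],
                [ranks[s] for s in unmatched],
                n_perm=m["n_perm"],
                seed=rng_seed + gi,
            )
        else:
            p = float("nan")
        rows.append(
            {
                "gene": name,
                "n_matched": len(matched),
                "n_unmatched": len(unmatched),
                "total_score": res.total_score,
                "p_value": p,
            }
        )
    pd.DataFrame(
        rows, columns=["gene", "n_matched", "n_unmatched", "total_score", "p_value"]
    ).to_csv(out / "match.tsv", sep="\t", index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "genotype": _stage_genotype,
    "assign": _stage_assign,
    "partition": _stage_partition,
    "herit": _stage_herit,
    "map-qtl": _stage_map_qtl,
    "map-eqtl": _stage_map_eqtl,
    "hotspots": _stage_hotspots,
    "cistrans": _stage_cistrans,
    "match": _stage_match,
}

_STAGE_OUTPUTS = {
    "simulate": [
        "map.tsv",
        "panel.tsv",
        "counts.tsv",
        "barcodes.tsv",
        "expression.mtx",
        "truth.tsv",
        "fitness.tsv",
        "genes.tsv",
        "architecture.json",
    ],
    "genotype": ["hmm_params.json", "posteriors.tsv"],
    "assign": ["assignments.tsv", "consensus_genotype.tsv", "consensus_expression.tsv"],
    "partition": ["partition.json"],
    "herit": ["herit.json"],
    "map-qtl": ["qtl_model.json"],
    "map-eqtl": ["eqtl_summary.tsv"],
    "hotspots": ["hotspots.tsv"],
    "cistrans": ["cistrans.tsv", "cis_trans_test.json"],
    "match": ["match.tsv"],
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.code = 3


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Run (or resume) the pipeline; returns the run manifest.

    A stage executes when forced, when any of its outputs is missing, or
    when an upstream stage executed in this run; otherwise its serialized
    outputs are reused, which makes partial re-runs bit-reproducible.
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config["seed"], "config": config.data, "stages": {}}
    upstream_ran = False
    for stage in STAGES:
        stage_dir = outdir / stage
        stage_dir.mkdir(exist_ok=True)
        outputs = [stage_dir / f for f in _STAGE_OUTPUTS[stage]]
        need = force or upstream_ran or any(not p.exists() for p in outputs)
        if need:
            logger.info("running stage %s", stage)
            try:
                _STAGE_FUNCS[stage](config, stage_dir)
            except Exception as exc:
                raise StageError(stage, exc) from exc
            upstream_ran = True
        else:
            logger.info("stage %s is up to date", stage)
        manifest["stages"][stage] = {
            "ran": bool(need),
            "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
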