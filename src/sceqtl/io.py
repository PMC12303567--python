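"""Readers and writers for the pipeline's on-disk formats.

All tables are plain TSV; expression matrices use Matrix Market triplets
with side-car barcode/gene lists (CellRanger-style); models and manifests
are JSON.  Physical coordinates are 1-based inclusive (stated in file
headers); inputs recorded in 0-based coordinates can be shifted on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse as sp

from .cross import CellAlleleCounts, GeneticMap, GenotypePanel, TrueArchitecture
from .sparse import QTLModel

__all__ = [
    "ParseError",
    "read_genetic_map",
    "write_genetic_map",
    "read_panel",
    "write_panel",
    "read_allele_counts",
    "write_allele_counts",
    "read_expression_mtx",
    "write_expression_mtx",
    "read_fitness",
    "write_fitness",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_qtl_model",
    "write_qtl_model",
    "read_architecture",
    "write_architecture",
]

_COORD_HEADER = "# coordinates: 1-based inclusive\n"


class ParseError(ValueError):
    """Malformed input file; message carries file and line number."""


def _read_table(path, required: list, dtypes: dict | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=dtypes)
    except pd.errors.ParserError as exc:  # pandas names the offending line
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}:1: missing required columns {missing}")
    return df


# -- genetic map ------------------------------------------------------------


def read_genetic_map(path, zero_based: bool = False) -> GeneticMap:
    df = _read_table(path, ["site", "chrom", "pos_bp", "pos_cm"])
    for i, v in enumerate(df["pos_bp"]):
        if pd.isna(v):
            raise ParseError(f"{path}:{i + 2}: missing physical position")
    if zero_based:
        df = df.assign(pos_bp=df["pos_bp"] + 1)
    try:
        return GeneticMap.from_frame(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_genetic_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        gmap.to_frame().to_csv(fh, sep="\t", index=False)


# -- genotype panel ---------------------------------------------------------


def read_panel(path, gmap: GeneticMap) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if list(df.columns) != list(gmap.site_id):
        raise ParseError(f"{path}: panel sites do not match the genetic map")
    return GenotypePanel(df.to_numpy(float), df.index.to_numpy(object), gmap)


def write_panel(panel: GenotypePanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("# strain x site RM-allele frequencies\n")
        panel.to_frame().to_csv(fh, sep="\t", index_label="strain")


def write_matrix_tsv(matrix: np.ndarray, index, columns, path, index_label="id") -> None:
    pd.DataFrame(matrix, index=index, columns=columns).to_csv(
        path, sep="\t", index_label=index_label
    )


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


# -- allele counts ----------------------------------------------------------


def write_allele_counts(counts: CellAlleleCounts, path, barcodes_path=None) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        counts.to_triplets().to_csv(fh, sep="\t", index=False)
    if barcodes_path is not None:
        pd.Series(counts.barcodes).to_csv(
            barcodes_path, sep="\t", index=False, header=False
        )


def read_allele_counts(path, gmap: GeneticMap, barcodes=None) -> CellAlleleCounts:
    df = _read_table(path, ["barcode", "site", "rm_count", "by_count"])
    site_index = {s: i for i, s in enumerate(gmap.site_id)}
    if barcodes is None:
        barcodes = pd.unique(df["barcode"])
    barcodes = np.asarray(barcodes, dtype=object)
    bc_index = {b: i for i, b in enumerate(barcodes)}
    rows, cols, rm, by = [], [], [], []
    for lineno, rec in enumerate(df.itertuples(index=False), start=2):
        if rec.site not in site_index:
            raise ParseError(f"{path}:{lineno}: unknown site {rec.site!r}")
        if rec.barcode not in bc_index:
            raise ParseError(f"{path}:{lineno}: unknown barcode {rec.barcode!r}")
        rows.append(bc_index[rec.barcode])
        cols.append(site_index[rec.site])
        rm.append(int(rec.rm_count))
        by.append(int(rec.by_count))
    shape = (len(barcodes), gmap.n_sites)
    return CellAlleleCounts(
        sp.csr_matrix((rm, (rows, cols)), shape=shape, dtype=np.int64),
        sp.csr_matrix((by, (rows, cols)), shape=shape, dtype=np.int64),
        barcodes,
        gmap,
    )


def read_barcodes(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", header=None)[0].to_numpy(object)


# -- expression (Matrix Market) ---------------------------------------------


def write_expression_mtx(umi: np.ndarray, barcodes, genes, prefix) -> None:
    """Write counts as <prefix>.mtx with <prefix>.barcodes.tsv / .genes.tsv."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix) + ".mtx", sp.coo_matrix(np.asarray(umi)))
    pd.Series(list(barcodes)).to_csv(
        str(prefix) + ".barcodes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(list(genes)).to_csv(
        str(prefix) + ".genes.tsv", sep="\t", index=False, header=False
    )


def read_expression_mtx(prefix) -> tuple:
    """Read <prefix>.mtx (+ barcode/gene lists); returns (matrix, barcodes, genes).

    Dimension mismatches between the matrix header and the side-car lists
    are rejected.
    """
    prefix = Path(prefix)
    mtx_path = str(prefix) + ".mtx"
    try:
        mat = spio.mmread(mtx_path)
    except ValueError as exc:
        raise ParseError(f"{mtx_path}:1: {exc}") from exc
    barcodes = read_barcodes(str(prefix) + ".barcodes.tsv")
    genes = read_barcodes(str(prefix) + ".genes.tsv")
    mat = np.asarray(sp.coo_matrix(mat).todense())
    if mat.shape[0] != len(barcodes):
        raise ParseError(
            f"{mtx_path}:2: matrix has {mat.shape[0]} rows but "
            f"{len(barcodes)} barcodes are listed"
        )
    if mat.shape[1] != len(genes):
        raise ParseError(
            f"{mtx_path}:2: matrix has {mat.shape[1]} columns but "
            f"{len(genes)} genes are listed"
        )
    return mat, barcodes, genes


# -- simple tables ----------------------------------------------------------


def read_fitness(path) -> pd.Series:
    df = _read_table(path, ["strain", "fitness"])
    return df.set_index("strain")["fitness"].astype(float)


def write_fitness(fitness: pd.Series, path) -> None:
    fitness.rename("fitness").to_csv(path, sep="\t", index_label="strain")


def read_gene_annotation(path, zero_based: bool = False) -> pd.DataFrame:
    df = _read_table(path, ["gene", "chrom", "start", "end"])
    if "strand" not in df.columns:
        df["strand"] = "+"
    if zero_based:
        df = df.assign(start=df["start"] + 1, end=df["end"] + 1)
    return df


def write_gene_annotation(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        genes.to_csv(fh, sep="\t", index=False)


# -- models and architecture ------------------------------------------------


def write_qtl_model(model: QTLModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def read_qtl_model(path) -> QTLModel:
    return QTLModel.from_dict(json.loads(Path(path).read_text()))


def write_architecture(arch: TrueArchitecture, path) -> None:
    Path(path).write_text(arch.to_json())


def read_architecture(path) -> TrueArchitecture:
    return TrueArchitecture.from_json(Path(path).read_text())
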