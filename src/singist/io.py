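"""Readers and writers for the package's on-disk interchange formats.

Counts come in as MatrixMarket (genes x cells) with companion TSV metadata,
or as a dense genes-x-cells TSV.  Gene sets are GMT (the MSigDB interchange
format); ortholog and cell-type maps are small TSVs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from singist.datamodel import (
    ABSENT,
    CellTypeMap,
    DataError,
    OrthologyMap,
    PseudobulkBlocks,
    SingleCellData,
)

logger = logging.getLogger(__name__)


def read_counts(
    counts_path: str | Path,
    cells_meta_path: str | Path,
    genes_meta_path: str | Path | None = None,
    samples_meta_path: str | Path | None = None,
) -> SingleCellData:
    """Read a genes-x-cells counts matrix with aligned annotations.

    ``counts_path`` may be MatrixMarket (``.mtx``) — then ``genes_meta_path``
    is required — or a dense TSV whose row index holds gene symbols and whose
    columns are cell ids.  ``cells_meta_path`` is a TSV with columns
    ``cell_id``, ``sample_id``, ``cell_type`` and, if no separate sample
    table is given, ``class_label``.
    """
    counts_path = Path(counts_path)
    cells = pd.read_csv(cells_meta_path, sep="\t", dtype=str)
    required = {"cell_id", "sample_id", "cell_type"}
    if not required <= set(cells.columns):
        raise DataError(f"{cells_meta_path}: needs columns {sorted(required)}")

    if counts_path.suffix == ".mtx":
        if genes_meta_path is None:
            raise DataError("MatrixMarket counts require a gene metadata file")
        counts = sp.csr_matrix(scipy.io.mmread(counts_path))
        genes = pd.Index(
            pd.read_csv(genes_meta_path, sep="\t", header=None).iloc[:, 0].astype(str)
        )
        if counts.nnz == 0:
            logger.warning("%s: matrix has zero non-zero entries", counts_path)
    else:
        dense = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts = sp.csr_matrix(dense.to_numpy())
        genes = pd.Index(dense.index.astype(str))
        if list(dense.columns) != list(cells["cell_id"]):
            # allow metadata in a different order as long as ids agree
            if set(dense.columns) != set(cells["cell_id"]):
                raise DataError(
                    f"{counts_path}: cell ids disagree with {cells_meta_path}"
                )
            cells = cells.set_index("cell_id").loc[list(dense.columns)].reset_index()

    if counts.shape[1] != len(cells):
        raise DataError(
            f"{counts_path}: {counts.shape[1]} cells in matrix but "
            f"{len(cells)} rows in {cells_meta_path}"
        )
    if counts.shape[0] != len(genes):
        raise DataError(
            f"{counts_path}: {counts.shape[0]} genes in matrix but {len(genes)} gene records"
        )

    if samples_meta_path is not None:
        sm = pd.read_csv(samples_meta_path, sep="\t", dtype=str)
        samples = sm.set_index("sample_id")["class_label"]
    else:
        if "class_label" not in cells.columns:
            raise DataError(f"{cells_meta_path}: no class_label column and no sample table")
        per_sample = cells.groupby("sample_id")["class_label"].nunique()
        if (per_sample > 1).any():
            bad = per_sample[per_sample > 1].index.tolist()
            raise DataError(f"samples with conflicting class labels: {bad}")
        samples = cells.groupby("sample_id")["class_label"].first()
    try:
        samples = samples.astype(int)
    except ValueError as exc:
        raise DataError(f"unknown class label: {exc}") from exc
    if not set(samples) <= {0, 1}:
        raise DataError(f"class labels must be 0/1, got {sorted(set(samples))}")

    data = SingleCellData(
        counts=counts,
        genes=genes,
        cells=cells.set_index("cell_id")[["sample_id", "cell_type"]],
        samples=samples,
    )
    return data.collapse_duplicate_genes()


def read_gmt(path: str | Path) -> list[tuple[str, list[str]]]:
    """Parse a GMT gene-set file into (pathway_id, genes) pairs, in file order.

    Gene symbols are uppercased; duplicates within a line deduplicated
    preserving first occurrence; lines with fewer than three fields skipped
    with a warning.
    """
    out: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: fewer than 3 fields, skipped", path, lineno)
                continue
            name = fields[0]
            genes = list(dict.fromkeys(g.strip().upper() for g in fields[2:] if g.strip()))
            out.append((name, genes))
    return out


def read_orthology(path: str | Path) -> OrthologyMap:
    """Read a 3-column TSV: human_symbol, model_symbol, one_to_one (0/1)."""
    df = pd.read_csv(
        path, sep="\t", header=0,
        names=["human_symbol", "model_symbol", "one_to_one"],
        dtype={"human_symbol": str, "model_symbol": str},
    )
    df["human_symbol"] = df["human_symbol"].str.upper()
    df["one_to_one"] = df["one_to_one"].astype(int).astype(bool)
    return OrthologyMap(df)


def read_celltype_map(path: str | Path) -> CellTypeMap:
    """Read a 2-column TSV: human_cell_type, model_cell_type (ABSENT = unmapped)."""
    df = pd.read_csv(path, sep="\t", header=0, names=["human_cell_type", "model_cell_type"],
                     dtype=str)
    if df["human_cell_type"].duplicated().any():
        dup = df.loc[df["human_cell_type"].duplicated(), "human_cell_type"].tolist()
        raise DataError(f"duplicated human cell types in map: {dup}")
    mapping = {
        row.human_cell_type: (None if row.model_cell_type == ABSENT else row.model_cell_type)
        for row in df.itertuples()
    }
    return CellTypeMap(mapping)


def read_fc_table(path: str | Path) -> pd.DataFrame:
    """Read a precomputed fold-change table: cell_type, model_gene, log2FC, adj_p."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_type": str, "model_gene": str})
    missing = {"cell_type", "model_gene", "log2FC", "adj_p"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: fold-change table lacks columns {sorted(missing)}")
    return df


def write_pseudobulk(blocks: PseudobulkBlocks, path: str | Path) -> None:
    """Serialize pseudobulk blocks to a single JSON file (full float precision)."""
    payload = {
        ct: {
            "samples": list(map(str, df.index)),
            "genes": list(map(str, df.columns)),
            "values": df.to_numpy().tolist(),
        }
        for ct, df in blocks.blocks.items()
    }
    Path(path).write_text(json.dumps(payload))


def read_pseudobulk(path: str | Path) -> PseudobulkBlocks:
    payload = json.loads(Path(path).read_text())
    return PseudobulkBlocks(
        {
            ct: pd.DataFrame(
                np.asarray(rec["values"], dtype=float),
                index=pd.Index(rec["samples"]),
                columns=pd.Index(rec["genes"]),
            )
            for ct, rec in payload.items()
        }
    )


def write_counts(
    data: SingleCellData, outdir: str | Path, prefix: str = "counts"
) -> dict[str, Path]:
    """Write counts as MatrixMarket plus TSV metadata; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{prefix}.mtx",
        "genes": outdir / f"{prefix}.genes.tsv",
        "cells": outdir / f"{prefix}.cells.tsv",
        "samples": outdir / f"{prefix}.samples.tsv",
    }
    scipy.io.mmwrite(paths["counts"], data.counts)
    pd.Series(data.genes).to_csv(paths["genes"], sep="\t", header=False, index=False)
    cells = data.cells.reset_index()
    cells.columns = ["cell_id", "sample_id", "cell_type"]
    cells.to_csv(paths["cells"], sep="\t", index=False)
    data.samples.rename("class_label").rename_axis("sample_id").reset_index().to_csv(
        paths["samples"], sep="\t", index=False
    )
    return paths
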