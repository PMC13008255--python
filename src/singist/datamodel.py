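"""Core data containers: annotated counts, superpathways, pseudobulk blocks.

The analysis unit is a *superpathway*: one pathway gene set partitioned into
per-cell-type gene subsets.  Human expression enters the model as pseudobulk
blocks, one samples-by-genes matrix per cell type, all sharing the same
sample order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: keyword used in cell-type map files for a human cell type with no
#: counterpart in the disease model
ABSENT = "ABSENT"


class DataError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class SingleCellData:
    """Genes-by-cells counts with per-cell and per-sample annotations.

    Parameters
    ----------
    counts
        Sparse or dense counts, shape ``(n_genes, n_cells)``.
    genes
        Gene symbols, one per matrix row.
    cells
        Per-cell annotation indexed by cell id with columns ``sample_id``
        and ``cell_type``.
    samples
        Per-sample binary class label (1 = target class, 0 = base class),
        indexed by sample id.
    """

    counts: sp.csr_matrix
    genes: pd.Index
    cells: pd.DataFrame
    samples: pd.Series

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.genes = pd.Index(self.genes)
        if self.counts.shape[0] != len(self.genes):
            raise DataError(
                f"counts has {self.counts.shape[0]} rows but {len(self.genes)} gene symbols"
            )
        if self.counts.shape[1] != len(self.cells):
            raise DataError(
                f"counts has {self.counts.shape[1]} columns but {len(self.cells)} cell records"
            )
        missing = {"sample_id", "cell_type"} - set(self.cells.columns)
        if missing:
            raise DataError(f"cell annotation lacks columns: {sorted(missing)}")
        unknown = set(self.cells["sample_id"]) - set(self.samples.index)
        if unknown:
            raise DataError(f"cells reference samples without class label: {sorted(unknown)}")
        labels = set(pd.unique(self.samples))
        if not labels <= {0, 1}:
            raise DataError(f"class labels must be 0/1, got {sorted(labels)}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def collapse_duplicate_genes(self) -> "SingleCellData":
        """Sum counts of duplicated gene symbols; no-op if all unique."""
        if self.genes.is_unique:
            return self
        dup = self.genes[self.genes.duplicated()].unique().tolist()
        logger.warning("collapsing %d duplicated gene symbols by sum: %s", len(dup), dup[:10])
        order = pd.Index(pd.unique(self.genes))
        codes = order.get_indexer(self.genes)
        ind = sp.csr_matrix(
            (np.ones(len(codes)), (codes, np.arange(len(codes)))),
            shape=(len(order), len(codes)),
        )
        return SingleCellData(ind @ self.counts, order, self.cells, self.samples)


@dataclass(frozen=True)
class Superpathway:
    """A pathway gene set with per-cell-type gene subsets.

    ``per_celltype[b]`` holds the subset of the pathway's genes expected to
    act in cell type ``b``; the superpathway is the union of these subsets.
    Empty subsets are dropped at construction.
    """

    pathway_id: str
    per_celltype: dict[str, tuple[str, ...]]
    full_gene_set: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        cleaned = {
            ct: tuple(dict.fromkeys(genes))
            for ct, genes in self.per_celltype.items()
            if len(genes) > 0
        }
        object.__setattr__(self, "per_celltype", cleaned)
        union = frozenset(g for genes in cleaned.values() for g in genes)
        if not self.full_gene_set:
            object.__setattr__(self, "full_gene_set", union)
        else:
            extra = union - self.full_gene_set
            if extra:
                raise DataError(
                    f"pathway {self.pathway_id}: cell-type subsets contain genes "
                    f"outside the pathway gene set: {sorted(extra)[:10]}"
                )
        if not cleaned:
            raise DataError(f"pathway {self.pathway_id}: no non-empty cell-type gene subsets")

    @property
    def cell_types(self) -> list[str]:
        return list(self.per_celltype)

    @classmethod
    def uniform(cls, pathway_id: str, genes, cell_types) -> "Superpathway":
        """Same gene set in every cell type (the default when no per-cell-type
        annotation is available)."""
        genes = tuple(genes)
        return cls(pathway_id, {ct: genes for ct in cell_types})


@dataclass
class PseudobulkBlocks:
    """Per-cell-type sample-by-gene pseudobulk matrices with shared sample order."""

    blocks: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise DataError("no pseudobulk blocks")
        ref = None
        for ct, df in self.blocks.items():
            if df.isna().any().any():
                raise DataError(f"block {ct!r} contains missing values")
            if ref is None:
                ref = df.index
            elif not df.index.equals(ref):
                raise DataError(f"block {ct!r} sample order differs from other blocks")

    @property
    def sample_ids(self) -> pd.Index:
        return next(iter(self.blocks.values())).index

    @property
    def cell_types(self) -> list[str]:
        return list(self.blocks)

    def subset_samples(self, sample_ids) -> "PseudobulkBlocks":
        return PseudobulkBlocks({ct: df.loc[sample_ids] for ct, df in self.blocks.items()})

    def copy(self) -> "PseudobulkBlocks":
        return PseudobulkBlocks({ct: df.copy() for ct, df in self.blocks.items()})


@dataclass
class OrthologyMap:
    """Human-to-model gene correspondence with a one-to-one flag per record."""

    records: pd.DataFrame  # columns: human_symbol, model_symbol, one_to_one

    def __post_init__(self) -> None:
        missing = {"human_symbol", "model_symbol", "one_to_one"} - set(self.records.columns)
        if missing:
            raise DataError(f"orthology map lacks columns: {sorted(missing)}")
        self.records = self.records.copy()
        self.records["one_to_one"] = self.records["one_to_one"].astype(bool)
        oto = self.records[self.records["one_to_one"]]
        if oto["human_symbol"].duplicated().any() or oto["model_symbol"].duplicated().any():
            dup = pd.concat(
                [
                    oto.loc[oto["human_symbol"].duplicated(keep=False), "human_symbol"],
                    oto.loc[oto["model_symbol"].duplicated(keep=False), "model_symbol"],
                ]
            )
            raise DataError(
                f"symbols flagged one-to-one appear in multiple records: {sorted(set(dup))[:10]}"
            )

    def one_to_one(self) -> dict[str, str]:
        """Mapping human symbol -> model symbol over one-to-one records only."""
        oto = self.records[self.records["one_to_one"]]
        return dict(zip(oto["human_symbol"], oto["model_symbol"]))


@dataclass
class CellTypeMap:
    """Human cell type -> disease-model cell type; ``None`` marks an absent type."""

    mapping: dict[str, str | None]

    def model_type(self, human_cell_type: str) -> str | None:
        if human_cell_type not in self.mapping:
            raise DataError(f"cell type {human_cell_type!r} missing from cell-type map")
        return self.mapping[human_cell_type]

    def is_mapped(self, human_cell_type: str) -> bool:
        return self.model_type(human_cell_type) is not None


def build_pseudobulk(
    data: SingleCellData,
    superpathway: Superpathway | None = None,
    norm_target: float = 1e4,
    min_cells: int = 10,
) -> PseudobulkBlocks:
    """Aggregate counts to log-normalized pseudobulk profiles per (sample, cell type).

    For each cell type ``b`` and sample ``i``: sum raw counts over that
    sample's cells of type ``b``, library-size normalize the summed profile to
    ``norm_target`` total counts, and transform to ``log2(1 + value)``.
    Normalization uses the full measured gene space, even when a superpathway
    restriction is requested afterwards.

    Cell types with fewer than ``min_cells`` cells in any sample are dropped
    for the whole dataset, as are cell types absent from some sample.
    """
    data = data.collapse_duplicate_genes()
    sample_ids = pd.Index(data.samples.index)
    cell_types = list(pd.unique(data.cells["cell_type"]))

    blocks: dict[str, pd.DataFrame] = {}
    for ct in cell_types:
        in_ct = (data.cells["cell_type"] == ct).to_numpy()
        counts_per_sample = data.cells.loc[in_ct, "sample_id"].value_counts()
        n_cells = counts_per_sample.reindex(sample_ids).fillna(0)
        if (n_cells < min_cells).any():
            bad = n_cells[n_cells < min_cells]
            logger.warning(
                "dropping cell type %r: <%d cells in sample(s) %s",
                ct, min_cells, list(bad.index[:5]),
            )
            continue
        rows = np.zeros((len(sample_ids), data.n_genes))
        for k, sid in enumerate(sample_ids):
            mask = in_ct & (data.cells["sample_id"] == sid).to_numpy()
            profile = np.asarray(data.counts[:, mask].sum(axis=1)).ravel()
            total = profile.sum()
            if total > 0:
                profile = profile * (norm_target / total)
            rows[k] = np.log2(1.0 + profile)
        blocks[ct] = pd.DataFrame(rows, index=sample_ids, columns=data.genes)

    if not blocks:
        raise DataError("all cell types dropped; no pseudobulk blocks can be built")
    pb = PseudobulkBlocks(blocks)
    if superpathway is not None:
        pb = assemble_superpathway_blocks(pb, superpathway)
    return pb


def assemble_superpathway_blocks(
    pseudobulk: PseudobulkBlocks, superpathway: Superpathway
) -> PseudobulkBlocks:
    """Restrict pseudobulk blocks to the superpathway's per-cell-type gene subsets.

    Genes of a subset that were not measured are dropped (never zero-filled);
    a block whose genes are all unmeasured is dropped; if every block drops,
    that is a hard error.
    """
    blocks: dict[str, pd.DataFrame] = {}
    for ct, genes in superpathway.per_celltype.items():
        if ct not in pseudobulk.blocks:
            logger.warning("cell type %r of pathway %s not in pseudobulk; skipped",
                           ct, superpathway.pathway_id)
            continue
        measured = pseudobulk.blocks[ct].columns
        keep = [g for g in genes if g in measured]
        dropped = [g for g in genes if g not in measured]
        if dropped:
            logger.warning(
                "pathway %s, cell type %r: %d/%d genes unmeasured, dropped",
                superpathway.pathway_id, ct, len(dropped), len(genes),
            )
        if not keep:
            logger.warning(
                "pathway %s, cell type %r: no genes measured; block dropped",
                superpathway.pathway_id, ct,
            )
            continue
        blocks[ct] = pseudobulk.blocks[ct][keep].copy()
    if not blocks:
        raise DataError(
            f"pathway {superpathway.pathway_id}: no measured genes in any cell-type block"
        )
    return PseudobulkBlocks(blocks)
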