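"""Synthetic human and disease-model datasets with known ground truth.

Emulates the statistical structure the method assumes: negative-binomial
single-cell counts, per-cell-type class location shifts on the log
pseudobulk scale, controllable orthology coverage, cell-type mapping and
fold-change concordance between human and model.  Every generator is
deterministic under its seed and emits a ground-truth manifest.

The count simulator produces approximate pseudobulk shifts (library-size
normalization couples genes); the ``simulate_exact_shift`` path injects the
shift directly at the pseudobulk stage, where the recapitulation identities
are defined, and is exact by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from singist.datamodel import (
    CellTypeMap,
    DataError,
    OrthologyMap,
    PseudobulkBlocks,
    SingleCellData,
    Superpathway,
)
from singist.recapitulation import FoldChangeBlocks

_CONCORDANCE_MODES = ("perfect", "sign-flipped", "partial", "null")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data generators.

    Defaults describe a small two-class skin-biopsy-like cohort: 5 samples
    per class, 3 annotated cell types with 60 cells each per sample, one
    50-gene pathway with 10 signal genes per cell type shifted by 2 log2
    units in the target class, on a background of 950 non-pathway genes so
    signal genes are a small fraction of each cell's library.
    """

    seed: int
    n_per_class: int = 5
    cell_types: tuple[str, ...] = ("TC", "KC", "DC")
    cells_per_sample: int = 60
    n_genes: int = 50                       # pathway genes
    n_background_genes: int = 950
    signal_genes_per_celltype: int = 10
    shift: float = 2.0                      # log2 units
    concordance: str = "perfect"            # perfect | sign-flipped | partial | null
    rho: float = 0.5                        # attenuation in partial mode
    partial_noise_sd: float = 0.25
    orthology_coverage: float = 1.0
    unmapped_celltypes: tuple[str, ...] = ()
    deg_significant_fraction: float = 1.0
    dispersion: float = 2.0                 # NB size parameter; larger = less noise
    base_mean_log_sigma: float = 0.5
    pathway_id: str = "SIM_PATHWAY"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise DataError("a seed is mandatory")
        if not (0.0 <= self.orthology_coverage <= 1.0):
            raise DataError("orthology coverage must lie in [0, 1]")
        if self.concordance not in _CONCORDANCE_MODES:
            raise DataError(f"concordance must be one of {_CONCORDANCE_MODES}")
        if self.n_per_class < 1 or self.cells_per_sample < 1 or self.n_genes < 1:
            raise DataError("sample, cell and gene counts must be positive")
        if not np.isfinite(self.shift):
            raise DataError("shift must be finite")


def _gene_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    pathway = [f"GENE{i:04d}" for i in range(1, config.n_genes + 1)]
    background = [f"BKG{i:04d}" for i in range(1, config.n_background_genes + 1)]
    return pathway, background


def _pick_signal_genes(config: SimulationConfig, rng: np.random.Generator,
                       pathway_genes: list[str]) -> dict[str, list[str]]:
    k = min(config.signal_genes_per_celltype, len(pathway_genes))
    return {
        ct: sorted(rng.choice(pathway_genes, size=k, replace=False).tolist())
        for ct in config.cell_types
    }


def model_symbol(human_symbol: str) -> str:
    """Model-organism styling of a human symbol (e.g. GENE0001 -> Gene0001)."""
    return human_symbol.capitalize()


@dataclass
class HumanSimulation:
    data: SingleCellData
    superpathway: Superpathway
    truth: dict


def simulate_human(config: SimulationConfig) -> HumanSimulation:
    """Simulate human single-cell counts with class location shifts.

    Counts are negative binomial around per-gene base means (lognormal across
    genes); target-class cells have the mean of each signal gene in their
    cell type multiplied by ``2**shift`` so the pseudobulk log2 shift is
    approximately ``shift``.
    """
    rng = np.random.default_rng(config.seed)
    pathway_genes, background_genes = _gene_names(config)
    genes = pd.Index(pathway_genes + background_genes)
    signal = _pick_signal_genes(config, rng, pathway_genes)

    base_mean = np.exp(rng.normal(0.0, config.base_mean_log_sigma, size=len(genes)))
    gene_pos = {g: i for i, g in enumerate(genes)}

    samples = [f"T{i:02d}" for i in range(1, config.n_per_class + 1)] + [
        f"B{i:02d}" for i in range(1, config.n_per_class + 1)
    ]
    labels = pd.Series(
        [1] * config.n_per_class + [0] * config.n_per_class,
        index=pd.Index(samples, name="sample_id"), name="class_label",
    )

    cell_rows = []
    count_cols = []
    theta = config.dispersion
    for sid in samples:
        is_target = labels[sid] == 1
        for ct in config.cell_types:
            mu = base_mean.copy()
            if is_target:
                for g in signal[ct]:
                    mu[gene_pos[g]] *= 2.0 ** config.shift
            p_nb = theta / (theta + mu)
            draws = rng.negative_binomial(
                theta, p_nb[:, None],
                size=(len(genes), config.cells_per_sample),
            )
            count_cols.append(sp.csr_matrix(draws))
            for k in range(config.cells_per_sample):
                cell_rows.append(
                    {"cell_id": f"{sid}_{ct}_{k:03d}", "sample_id": sid, "cell_type": ct}
                )
    counts = sp.hstack(count_cols, format="csr")
    cells = pd.DataFrame(cell_rows).set_index("cell_id")

    superpathway = Superpathway.uniform(config.pathway_id, pathway_genes,
                                        config.cell_types)
    truth = {
        "signal_genes": signal,
        "shift": config.shift,
        "pathway_genes": pathway_genes,
        "seed": config.seed,
    }
    data = SingleCellData(counts=counts, genes=genes, cells=cells, samples=labels)
    return HumanSimulation(data=data, superpathway=superpathway, truth=truth)


@dataclass
class ModelSimulation:
    fc: FoldChangeBlocks
    fc_table: pd.DataFrame
    orthology: OrthologyMap
    ctmap: CellTypeMap
    truth: dict


def simulate_model(config: SimulationConfig, human: HumanSimulation) -> ModelSimulation:
    """Derive a disease-model fold-change table concordant with the human truth.

    Modes: ``perfect`` — model log2FC equals the human shift on every covered
    one-to-one ortholog, significant; ``sign-flipped`` — negated; ``partial``
    — attenuated by ``rho`` plus noise; ``null`` — zero and non-significant.
    ``orthology_coverage`` controls the exact fraction of pathway genes
    flagged one-to-one; ``unmapped_celltypes`` are emitted as absent.
    """
    rng = np.random.default_rng(config.seed + 1)
    pathway_genes = human.truth["pathway_genes"]
    signal = human.truth["signal_genes"]
    s = float(human.truth["shift"])

    n_cov = int(round(config.orthology_coverage * len(pathway_genes)))
    n_cov = min(n_cov, len(pathway_genes))
    # prefix of one seeded permutation: coverage levels are nested, so lowering
    # coverage only ever removes orthologs
    order = rng.permutation(pathway_genes)
    covered = set(order[:n_cov].tolist())
    orth = pd.DataFrame(
        {
            "human_symbol": pathway_genes,
            "model_symbol": [model_symbol(g) for g in pathway_genes],
            "one_to_one": [g in covered for g in pathway_genes],
        }
    )

    ctmap = CellTypeMap(
        {
            ct: (None if ct in config.unmapped_celltypes else f"m{ct}")
            for ct in config.cell_types
        }
    )

    rows = []
    for ct in config.cell_types:
        model_ct = ctmap.mapping[ct]
        if model_ct is None:
            continue
        sig_set = set(signal[ct])
        for g in pathway_genes:
            is_sig_gene = g in sig_set
            if config.concordance == "null" or not is_sig_gene:
                lfc, adj_p = 0.0, 1.0
            else:
                if config.concordance == "perfect":
                    lfc = s
                elif config.concordance == "sign-flipped":
                    lfc = -s
                else:  # partial
                    lfc = config.rho * s + rng.normal(0.0, config.partial_noise_sd)
                significant = rng.random() < config.deg_significant_fraction
                adj_p = 0.001 if significant else 0.5
            rows.append(
                {"cell_type": model_ct, "model_gene": model_symbol(g),
                 "log2FC": lfc, "adj_p": adj_p}
            )
    fc_table = pd.DataFrame(rows)
    fc = FoldChangeBlocks.from_table(fc_table)
    truth = {
        "concordance": config.concordance,
        "covered_genes": sorted(covered),
        "orthology_coverage": config.orthology_coverage,
        "unmapped_celltypes": list(config.unmapped_celltypes),
    }
    return ModelSimulation(fc=fc, fc_table=fc_table, orthology=OrthologyMap(orth),
                           ctmap=ctmap, truth=truth)


@dataclass
class ExactShiftDataset:
    """Paired location-shift dataset defined directly at the pseudobulk stage.

    Target sample k is an exact copy of base sample k plus the per-gene shift
    on signal genes, so reference and predicted recapitulations coincide
    identically when the model fold change equals the injected shift.
    """

    blocks: PseudobulkBlocks
    y: pd.Series
    superpathway: Superpathway
    fc: FoldChangeBlocks
    orthology: OrthologyMap
    ctmap: CellTypeMap
    truth: dict


def simulate_exact_shift(config: SimulationConfig) -> ExactShiftDataset:
    """Location-shift pseudobulk with the shift injected exactly.

    Base-class pseudobulk values are Gaussian on the log2 scale; each target
    sample equals one base sample plus ``shift`` on the signal genes of each
    cell type.  The accompanying disease-model fold changes follow the
    configured concordance mode with full significance on signal genes.
    """
    rng = np.random.default_rng(config.seed)
    pathway_genes, _ = _gene_names(config)
    signal = _pick_signal_genes(config, rng, pathway_genes)

    samples = [f"T{i:02d}" for i in range(1, config.n_per_class + 1)] + [
        f"B{i:02d}" for i in range(1, config.n_per_class + 1)
    ]
    y = pd.Series(
        [1] * config.n_per_class + [0] * config.n_per_class,
        index=pd.Index(samples, name="sample_id"), name="class_label",
    )

    blocks = {}
    for ct in config.cell_types:
        base = rng.normal(5.0, 1.0, size=(config.n_per_class, len(pathway_genes)))
        target = base.copy()
        sig_idx = [pathway_genes.index(g) for g in signal[ct]]
        target[:, sig_idx] += config.shift
        mat = np.vstack([target, base])
        blocks[ct] = pd.DataFrame(mat, index=y.index, columns=pathway_genes)
    pb = PseudobulkBlocks(blocks)

    superpathway = Superpathway.uniform(config.pathway_id, pathway_genes,
                                        config.cell_types)
    human = HumanSimulation(
        data=None,  # type: ignore[arg-type]  # pseudobulk-level dataset has no counts
        superpathway=superpathway,
        truth={"signal_genes": signal, "shift": config.shift,
               "pathway_genes": pathway_genes, "seed": config.seed},
    )
    model = simulate_model(config, human)
    truth = dict(human.truth)
    truth.update(model.truth)
    return ExactShiftDataset(
        blocks=pb, y=y, superpathway=superpathway, fc=model.fc,
        orthology=model.orthology, ctmap=model.ctmap, truth=truth,
    )


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, default=str))
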