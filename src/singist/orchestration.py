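"""End-to-end runner: train -> validate -> treat -> report per (pathway, model).

Each superpathway and each disease model is analysed independently.  A
superpathway must pass the permutation validity gate (BH across pathways at
the configured FDR) for its recapitulation fractions to appear in the
headline table; failing pathways are still written, flagged, with fractions
suppressed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import singist
from singist.asmbplsda import AsmbPLSDAModel, fit, decompose, tune_loocv
from singist.datamodel import (
    DataError,
    PseudobulkBlocks,
    Superpathway,
    assemble_superpathway_blocks,
    build_pseudobulk,
)
from singist.inference import (
    bh_adjust,
    compute_cip_gip,
    gip_significance,
    permutation_validity_test,
)
from singist.io import (
    read_celltype_map,
    read_counts,
    read_fc_table,
    read_gmt,
    read_orthology,
)
from singist.recapitulation import (
    FoldChangeBlocks,
    apply_treatment,
    compute_fold_changes,
    fraction_report,
    predicted_recapitulation,
    reference_recapitulation,
)

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """One disease model: either a precomputed FC table or raw counts."""

    name: str
    orthology: str
    celltype_map: str
    fc_table: str | None = None
    counts: str | None = None
    cells_meta: str | None = None
    genes_meta: str | None = None
    samples_meta: str | None = None


@dataclass
class RunConfig:
    """Full run configuration; thresholds default to the method's choices
    (permutation alpha 0.05, FDR 0.1, fold-change gate 0.05)."""

    seed: int
    outdir: str
    human_counts: str = ""
    human_cells_meta: str = ""
    human_genes_meta: str | None = None
    human_samples_meta: str | None = None
    gmt: str = ""
    pathways: list[str] = field(default_factory=list)   # empty = all in the GMT
    models: list[ModelSpec] = field(default_factory=list)
    norm_target: float = 1e4
    min_cells: int = 10
    J_grid: list[int] = field(default_factory=lambda: [1, 2, 3])
    lambda_grid: list[float] = field(
        default_factory=lambda: [0.0, 0.25, 0.5, 0.75, 0.9, 0.95, 0.99, 1.0]
    )
    per_block_lambdas: bool = True
    threshold_mode: str = "soft"
    alpha: float = 0.05
    fdr: float = 0.1
    fc_gate: float = 0.05
    n_perm: int = 1000
    gip_n_perm: int = 200
    run_gip_significance: bool = False

    def __post_init__(self) -> None:
        for name, v in (("alpha", self.alpha), ("fdr", self.fdr), ("fc_gate", self.fc_gate)):
            if not (0.0 < v < 1.0):
                raise DataError(f"{name} must lie in (0, 1), got {v}")
        self.models = [
            m if isinstance(m, ModelSpec) else ModelSpec(**m) for m in self.models
        ]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class PairResult:
    """Everything computed for one (superpathway, disease model) pair."""

    pathway_id: str
    model_name: str
    cv: "singist.CVResult"
    model: AsmbPLSDAModel
    permutation: "singist.PermutationTestResult"
    importance: "singist.ImportanceReport"
    report: "singist.RecapitulationReport"

    @property
    def valid(self) -> bool:
        return self.permutation.passed


def run_pair(
    blocks: PseudobulkBlocks,
    y,
    pathway_id: str,
    fc: FoldChangeBlocks,
    orthology,
    ctmap,
    model_name: str = "model",
    config: RunConfig | None = None,
    seed: int | None = None,
    fitted: tuple | None = None,
):
    """Analyse one (superpathway, disease model) pair on in-memory inputs.

    ``fitted`` may carry a previously tuned (cv, model, permutation,
    importance) tuple so several disease models reuse one human fit.
    """
    cfg = config or RunConfig(seed=seed if seed is not None else 0, outdir=".")
    seed = cfg.seed if seed is None else seed
    y_arr = np.asarray(y, dtype=float).ravel()

    if fitted is None:
        cv = tune_loocv(
            blocks, y_arr, J_grid=cfg.J_grid, lambda_grid=cfg.lambda_grid,
            per_block=cfg.per_block_lambdas, threshold_mode=cfg.threshold_mode,
        )
        model = fit(blocks, y_arr, J=cv.best_J, lambdas=cv.best_lambdas,
                    threshold_mode=cfg.threshold_mode)
        perm = permutation_validity_test(
            blocks, y_arr, J=model.J, lambdas=model.lambdas, n_perm=cfg.n_perm,
            seed=seed, alpha=cfg.alpha, fdr=cfg.fdr, threshold_mode=cfg.threshold_mode,
        )
        if cfg.run_gip_significance:
            importance = gip_significance(blocks, y_arr, model,
                                          n_perm=cfg.gip_n_perm, seed=seed)
        else:
            importance = compute_cip_gip(model)
    else:
        cv, model, perm, importance = fitted

    decomp = decompose(model, blocks)
    omega_ref, gamma_ref = reference_recapitulation(decomp, y_arr)
    base_ids = blocks.sample_ids[y_arr == 0]
    base_blocks = blocks.subset_samples(base_ids)
    treatment = apply_treatment(base_blocks, fc, orthology, ctmap)
    omega_pred, gamma_pred, d_base, d_treat = predicted_recapitulation(
        model, base_blocks, treatment.blocks
    )
    report = fraction_report(
        pathway_id, omega_ref, omega_pred, gamma_ref, gamma_pred,
        d_base, d_treat, treatment.gating,
    )
    return PairResult(
        pathway_id=pathway_id, model_name=model_name, cv=cv, model=model,
        permutation=perm, importance=importance, report=report,
    )


def run_full(config: RunConfig) -> dict:
    """Run the complete pipeline from files per the configuration.

    Returns a dict with per-(pathway, model) results, the headline table and
    the manifest; also writes reports/*.tsv, manifest.json and a run log
    under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    (outdir / "reports").mkdir(parents=True, exist_ok=True)
    (outdir / "logs").mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "logs" / "run.log")
    logging.getLogger("singist").addHandler(handler)

    try:
        human = read_counts(
            config.human_counts, config.human_cells_meta,
            config.human_genes_meta, config.human_samples_meta,
        )
        gene_sets = read_gmt(config.gmt)
        if config.pathways:
            gene_sets = [(pid, g) for pid, g in gene_sets if pid in config.pathways]
        if not gene_sets:
            raise DataError("no pathways selected")

        pseudobulk = build_pseudobulk(
            human, norm_target=config.norm_target, min_cells=config.min_cells
        )
        y = human.samples.loc[pseudobulk.sample_ids].to_numpy(dtype=float)

        model_inputs = []
        for spec in config.models:
            orthology = read_orthology(spec.orthology)
            ctmap = read_celltype_map(spec.celltype_map)
            if spec.fc_table:
                fc_source = ("table", read_fc_table(spec.fc_table))
            else:
                md = read_counts(spec.counts, spec.cells_meta, spec.genes_meta,
                                 spec.samples_meta)
                fc_source = ("counts", md)
            model_inputs.append((spec, orthology, ctmap, fc_source))

        results: list[PairResult] = []
        failures: list[dict] = []
        for pid, genes in gene_sets:
            sp_def = Superpathway.uniform(pid, genes, pseudobulk.cell_types)
            try:
                blocks = assemble_superpathway_blocks(pseudobulk, sp_def)
            except DataError as exc:
                failures.append({"pathway": pid, "model": "*", "error": str(exc)})
                continue
            fitted = None
            for spec, orthology, ctmap, (kind, src) in model_inputs:
                try:
                    if kind == "table":
                        fc = FoldChangeBlocks.from_table(src, gate=config.fc_gate)
                    else:
                        oto = orthology.one_to_one()
                        genes_model = {}
                        for ct in blocks.cell_types:
                            mct = ctmap.model_type(ct)
                            if mct is None:
                                continue
                            genes_model.setdefault(mct, [])
                            genes_model[mct].extend(
                                oto[g] for g in blocks.blocks[ct].columns if g in oto
                            )
                        fc = compute_fold_changes(src, genes=genes_model,
                                                  gate=config.fc_gate)
                    pair = run_pair(
                        blocks, y, pid, fc, orthology, ctmap,
                        model_name=spec.name, config=config, fitted=fitted,
                    )
                    fitted = (pair.cv, pair.model, pair.permutation, pair.importance)
                    results.append(pair)
                except DataError as exc:
                    logger.error("pathway %s, model %s failed: %s", pid, spec.name, exc)
                    failures.append({"pathway": pid, "model": spec.name,
                                     "error": str(exc)})

        # BH across pathways on the permutation p-values (one p per pathway)
        per_pathway: dict[str, list[PairResult]] = {}
        for r in results:
            per_pathway.setdefault(r.pathway_id, []).append(r)
        pids = list(per_pathway)
        raw_p = np.array([per_pathway[p][0].permutation.p_value for p in pids])
        adj = bh_adjust(raw_p) if len(raw_p) else raw_p
        for p, a in zip(pids, adj):
            for r in per_pathway[p]:
                r.permutation.p_adjusted = float(a)

        headline_rows = []
        for r in results:
            row = {
                "pathway": r.pathway_id,
                "model": r.model_name,
                "valid": r.valid,
                "perm_p": r.permutation.p_value,
                "perm_p_adjusted": r.permutation.p_adjusted,
                "omega_frac_pct": r.report.omega_frac if r.valid else np.nan,
            }
            for ct in r.report.gamma.index:
                row[f"gamma_frac_pct[{ct}]"] = (
                    r.report.gamma.loc[ct, "fraction"] if r.valid else np.nan
                )
            headline_rows.append(row)
        headline = pd.DataFrame(headline_rows)

        headline.to_csv(outdir / "reports" / "headline.tsv", sep="\t", index=False)
        for r in results:
            stem = f"{r.pathway_id}__{r.model_name}".replace("/", "_")
            r.report.to_frame().to_csv(
                outdir / "reports" / f"{stem}.recapitulation.tsv", sep="\t", index=False
            )
            r.importance.gene_table().to_csv(
                outdir / "reports" / f"{stem}.importance.tsv", sep="\t", index=False
            )
            r.model.save(outdir / "reports" / f"{stem}.model.json")

        manifest = {
            "singist_version": singist.__version__,
            "seed": config.seed,
            "n_perm": config.n_perm,
            "alpha": config.alpha,
            "fdr": config.fdr,
            "fc_gate": config.fc_gate,
            "J_grid": list(config.J_grid),
            "lambda_grid": list(config.lambda_grid),
            "pathways": pids,
            "models": [m.name for m in config.models],
            "failures": failures,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return {"results": results, "headline": headline, "manifest": manifest}
    finally:
        logging.getLogger("singist").removeHandler(handler)
        handler.close()
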