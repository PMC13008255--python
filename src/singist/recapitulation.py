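"""The singIST core: fold-change gating, in silico treatment, recapitulation.

A disease model's per-gene log2 fold changes (target vs. base class) are
gated on significance, injected into the human *base-class* pseudobulk
wherever a mapped cell type and a one-to-one ortholog exist, and the treated
samples are scored with the frozen human-fitted asmbPLS-DA.  Recapitulation
is the median score shift of treated vs. untreated base samples, expressed
as a percentage of the human target-vs-base reference shift, at the
superpathway, cell-type and gene levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from singist.asmbplsda import AsmbPLSDAModel, ScoreDecomposition, decompose
from singist.datamodel import CellTypeMap, DataError, OrthologyMap, PseudobulkBlocks, SingleCellData
from singist.inference import bh_adjust

logger = logging.getLogger(__name__)

# gating reason codes attached to each (cell type, gene) pair
REASON_OK = "ok"
REASON_UNMAPPED = "unmapped_cell_type"
REASON_NO_ORTHOLOG = "no_one_to_one_ortholog"
REASON_NOT_IN_MODEL = "not_sequenced_in_model"
REASON_NOT_SIGNIFICANT = "non_significant"
REASON_TOO_FEW_CELLS = "too_few_cells"

#: below this absolute reference shift, fractions are reported as undefined
DEGENERATE_EPS = 1e-8


@dataclass
class FoldChangeBlocks:
    """Per-model-cell-type gated log2 fold changes.

    ``blocks[ct]`` is indexed by model gene symbol with columns ``log2FC``,
    ``adj_p`` and ``r`` — the gated value: 0 when the adjusted p-value
    exceeds the gate, the raw log2FC otherwise.
    """

    blocks: dict[str, pd.DataFrame]
    gate: float = 0.05

    def __post_init__(self) -> None:
        for ct, df in self.blocks.items():
            missing = {"log2FC", "adj_p", "r"} - set(df.columns)
            if missing:
                raise DataError(f"fold-change block {ct!r} lacks columns {sorted(missing)}")

    @classmethod
    def from_table(cls, table: pd.DataFrame, gate: float = 0.05) -> "FoldChangeBlocks":
        """Build from a tidy table with columns cell_type, model_gene, log2FC, adj_p."""
        blocks = {}
        for ct, grp in table.groupby("cell_type", sort=False):
            df = grp.set_index("model_gene")[["log2FC", "adj_p"]].astype(float)
            df["r"] = np.where(df["adj_p"] <= gate, df["log2FC"], 0.0)
            blocks[str(ct)] = df
        return cls(blocks, gate=gate)

    def negated(self) -> "FoldChangeBlocks":
        """Same gating, every fold change multiplied by -1."""
        out = {}
        for ct, df in self.blocks.items():
            neg = df.copy()
            neg["log2FC"] = -neg["log2FC"]
            neg["r"] = -neg["r"]
            out[ct] = neg
        return FoldChangeBlocks(out, gate=self.gate)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for ct, df in self.blocks.items():
            t = df.reset_index(names="model_gene")
            t.insert(0, "cell_type", ct)
            rows.append(t)
        return pd.concat(rows, ignore_index=True)


def compute_fold_changes(
    model_data: SingleCellData,
    genes: dict[str, list[str]] | None = None,
    gate: float = 0.05,
    min_cells_per_class: int = 3,
) -> FoldChangeBlocks:
    """Per-cell-type, per-gene gated log2 fold changes of the disease model.

    The fold change is the difference of mean ``log2(count + 1)`` between
    target- and base-class cells (the log2 ratio of geometric means of
    counts + 1).  P-values come from a two-sided Wilcoxon rank-sum test on
    the per-cell log values, Benjamini-Hochberg adjusted within each cell
    type, and gate the fold change at adjusted p <= ``gate``.

    ``genes`` optionally restricts each model cell type to a gene list (the
    superpathway translated to model symbols).  Cell types with fewer than
    ``min_cells_per_class`` cells in either class are fully gated to zero.
    """
    cls = model_data.samples.loc[model_data.cells["sample_id"]].to_numpy()
    cell_types = list(pd.unique(model_data.cells["cell_type"]))
    if genes is not None:
        cell_types = [ct for ct in cell_types if ct in genes]

    blocks: dict[str, pd.DataFrame] = {}
    for ct in cell_types:
        in_ct = (model_data.cells["cell_type"] == ct).to_numpy()
        if genes is None:
            gene_list = list(model_data.genes)
        else:
            gene_list = [g for g in genes[ct] if g in set(model_data.genes)]
        if not gene_list:
            continue
        gi = model_data.genes.get_indexer(pd.Index(gene_list))
        target = in_ct & (cls == 1)
        base = in_ct & (cls == 0)
        X_t = np.log2(1.0 + np.asarray(model_data.counts[gi][:, target].todense()))
        X_b = np.log2(1.0 + np.asarray(model_data.counts[gi][:, base].todense()))
        lfc = X_t.mean(axis=1) - X_b.mean(axis=1) if X_t.size and X_b.size else np.zeros(len(gi))
        if target.sum() < min_cells_per_class or base.sum() < min_cells_per_class:
            logger.warning(
                "cell type %r: <%d cells in a class; all fold changes gated to zero",
                ct, min_cells_per_class,
            )
            df = pd.DataFrame(
                {"log2FC": lfc, "adj_p": 1.0, "r": 0.0, "reason": REASON_TOO_FEW_CELLS},
                index=pd.Index(gene_list, name="model_gene"),
            )
            blocks[ct] = df
            continue
        pvals = np.ones(len(gene_list))
        for k in range(len(gene_list)):
            a, b = X_t[k], X_b[k]
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                pvals[k] = 1.0
            else:
                pvals[k] = mannwhitneyu(a, b, alternative="two-sided").pvalue
        adj = bh_adjust(pvals)
        r = np.where(adj <= gate, lfc, 0.0)
        blocks[ct] = pd.DataFrame(
            {"log2FC": lfc, "adj_p": adj, "r": r, "reason": ""},
            index=pd.Index(gene_list, name="model_gene"),
        )
    if not blocks:
        raise DataError("no cell types with genes to test in the disease model data")
    return FoldChangeBlocks(blocks, gate=gate)


@dataclass
class TreatmentResult:
    """singIST-treated base-class pseudobulk plus the per-gene gating log."""

    blocks: PseudobulkBlocks
    gating: pd.DataFrame  # cell_type, gene, model_gene, r, reason


def apply_treatment(
    base_blocks: PseudobulkBlocks,
    fc: FoldChangeBlocks,
    orthology: OrthologyMap,
    ctmap: CellTypeMap,
) -> TreatmentResult:
    """Inject the disease model's gated fold changes into base-class pseudobulk.

    For each human gene g in cell type b: if b maps to a model cell type AND
    g has a one-to-one ortholog observed in the model, the treated value is
    ``x + r`` with r the gated model log2FC; otherwise the value is left
    unchanged.  Treated blocks keep human symbols and sample order.
    """
    oto = orthology.one_to_one()
    rows = []
    for ct, df in base_blocks.blocks.items():
        model_ct = ctmap.model_type(ct)
        for g in df.columns:
            model_gene = oto.get(g)
            r, reason = 0.0, REASON_OK
            if model_ct is None:
                reason = REASON_UNMAPPED
            elif model_gene is None:
                reason = REASON_NO_ORTHOLOG
            elif model_ct not in fc.blocks or model_gene not in fc.blocks[model_ct].index:
                reason = REASON_NOT_IN_MODEL
            else:
                rec = fc.blocks[model_ct].loc[model_gene]
                stated = str(rec["reason"]) if "reason" in rec.index else ""
                r = float(rec["r"])
                if r == 0.0:
                    reason = stated or REASON_NOT_SIGNIFICANT
            rows.append(
                {"cell_type": ct, "gene": g, "model_gene": model_gene,
                 "r": r, "reason": reason}
            )
    gating = pd.DataFrame(rows)
    treated = {}
    for ct, df in base_blocks.blocks.items():
        sub = gating[gating["cell_type"] == ct]
        shift = sub.set_index("gene")["r"].reindex(df.columns).fillna(0.0)
        treated[ct] = df + shift.to_numpy()[np.newaxis, :]
    return TreatmentResult(blocks=PseudobulkBlocks(treated), gating=gating)


def reference_recapitulation(
    decomp: ScoreDecomposition, y
) -> tuple[float, pd.Series]:
    """Reference shifts: median target minus median base, overall and per cell type."""
    y = np.asarray(y, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise DataError("reference recapitulation needs both classes")
    t, b = y == 1, y == 0
    omega = float(np.median(decomp.y[t]) - np.median(decomp.y[b]))
    gamma = decomp.gamma[t].median(axis=0) - decomp.gamma[b].median(axis=0)
    gamma.name = "Gamma_ref"
    if abs(omega) < DEGENERATE_EPS:
        logger.warning("degenerate reference shift |Omega| < %g", DEGENERATE_EPS)
    return omega, gamma


def predicted_recapitulation(
    model: AsmbPLSDAModel,
    base_blocks: PseudobulkBlocks,
    treated_blocks: PseudobulkBlocks,
) -> tuple[float, pd.Series, ScoreDecomposition, ScoreDecomposition]:
    """Predicted shifts: median treated minus median untreated, base samples only.

    Uses the step-1 fitted model unmodified (identical loadings, scaling and
    reference).  Returns the shifts plus both score decompositions so gene
    increments can be derived downstream.
    """
    d_base = decompose(model, base_blocks)
    d_treat = decompose(model, treated_blocks)
    omega_p = float(d_treat.y.median() - d_base.y.median())
    gamma_p = d_treat.gamma.median(axis=0) - d_base.gamma.median(axis=0)
    gamma_p.name = "Gamma_pred"
    return omega_p, gamma_p, d_base, d_treat


@dataclass
class RecapitulationReport:
    """All recapitulation quantities for one (superpathway, disease model) pair.

    Fractions are percentages of the corresponding reference shift; they are
    NaN (never infinite) where the reference is degenerate.
    """

    pathway_id: str
    omega_ref: float
    omega_pred: float
    omega_frac: float                       # percent; NaN if degenerate
    gamma: pd.DataFrame                     # per cell type: reference, predicted, fraction
    delta: dict[str, pd.Series]             # ct -> per-gene increment (sample-independent)
    delta_frac: dict[str, pd.Series]        # ct -> percent of Gamma_ref[ct]
    gating: pd.DataFrame
    orthology_coverage: pd.Series           # percent of block genes with 1:1 orthologs
    degenerate_reference: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table across superpathway, cell-type and gene levels."""
        rows = [
            {"level": "superpathway", "pathway": self.pathway_id, "cell_type": "",
             "gene": "", "reference": self.omega_ref, "predicted": self.omega_pred,
             "fraction": self.omega_frac, "reason_code": ""}
        ]
        for ct in self.gamma.index:
            rows.append(
                {"level": "cell_type", "pathway": self.pathway_id, "cell_type": ct,
                 "gene": "", "reference": self.gamma.loc[ct, "reference"],
                 "predicted": self.gamma.loc[ct, "predicted"],
                 "fraction": self.gamma.loc[ct, "fraction"], "reason_code": ""}
            )
        reasons = self.gating.set_index(["cell_type", "gene"])["reason"]
        for ct, dfrac in self.delta_frac.items():
            for g in dfrac.index:
                rows.append(
                    {"level": "gene", "pathway": self.pathway_id, "cell_type": ct,
                     "gene": g, "reference": np.nan,
                     "predicted": self.delta[ct].loc[g],
                     "fraction": dfrac.loc[g],
                     "reason_code": reasons.get((ct, g), "")}
                )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "pathway": self.pathway_id,
            "omega_ref": self.omega_ref,
            "omega_pred": self.omega_pred,
            "omega_frac_pct": None if np.isnan(self.omega_frac) else self.omega_frac,
            "gamma_frac_pct": {
                ct: (None if np.isnan(v) else float(v))
                for ct, v in self.gamma["fraction"].items()
            },
            "orthology_coverage_pct": {
                ct: float(v) for ct, v in self.orthology_coverage.items()
            },
            "degenerate_reference": bool(self.degenerate_reference),
        }


def fraction_report(
    pathway_id: str,
    omega_ref: float,
    omega_pred: float,
    gamma_ref: pd.Series,
    gamma_pred: pd.Series,
    decomp_base: ScoreDecomposition,
    decomp_treated: ScoreDecomposition,
    gating: pd.DataFrame,
    eps: float = DEGENERATE_EPS,
    tol_constant: float = 1e-10,
) -> RecapitulationReport:
    """Assemble fractions and gene attributions into a report.

    The per-gene increment Delta_gb = delta'_igb - delta_igb is provably
    sample-independent (treatment adds a per-gene constant on the scaled
    predictor); it is computed from the first sample and verified constant
    across samples to ``tol_constant``.
    """
    degenerate = abs(omega_ref) < eps
    omega_frac = np.nan if degenerate else 100.0 * omega_pred / omega_ref

    gamma = pd.DataFrame({"reference": gamma_ref, "predicted": gamma_pred})
    gamma["fraction"] = np.where(
        gamma["reference"].abs() < eps, np.nan,
        100.0 * gamma["predicted"] / gamma["reference"],
    )

    delta: dict[str, pd.Series] = {}
    delta_frac: dict[str, pd.Series] = {}
    for ct in decomp_base.delta:
        diff = decomp_treated.delta[ct] - decomp_base.delta[ct]
        spread = (diff.max(axis=0) - diff.min(axis=0)).max()
        if spread > tol_constant:
            logger.warning(
                "cell type %r: gene increments vary across samples by %.3g "
                "(expected constant)", ct, spread,
            )
        d = diff.iloc[0]
        d.name = "Delta"
        delta[ct] = d
        ref = gamma_ref.get(ct, np.nan)
        if pd.isna(ref) or abs(ref) < eps:
            delta_frac[ct] = pd.Series(np.nan, index=d.index, name="Delta_frac")
        else:
            delta_frac[ct] = (100.0 * d / ref).rename("Delta_frac")

    cov = {}
    for ct, grp in gating.groupby("cell_type", sort=False):
        observed = (~grp["reason"].isin([REASON_NO_ORTHOLOG, REASON_NOT_IN_MODEL,
                                         REASON_UNMAPPED])).sum()
        # unmapped cell types have no observable orthology; report coverage of
        # the gene-level mapping irrespective of the cell-type gate
        if (grp["reason"] == REASON_UNMAPPED).all():
            observed = grp["model_gene"].notna().sum()
        cov[ct] = 100.0 * observed / len(grp)
    coverage = pd.Series(cov, name="orthology_coverage_pct")

    return RecapitulationReport(
        pathway_id=pathway_id,
        omega_ref=omega_ref,
        omega_pred=omega_pred,
        omega_frac=omega_frac,
        gamma=gamma,
        delta=delta,
        delta_frac=delta_frac,
        gating=gating,
        orthology_coverage=coverage,
        degenerate_reference=degenerate,
    )
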