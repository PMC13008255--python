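"""Model validity and importance inference for fitted asmbPLS-DA models.

Three procedures: a label-permutation test of the tuned model's LOOCV F1
error (is the class separation better than chance?); cell- and gene-level
importance projections (CIP/GIP), component-importance-weighted squared PLS
weights that sum to one; and a jackknife-vs-null Mann-Whitney test of GIP
significance with a Bonferroni factor bounded below by the expected number
of true null genes per block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import f1_score
from statsmodels.stats.multitest import multipletests

from singist.asmbplsda import (
    AsmbPLSDAModel,
    DataError,
    SingleClassError,
    _loocv_error,
    fit,
    predict,
)
from singist.datamodel import PseudobulkBlocks

logger = logging.getLogger(__name__)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PermutationTestResult:
    """Label-permutation validity test of one tuned superpathway model."""

    observed_error: float
    null_errors: np.ndarray
    p_value: float
    ci_low: float                  # lower bound of the two-sided CI(1-alpha) of the null
    alpha: float
    p_adjusted: float | None = None
    fdr: float = 0.1

    @property
    def passed(self) -> bool:
        """Valid model: BH-adjusted p under the FDR AND observed error below
        the null CI(1-alpha)."""
        p = self.p_value if self.p_adjusted is None else self.p_adjusted
        return bool(p <= self.fdr and self.observed_error < self.ci_low)


def permutation_validity_test(
    blocks: PseudobulkBlocks,
    y,
    J: int,
    lambdas,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    fdr: float = 0.1,
    threshold_mode: str = "soft",
) -> PermutationTestResult:
    """Permutation test of the tuned model against the no-association null.

    The observed statistic is the LOOCV F1 error at the tuned ``(J, lambdas)``.
    For each permutation the labels are shuffled, one uniformly chosen sample
    is held out of fitting (guarding against overfit nulls), all samples are
    predicted and scored by F1 against the *true* labels.  The p-value is the
    plus-one-corrected fraction of null errors at least as small as observed.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    ids = blocks.sample_ids
    lam = np.asarray(lambdas, dtype=float)

    observed = _loocv_error(blocks, y, J, lam, threshold_mode)

    null_errors = np.empty(n_perm)
    for k in range(n_perm):
        err = _one_null_error(blocks, y, J, lam, threshold_mode, rng, ids, n)
        if err is None:  # one resample on a failed fit, then count as F1 = 0
            err = _one_null_error(blocks, y, J, lam, threshold_mode, rng, ids, n)
            if err is None:
                err = 1.0
        null_errors[k] = err

    k_better = int(np.sum(null_errors <= observed))
    p = (k_better + 1) / (n_perm + 1)
    ci_low = float(np.quantile(null_errors, alpha / 2))
    return PermutationTestResult(
        observed_error=float(observed),
        null_errors=null_errors,
        p_value=float(p),
        ci_low=ci_low,
        alpha=alpha,
        fdr=fdr,
    )


def _one_null_error(blocks, y, J, lam, threshold_mode, rng, ids, n) -> float | None:
    y_perm = rng.permutation(y)
    hold = int(rng.integers(n))
    keep = np.ones(n, dtype=bool)
    keep[hold] = False
    try:
        m = fit(blocks.subset_samples(ids[keep]), y_perm[keep], J=J, lambdas=lam,
                threshold_mode=threshold_mode)
    except (SingleClassError, DataError):
        return None
    preds = predict(m, blocks).to_numpy()
    y_cls = (preds >= 0.5).astype(int)
    return 1.0 - f1_score(y.astype(int), y_cls, zero_division=0)


@dataclass
class ImportanceReport:
    """CIP/GIP importance of a fitted model, optionally with GIP significance."""

    cip: pd.Series                         # per cell type, in [0, 1], sums to 1
    cip_sign: pd.Series
    gip: dict[str, pd.Series]              # ct -> per-gene, sums to 1 per active block
    gip_sign: dict[str, pd.Series]
    q_weights: np.ndarray                  # normalized component importances
    uninformative_blocks: list[str] = field(default_factory=list)
    gip_pvalues: dict[str, pd.Series] | None = None
    gip_adjusted: dict[str, pd.Series] | None = None
    m0: dict[str, int] | None = None

    def gene_table(self) -> pd.DataFrame:
        rows = []
        for ct in self.gip:
            df = pd.DataFrame({"GIP": self.gip[ct], "sign": self.gip_sign[ct]})
            df.insert(0, "cell_type", ct)
            if self.gip_pvalues is not None:
                df["p"] = self.gip_pvalues[ct]
                df["p_adjusted"] = self.gip_adjusted[ct]
            rows.append(df.reset_index(names="gene"))
        return pd.concat(rows, ignore_index=True)


def _component_importance(model: AsmbPLSDAModel) -> np.ndarray:
    """Relative importance q_j of each PLS component: the share of response
    sum-of-squares captured by the component during fitting."""
    expl = np.asarray(model.explained, dtype=float)
    total = expl.sum()
    if total <= 0:
        raise DataError("degenerate model: no component explains any response variance")
    return expl / total


def compute_cip_gip(model: AsmbPLSDAModel) -> ImportanceReport:
    """Cell and Gene Importance Projections of a fitted model.

    CIP_b is the q-weighted average of squared super weights; GIP_gb the
    q-weighted average of squared block weights, with each block's weighting
    restricted to the components where the block is active so that both
    indices sum to one (CIP across blocks; GIP within each active block).
    A block with zero weight in every component has GIP identically zero and
    is flagged uninformative.
    """
    qw = _component_importance(model)
    J = model.J
    cts = model.cell_types

    sup = model.super_weights  # (J, B), rows unit norm
    cip_vals = (qw[:, None] * sup**2).sum(axis=0)
    cip = pd.Series(cip_vals, index=cts, name="CIP")
    cip_sign = pd.Series(
        np.sign((qw[:, None] * sup).sum(axis=0)), index=cts, name="sign"
    )

    gip, gip_sign = {}, {}
    uninformative = []
    for bi, ct in enumerate(cts):
        Wmat = np.vstack([model.block_weights[j][ct] for j in range(J)])  # (J, p)
        norms2 = (Wmat**2).sum(axis=1)                                    # 0 or 1 per comp
        denom = float((qw * norms2).sum())
        if denom <= 0:
            gip[ct] = pd.Series(0.0, index=model.genes[ct], name="GIP")
            gip_sign[ct] = pd.Series(0.0, index=model.genes[ct], name="sign")
            uninformative.append(ct)
            continue
        vals = (qw[:, None] * Wmat**2).sum(axis=0) / denom
        gip[ct] = pd.Series(vals, index=model.genes[ct], name="GIP")
        gip_sign[ct] = pd.Series(
            np.sign((qw[:, None] * Wmat).sum(axis=0)), index=model.genes[ct], name="sign"
        )

    return ImportanceReport(
        cip=cip,
        cip_sign=cip_sign,
        gip=gip,
        gip_sign=gip_sign,
        q_weights=qw,
        uninformative_blocks=uninformative,
    )


def m0_lower_bound(model: AsmbPLSDAModel) -> dict[str, int]:
    """Per-block lower bound on the expected number of true null genes:
    floor(prod_j lambda_jb * |genes_b|), floored at 1."""
    out = {}
    for bi, ct in enumerate(model.cell_types):
        prod = float(np.prod(model.lambdas[:, bi]))
        out[ct] = max(1, int(np.floor(prod * len(model.genes[ct]))))
    return out


def gip_significance(
    blocks: PseudobulkBlocks,
    y,
    model: AsmbPLSDAModel,
    n_perm: int = 200,
    seed: int | None = None,
) -> ImportanceReport:
    """GIP significance by jackknife-vs-null Mann-Whitney tests.

    The jackknife distribution of each gene's GIP comes from leave-one-
    sample-out refits at the tuned hyperparameters.  The null distribution
    per block pools GIP values from refits on data whose entries (samples
    and genes jointly) are permuted within each block — never across blocks,
    where exchangeability would fail.  A one-sided Mann-Whitney U test
    (jackknife greater) yields the p-value, Bonferroni-adjusted by the m0
    lower bound on true nulls in the block.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 4:
        raise DataError("jackknife requires at least 4 samples")
    ids = blocks.sample_ids
    report = compute_cip_gip(model)

    # jackknife GIP distributions
    jack: dict[str, list[np.ndarray]] = {ct: [] for ct in model.cell_types}
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        try:
            m = fit(blocks.subset_samples(ids[keep]), y[keep], J=model.J,
                    lambdas=model.lambdas, threshold_mode=model.threshold_mode)
            imp = compute_cip_gip(m)
        except (SingleClassError, DataError):
            continue
        for ct in model.cell_types:
            jack[ct].append(imp.gip[ct].to_numpy())

    # null GIP distributions: entries permuted within blocks
    null_pool: dict[str, list[float]] = {ct: [] for ct in model.cell_types}
    for _ in range(n_perm):
        perm_blocks = {}
        for ct, df in blocks.blocks.items():
            vals = df.to_numpy().ravel()
            perm = rng.permutation(vals).reshape(df.shape)
            perm_blocks[ct] = pd.DataFrame(perm, index=df.index, columns=df.columns)
        try:
            m = fit(PseudobulkBlocks(perm_blocks), y, J=model.J,
                    lambdas=model.lambdas, threshold_mode=model.threshold_mode)
            imp = compute_cip_gip(m)
        except (SingleClassError, DataError):
            continue
        for ct in model.cell_types:
            null_pool[ct].extend(imp.gip[ct].to_numpy().tolist())

    m0 = m0_lower_bound(model)
    pvals: dict[str, pd.Series] = {}
    padj: dict[str, pd.Series] = {}
    for ct in model.cell_types:
        genes_ct = model.genes[ct]
        J_arr = np.vstack(jack[ct]) if jack[ct] else np.empty((0, len(genes_ct)))
        null = np.asarray(null_pool[ct])
        p = np.ones(len(genes_ct))
        for gi in range(len(genes_ct)):
            d = J_arr[:, gi] if J_arr.size else np.array([])
            if d.size == 0 or null.size == 0:
                p[gi] = 1.0
            elif np.all(d == 0):
                p[gi] = 1.0  # weight-zeroed gene cannot beat the null
            else:
                p[gi] = mannwhitneyu(d, null, alternative="greater").pvalue
        pvals[ct] = pd.Series(p, index=genes_ct, name="p")
        padj[ct] = pd.Series(np.minimum(1.0, p * m0[ct]), index=genes_ct,
                             name="p_adjusted")

    report.gip_pvalues = pvals
    report.gip_adjusted = padj
    report.m0 = m0
    return report
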