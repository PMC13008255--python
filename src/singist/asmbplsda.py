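"""Adaptive sparse multi-block PLS discriminant analysis (asmbPLS-DA).

Multi-block PLS on centered/scaled pseudobulk blocks against a centered/
scaled 0/1 response, with per-block adaptive sparsity: at each component the
block weight vector is soft-thresholded at the lambda_jb quantile of its
absolute entries, so lambda_jb = 0 keeps every gene and lambda_jb = 1 zeroes
the block.  Block scores are scaled by 1/sqrt(block width) so wide blocks do
not dominate the super level.  Deflation of blocks and response is by the
super score.

Because every step is linear in the scaled inputs, the fitted predictor has
an exact accumulated linear coefficient per gene; this is what makes the
additive cell-type/gene score decomposition and the treatment-shift algebra
exact rather than approximate.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from singist.datamodel import DataError, PseudobulkBlocks

logger = logging.getLogger(__name__)


class SingleClassError(DataError):
    """Response contains a single class; the discriminant model is undefined."""


@dataclass
class AsmbPLSDAModel:
    """Fitted asmbPLS-DA: weights, loadings, scalers and accumulated coefficients.

    ``coef[ct]`` is the per-gene accumulated linear coefficient on the
    centered/scaled block input, mapping to the *scaled* response; the
    prediction for sample ``i`` is
    ``y_mean + y_std * sum_b z_ib . coef[b]``.
    """

    cell_types: list[str]
    genes: dict[str, list[str]]
    J: int
    lambdas: np.ndarray                      # (J, B)
    x_mean: dict[str, np.ndarray]
    x_std: dict[str, np.ndarray]
    y_mean: float
    y_std: float
    block_weights: list[dict[str, np.ndarray]]   # per component: ct -> unit/zero vector
    super_weights: np.ndarray                # (J, B), unit rows
    block_loadings: list[dict[str, np.ndarray]]
    q: np.ndarray                            # (J,) response loadings on scaled y
    explained: np.ndarray                    # (J,) response SS captured per component
    coef: dict[str, np.ndarray]
    threshold_mode: str = "soft"

    @property
    def n_blocks(self) -> int:
        return len(self.cell_types)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "cell_types": self.cell_types,
            "genes": self.genes,
            "J": self.J,
            "lambdas": self.lambdas.tolist(),
            "x_mean": {ct: v.tolist() for ct, v in self.x_mean.items()},
            "x_std": {ct: v.tolist() for ct, v in self.x_std.items()},
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "block_weights": [
                {ct: v.tolist() for ct, v in comp.items()} for comp in self.block_weights
            ],
            "super_weights": self.super_weights.tolist(),
            "block_loadings": [
                {ct: v.tolist() for ct, v in comp.items()} for comp in self.block_loadings
            ],
            "q": self.q.tolist(),
            "explained": self.explained.tolist(),
            "coef": {ct: v.tolist() for ct, v in self.coef.items()},
            "threshold_mode": self.threshold_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AsmbPLSDAModel":
        arr = np.asarray
        return cls(
            cell_types=list(d["cell_types"]),
            genes={ct: list(v) for ct, v in d["genes"].items()},
            J=int(d["J"]),
            lambdas=arr(d["lambdas"], dtype=float),
            x_mean={ct: arr(v, dtype=float) for ct, v in d["x_mean"].items()},
            x_std={ct: arr(v, dtype=float) for ct, v in d["x_std"].items()},
            y_mean=float(d["y_mean"]),
            y_std=float(d["y_std"]),
            block_weights=[
                {ct: arr(v, dtype=float) for ct, v in comp.items()}
                for comp in d["block_weights"]
            ],
            super_weights=arr(d["super_weights"], dtype=float),
            block_loadings=[
                {ct: arr(v, dtype=float) for ct, v in comp.items()}
                for comp in d["block_loadings"]
            ],
            q=arr(d["q"], dtype=float),
            explained=arr(d["explained"], dtype=float),
            coef={ct: arr(v, dtype=float) for ct, v in d["coef"].items()},
            threshold_mode=d.get("threshold_mode", "soft"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "AsmbPLSDAModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ScoreDecomposition:
    """Additive decomposition of the predicted score.

    ``y`` is the centered score (prediction minus the ``intercept``, which is
    the training response mean); the identity ``y_i = sum_b gamma_ib =
    sum_b sum_g delta_igb`` holds exactly under this convention, and the
    intercept cancels in every downstream difference of scores.
    """

    y: pd.Series
    intercept: float
    gamma: pd.DataFrame                  # samples x cell types
    delta: dict[str, pd.DataFrame]       # ct -> samples x genes

    @property
    def predicted(self) -> pd.Series:
        """Prediction on the original 0/1 response scale."""
        return self.y + self.intercept


def _normalize_lambdas(lambdas, J: int, B: int) -> np.ndarray:
    lam = np.asarray(lambdas, dtype=float)
    if lam.ndim == 0:
        lam = np.full((J, B), float(lam))
    elif lam.ndim == 1:
        if lam.shape[0] != B:
            raise DataError(f"lambda vector length {lam.shape[0]} != number of blocks {B}")
        lam = np.tile(lam, (J, 1))
    elif lam.shape != (J, B):
        raise DataError(f"lambda array shape {lam.shape} != (J={J}, B={B})")
    if ((lam < 0) | (lam > 1)).any():
        raise DataError("sparsity quantiles must lie in [0, 1]")
    return lam


def _threshold(w: np.ndarray, lam: float, mode: str) -> np.ndarray:
    """Quantile sparsity: zero entries with |w| <= lambda-quantile of |w|.

    lambda = 0 applies no threshold; in "soft" mode survivors are shrunk by
    the threshold before renormalization.
    """
    if lam <= 0:
        return w.copy()
    tau = np.quantile(np.abs(w), lam)
    if mode == "soft":
        out = np.sign(w) * np.maximum(np.abs(w) - tau, 0.0)
    elif mode == "hard":
        out = np.where(np.abs(w) > tau, w, 0.0)
    else:
        raise DataError(f"unknown threshold mode {mode!r}")
    return out


def fit(
    blocks: PseudobulkBlocks,
    y,
    J: int = 1,
    lambdas=0.0,
    threshold_mode: str = "soft",
) -> AsmbPLSDAModel:
    """Fit asmbPLS-DA on pseudobulk blocks against a binary response.

    Parameters
    ----------
    blocks
        Per-cell-type samples-x-genes matrices, shared sample order.
    y
        Binary 0/1 class labels aligned with the block sample order
        (1 = target class; base class is the reference).
    J
        Number of PLS components requested; truncated with a warning if the
        data cannot support them.
    lambdas
        Sparsity quantiles: scalar, per-block vector of length B, or (J, B)
        array.  ``lambda = 1`` removes a block from a component entirely.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n != len(blocks.sample_ids):
        raise DataError(f"{n} labels but {len(blocks.sample_ids)} samples in blocks")
    if n < 2 or len(np.unique(y)) < 2:
        raise SingleClassError("fitting requires samples from both classes")

    cell_types = blocks.cell_types
    B = len(cell_types)
    lam = _normalize_lambdas(lambdas, J, B)

    # center/scale blocks and response; constant columns get unit scale and,
    # being exactly zero after centering, can never acquire weight
    Z: dict[str, np.ndarray] = {}
    x_mean, x_std = {}, {}
    genes = {}
    for ct in cell_types:
        X = blocks.blocks[ct].to_numpy(dtype=float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        Z[ct] = (X - mu) / sd
        x_mean[ct], x_std[ct] = mu, sd
        genes[ct] = list(blocks.blocks[ct].columns)
    y_mean = float(y.mean())
    y_std = float(y.std(ddof=1))
    f = (y - y_mean) / y_std

    inv_sqrt_p = {ct: 1.0 / np.sqrt(Z[ct].shape[1]) for ct in cell_types}

    block_weights: list[dict[str, np.ndarray]] = []
    block_loadings: list[dict[str, np.ndarray]] = []
    super_rows: list[np.ndarray] = []
    qs: list[float] = []
    explained: list[float] = []
    a_vecs: list[np.ndarray] = []     # concat weight directions, for coefficients
    p_vecs: list[np.ndarray] = []     # concat block loadings

    J_fit = 0
    for j in range(J):
        W: dict[str, np.ndarray] = {}
        T = np.zeros((n, B))
        for bi, ct in enumerate(cell_types):
            w = Z[ct].T @ f
            w = _threshold(w, lam[j, bi], threshold_mode)
            nw = np.linalg.norm(w)
            if nw > 0:
                w = w / nw
            W[ct] = w
            T[:, bi] = (Z[ct] @ w) * inv_sqrt_p[ct]
        ws = T.T @ f
        nws = np.linalg.norm(ws)
        if nws < 1e-12:
            logger.warning("component %d carries no signal; truncating J to %d", j + 1, j)
            break
        ws = ws / nws
        t = T @ ws
        tt = float(t @ t)
        if tt < 1e-12:
            logger.warning("degenerate super score at component %d; truncating J to %d",
                           j + 1, j)
            break
        qj = float(f @ t) / tt
        P: dict[str, np.ndarray] = {}
        for ct in cell_types:
            p = Z[ct].T @ t / tt
            P[ct] = p
            Z[ct] = Z[ct] - np.outer(t, p)
        f = f - qj * t

        block_weights.append(W)
        block_loadings.append(P)
        super_rows.append(ws)
        qs.append(qj)
        explained.append(qj * qj * tt)
        a_vecs.append(
            np.concatenate([ws[bi] * W[ct] * inv_sqrt_p[ct]
                            for bi, ct in enumerate(cell_types)])
        )
        p_vecs.append(np.concatenate([P[ct] for ct in cell_types]))
        J_fit += 1

    if J_fit == 0:
        raise DataError(
            "no non-degenerate PLS component could be fitted "
            "(all block weights zero; consider a smaller sparsity quantile)"
        )
    if J_fit < J:
        logger.warning("requested J=%d, fitted J=%d", J, J_fit)

    # accumulated linear coefficients: v_j = a_j - sum_{k<j} v_k (p_k . a_j)
    vs: list[np.ndarray] = []
    for j in range(J_fit):
        v = a_vecs[j].copy()
        for k in range(j):
            v -= vs[k] * float(p_vecs[k] @ a_vecs[j])
        vs.append(v)
    beta = np.zeros_like(vs[0])
    for j in range(J_fit):
        beta += qs[j] * vs[j]
    coef: dict[str, np.ndarray] = {}
    offset = 0
    for ct in cell_types:
        p_ct = len(genes[ct])
        coef[ct] = beta[offset:offset + p_ct]
        offset += p_ct

    return AsmbPLSDAModel(
        cell_types=cell_types,
        genes=genes,
        J=J_fit,
        lambdas=lam[:J_fit],
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        block_weights=block_weights,
        super_weights=np.vstack(super_rows),
        block_loadings=block_loadings,
        q=np.asarray(qs),
        explained=np.asarray(explained),
        coef=coef,
        threshold_mode=threshold_mode,
    )


def _scaled_blocks(model: AsmbPLSDAModel, blocks: PseudobulkBlocks) -> dict[str, np.ndarray]:
    Z = {}
    for ct in model.cell_types:
        if ct not in blocks.blocks:
            raise DataError(f"blocks lack cell type {ct!r} required by the model")
        df = blocks.blocks[ct]
        missing = [g for g in model.genes[ct] if g not in df.columns]
        if missing:
            raise DataError(f"block {ct!r} lacks model genes: {missing[:10]}")
        # canonical layout so identical values give bitwise-identical sums
        X = np.ascontiguousarray(df[model.genes[ct]].to_numpy(dtype=float))
        Z[ct] = (X - model.x_mean[ct]) / model.x_std[ct]
    return Z


def predict(model: AsmbPLSDAModel, blocks: PseudobulkBlocks) -> pd.Series:
    """Predicted continuous response (superpathway score) per sample."""
    Z = _scaled_blocks(model, blocks)
    score = np.zeros(len(blocks.sample_ids))
    for ct in model.cell_types:
        score += Z[ct] @ model.coef[ct]
    return pd.Series(model.y_mean + model.y_std * score, index=blocks.sample_ids, name="y_hat")


def decompose(model: AsmbPLSDAModel, blocks: PseudobulkBlocks) -> ScoreDecomposition:
    """Additive cell-type and gene decomposition of the predicted score.

    ``delta[ct].loc[i, g]`` is gene g's contribution to sample i's score in
    cell type ct; summing genes gives the cell-type contribution gamma, and
    summing cell types gives the centered score.
    """
    Z = _scaled_blocks(model, blocks)
    idx = blocks.sample_ids
    delta = {}
    gamma = {}
    for ct in model.cell_types:
        d = model.y_std * Z[ct] * model.coef[ct][np.newaxis, :]
        delta[ct] = pd.DataFrame(d, index=idx, columns=model.genes[ct])
        gamma[ct] = delta[ct].sum(axis=1)
    gamma_df = pd.DataFrame(gamma)
    y = gamma_df.sum(axis=1)
    y.name = "y_centered"
    return ScoreDecomposition(y=y, intercept=model.y_mean, gamma=gamma_df, delta=delta)


@dataclass
class CVResult:
    """Leave-one-out cross-validation over (J, lambda) candidates."""

    table: pd.DataFrame          # columns: J, lambdas (tuple over blocks), error
    best_J: int
    best_lambdas: np.ndarray     # (best_J, B)
    best_error: float

    @property
    def selected(self) -> dict:
        return {"J": self.best_J, "lambdas": self.best_lambdas, "error": self.best_error}


def _loocv_error(blocks, y, J, lam, threshold_mode) -> float:
    """1 - F1 of leave-one-out class predictions at fixed hyperparameters."""
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    ids = blocks.sample_ids
    preds = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        try:
            m = fit(blocks.subset_samples(ids[keep]), y[keep], J=J, lambdas=lam,
                    threshold_mode=threshold_mode)
            preds[i] = predict(m, blocks.subset_samples(ids[[i]])).iloc[0]
        except SingleClassError:
            preds[i] = float(y[keep].mean())
        except DataError:
            preds[i] = float(y[keep].mean())
    y_cls = (preds >= 0.5).astype(int)
    return 1.0 - f1_score(y.astype(int), y_cls, zero_division=0)


def tune_loocv(
    blocks: PseudobulkBlocks,
    y,
    J_grid=(1, 2, 3),
    lambda_grid=(0.0, 0.25, 0.5, 0.75, 0.9, 0.95, 0.99, 1.0),
    per_block: bool = True,
    threshold_mode: str = "soft",
) -> CVResult:
    """Select the component count and per-block sparsity quantiles by LOOCV F1.

    Candidates are the Cartesian product of ``J_grid`` with per-block lambda
    combinations (``per_block=False`` shares one lambda across blocks);
    lambdas are shared across components.  Ties break toward the smallest J,
    then the sparsest model (largest summed lambda).
    """
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 4:
        raise DataError("LOOCV tuning requires at least 4 samples")
    B = len(blocks.cell_types)
    if not len(J_grid) or not len(lambda_grid):
        raise DataError("empty hyperparameter grid")
    if per_block:
        lam_candidates = [c for c in itertools.product(lambda_grid, repeat=B)]
    else:
        lam_candidates = [(l,) * B for l in lambda_grid]
    # a candidate zeroing every block can never fit; screened out up front
    lam_candidates = [c for c in lam_candidates if any(l < 1 for l in c)]
    if not lam_candidates:
        raise DataError("all lambda candidates zero every block; change the grid")

    rows = []
    any_ok = False
    for J in J_grid:
        for lam in lam_candidates:
            try:
                err = _loocv_error(blocks, y, J, np.asarray(lam), threshold_mode)
                any_ok = True
            except DataError:
                err = np.nan
            rows.append({"J": J, "lambdas": lam, "error": err})
    if not any_ok:
        raise DataError("all (J, lambda) candidates degenerate; change the grid")
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["error"]).copy()
    valid["sum_lam"] = valid["lambdas"].map(sum)
    valid = valid.sort_values(
        ["error", "J", "sum_lam"], ascending=[True, True, False], kind="stable"
    )
    best = valid.iloc[0]
    best_lam = np.tile(np.asarray(best["lambdas"], dtype=float), (int(best["J"]), 1))
    return CVResult(
        table=table,
        best_J=int(best["J"]),
        best_lambdas=best_lam,
        best_error=float(best["error"]),
    )
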