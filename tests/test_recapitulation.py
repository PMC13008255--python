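"""Fold-change gating, in silico treatment and recapitulation measures."""

import numpy as np
import pandas as pd
import pytest

from singist.asmbplsda import decompose, fit
from singist.datamodel import CellTypeMap, OrthologyMap, PseudobulkBlocks
from singist.recapitulation import (
    REASON_NO_ORTHOLOG,
    REASON_NOT_SIGNIFICANT,
    REASON_TOO_FEW_CELLS,
    REASON_UNMAPPED,
    FoldChangeBlocks,
    apply_treatment,
    compute_fold_changes,
    fraction_report,
    predicted_recapitulation,
    reference_recapitulation,
)
from singist.simulate import SimulationConfig, simulate_exact_shift
from tests.conftest import make_blocks, make_sc_data


def _run_chain(ds, J=1, lam=0.0):
    model = fit(ds.blocks, ds.y, J=J, lambdas=lam)
    d = decompose(model, ds.blocks)
    omega, gamma = reference_recapitulation(d, ds.y)
    base = ds.blocks.subset_samples(ds.y.index[ds.y == 0])
    tr = apply_treatment(base, ds.fc, ds.orthology, ds.ctmap)
    omega_p, gamma_p, d_b, d_t = predicted_recapitulation(model, base, tr.blocks)
    return fraction_report(ds.superpathway.pathway_id, omega, omega_p,
                           gamma, gamma_p, d_b, d_t, tr.gating)


# ---------------------------------------------------------------- fold changes

def test_gated_to_zero_when_adjusted_p_above_gate():
    table = pd.DataFrame({"cell_type": ["mTC"], "model_gene": ["Gene1"],
                          "log2FC": [1.7], "adj_p": [0.2]})
    fc = FoldChangeBlocks.from_table(table)
    assert fc.blocks["mTC"].loc["Gene1", "r"] == 0.0
    assert fc.blocks["mTC"].loc["Gene1", "log2FC"] == 1.7


def test_fold_change_log2_ratio_of_geometric_means():
    # target cells counts {3,3}, base {1,1}: log2(4) - log2(2) = 1.0
    import scipy.sparse as sp
    from singist.datamodel import SingleCellData

    data = SingleCellData(
        counts=sp.csr_matrix(np.array([[3, 3, 1, 1]])),
        genes=pd.Index(["Genea"]),
        cells=pd.DataFrame(
            {"sample_id": ["t", "t", "b", "b"], "cell_type": ["A"] * 4},
            index=pd.Index([f"c{i}" for i in range(4)], name="cell_id")),
        samples=pd.Series([1, 0], index=pd.Index(["t", "b"], name="sample_id")),
    )
    fc = compute_fold_changes(data, min_cells_per_class=2)
    assert fc.blocks["A"].loc["Genea", "log2FC"] == pytest.approx(1.0)


def test_identical_expression_gives_zero_fold_change():
    import scipy.sparse as sp
    from singist.datamodel import SingleCellData

    data = SingleCellData(
        counts=sp.csr_matrix(np.array([[2, 2, 2, 2, 2, 2]])),
        genes=pd.Index(["Geneb"]),
        cells=pd.DataFrame(
            {"sample_id": ["t"] * 3 + ["b"] * 3, "cell_type": ["A"] * 6},
            index=pd.Index([f"c{i}" for i in range(6)], name="cell_id")),
        samples=pd.Series([1, 0], index=pd.Index(["t", "b"], name="sample_id")),
    )
    fc = compute_fold_changes(data)
    assert fc.blocks["A"].loc["Geneb", "log2FC"] == 0.0
    assert fc.blocks["A"].loc["Geneb", "r"] == 0.0


def test_too_few_cells_gates_whole_cell_type():
    data = make_sc_data(seed=0, cells_per=2)
    fc = compute_fold_changes(data, min_cells_per_class=3)
    for ct in fc.blocks:
        assert (fc.blocks[ct]["r"] == 0.0).all()
        assert (fc.blocks[ct]["reason"] == REASON_TOO_FEW_CELLS).all()


def test_wilcoxon_gate_on_simulated_signal():
    """Strongly shifted genes pass the BH gate; flat genes do not."""
    from singist.simulate import SimulationConfig, simulate_human

    cfg = SimulationConfig(seed=2, n_per_class=2, cells_per_sample=80,
                           n_genes=20, n_background_genes=30, shift=3.0,
                           dispersion=20.0, signal_genes_per_celltype=4)
    human = simulate_human(cfg)
    fc = compute_fold_changes(human.data)
    sig = set(human.truth["signal_genes"]["TC"])
    block = fc.blocks["TC"]
    assert all(block.loc[g, "r"] != 0.0 for g in sig)
    flat = [g for g in human.truth["pathway_genes"] if g not in sig]
    assert np.mean([block.loc[g, "r"] == 0.0 for g in flat]) > 0.8


# ------------------------------------------------------------------ treatment

def _toy_treatment(r=2.0, adj_p=0.01, mapped=True, ortholog=True):
    ids = pd.Index(["b1", "b2"])
    base = PseudobulkBlocks({"TC": pd.DataFrame([[1.5, 2.0], [1.0, 3.0]],
                                                index=ids, columns=["GA", "GB"])})
    fc = FoldChangeBlocks.from_table(pd.DataFrame({
        "cell_type": ["mTC", "mTC"], "model_gene": ["Ga", "Gb"],
        "log2FC": [r, 0.0], "adj_p": [adj_p, 1.0],
    }))
    orth = OrthologyMap(pd.DataFrame({
        "human_symbol": ["GA", "GB"],
        "model_symbol": ["Ga", "Gb"],
        "one_to_one": [ortholog, True],
    }))
    ctmap = CellTypeMap({"TC": "mTC" if mapped else None})
    return base, fc, orth, ctmap


def test_treatment_adds_fold_change_when_mapped_and_orthologous():
    base, fc, orth, ctmap = _toy_treatment(r=2.0)
    out = apply_treatment(base, fc, orth, ctmap)
    assert out.blocks.blocks["TC"].loc["b1", "GA"] == pytest.approx(3.5)
    assert out.blocks.blocks["TC"].loc["b1", "GB"] == pytest.approx(2.0)  # r=0


def test_treatment_noop_without_one_to_one_ortholog():
    base, fc, orth, ctmap = _toy_treatment(ortholog=False)
    out = apply_treatment(base, fc, orth, ctmap)
    pd.testing.assert_frame_equal(out.blocks.blocks["TC"][["GA"]],
                                  base.blocks["TC"][["GA"]])
    row = out.gating[(out.gating["gene"] == "GA")].iloc[0]
    assert row["reason"] == REASON_NO_ORTHOLOG


def test_treatment_noop_for_unmapped_cell_type():
    base, fc, orth, ctmap = _toy_treatment(mapped=False)
    out = apply_treatment(base, fc, orth, ctmap)
    pd.testing.assert_frame_equal(out.blocks.blocks["TC"], base.blocks["TC"])
    assert (out.gating["reason"] == REASON_UNMAPPED).all()


def test_treatment_noop_when_not_significant():
    base, fc, orth, ctmap = _toy_treatment(adj_p=0.2)
    out = apply_treatment(base, fc, orth, ctmap)
    pd.testing.assert_frame_equal(out.blocks.blocks["TC"], base.blocks["TC"])
    row = out.gating[(out.gating["gene"] == "GA")].iloc[0]
    assert row["reason"] == REASON_NOT_SIGNIFICANT


# ------------------------------------------------------------- recapitulation

def test_reference_recapitulation_median_arithmetic():
    """Matches direct median recomputation on a random fixture."""
    blocks, y = make_blocks(seed=30, shift=2.0)
    model = fit(blocks, y, J=2, lambdas=0.5)
    d = decompose(model, blocks)
    omega, gamma = reference_recapitulation(d, y)
    yv = d.y.to_numpy()
    assert omega == pytest.approx(np.median(yv[y == 1]) - np.median(yv[y == 0]),
                                  abs=1e-12)
    for ct in gamma.index:
        g = d.gamma[ct].to_numpy()
        assert gamma[ct] == pytest.approx(np.median(g[y == 1]) - np.median(g[y == 0]),
                                          abs=1e-12)


def test_identical_classes_flag_degenerate_reference():
    blocks, y = make_blocks(seed=31, shift=1.0)
    model = fit(blocks, y, J=1, lambdas=0.0)
    same = PseudobulkBlocks({
        ct: pd.DataFrame(np.tile(df.iloc[:1].to_numpy(), (len(df), 1)),
                         index=df.index, columns=df.columns)
        for ct, df in blocks.blocks.items()
    })
    d = decompose(model, same)
    omega, gamma = reference_recapitulation(d, y)
    assert omega == 0.0
    rep = fraction_report("p", omega, 0.0, gamma, gamma * 0.0, d, d,
                          pd.DataFrame(columns=["cell_type", "gene", "model_gene",
                                                "r", "reason"]))
    assert rep.degenerate_reference
    assert np.isnan(rep.omega_frac)
    assert not np.isinf(rep.gamma["fraction"].fillna(0)).any()


def test_no_op_treatment_gives_zero_predicted_shift(exact_ds):
    ds = exact_ds
    model = fit(ds.blocks, ds.y, J=1, lambdas=0.0)
    base = ds.blocks.subset_samples(ds.y.index[ds.y == 0])
    omega_p, gamma_p, *_ = predicted_recapitulation(model, base, base)
    assert omega_p == 0.0
    assert (gamma_p == 0.0).all()


def test_single_gene_treatment_matches_linearity_oracle(exact_ds):
    """Treating one gene with fold change r shifts every score by
    y_std * coef_g * r / scale_g exactly."""
    ds = exact_ds
    model = fit(ds.blocks, ds.y, J=1, lambdas=0.0)
    base = ds.blocks.subset_samples(ds.y.index[ds.y == 0])
    gene = model.genes["TC"][0]
    r = 1.7
    treated = base.copy()
    treated.blocks["TC"][gene] += r
    omega_p, gamma_p, *_ = predicted_recapitulation(model, base, treated)
    gi = model.genes["TC"].index(gene)
    oracle = model.y_std * model.coef["TC"][gi] * r / model.x_std["TC"][gi]
    assert omega_p == pytest.approx(oracle, abs=1e-12)
    assert gamma_p["TC"] == pytest.approx(oracle, abs=1e-12)
    assert gamma_p.drop("TC").abs().max() == 0.0


def test_location_shift_recovery_exact(exact_ds, exact_ds_flipped):
    rep = _run_chain(exact_ds, J=2, lam=0.25)
    assert rep.omega_frac == pytest.approx(100.0, abs=1e-8)
    assert np.allclose(rep.gamma["fraction"], 100.0, atol=1e-8)
    rep_neg = _run_chain(exact_ds_flipped, J=2, lam=0.25)
    assert rep_neg.omega_frac == pytest.approx(-100.0, abs=1e-8)


def test_fractions_can_overshoot_100():
    """A model shift larger than the human shift yields fractions over 100."""
    ds = simulate_exact_shift(SimulationConfig(seed=40, shift=1.0))
    doubled = FoldChangeBlocks({
        ct: df.assign(log2FC=df["log2FC"] * 3.0, r=df["r"] * 3.0)
        for ct, df in ds.fc.blocks.items()
    })
    ds2 = type(ds)(blocks=ds.blocks, y=ds.y, superpathway=ds.superpathway,
                   fc=doubled, orthology=ds.orthology, ctmap=ds.ctmap,
                   truth=ds.truth)
    rep = _run_chain(ds2)
    assert rep.omega_frac == pytest.approx(300.0, abs=1e-6)


def test_zero_gating_and_unmapped_cell_type():
    ds = simulate_exact_shift(
        SimulationConfig(seed=41, orthology_coverage=0.6, unmapped_celltypes=("DC",))
    )
    rep = _run_chain(ds)
    # unmapped cell type contributes nothing
    assert rep.gamma.loc["DC", "predicted"] == 0.0
    assert rep.gamma.loc["DC", "fraction"] == pytest.approx(0.0, abs=1e-10)
    # every gene with a gating reason has exactly zero attribution
    reasons = rep.gating.set_index(["cell_type", "gene"])["reason"]
    for ct, dfrac in rep.delta_frac.items():
        for g in dfrac.index:
            if reasons.get((ct, g), "ok") != "ok":
                assert rep.delta[ct].loc[g] == 0.0
                assert dfrac.loc[g] == 0.0 or np.isnan(dfrac.loc[g])


def test_gene_attribution_additivity_and_sample_independence(exact_ds):
    rep = _run_chain(exact_ds, J=2, lam=0.5)
    for ct in rep.delta_frac:
        assert rep.delta_frac[ct].sum() == pytest.approx(
            rep.gamma.loc[ct, "fraction"], abs=1e-8)


def test_coverage_monotonicity_of_recapitulation():
    """Dropping one-to-one orthologs never increases |Omega_f| in the
    location-shift scenario."""
    fracs = []
    for cov in (1.0, 0.8, 0.6, 0.4, 0.2, 0.0):
        ds = simulate_exact_shift(SimulationConfig(seed=42, orthology_coverage=cov))
        rep = _run_chain(ds)
        fracs.append(abs(rep.omega_frac))
    assert all(a >= b - 1e-9 for a, b in zip(fracs, fracs[1:]))
    assert fracs[-1] == pytest.approx(0.0, abs=1e-10)


def test_report_table_round_trip(exact_ds, tmp_path):
    rep = _run_chain(exact_ds)
    frame = rep.to_frame()
    assert set(frame["level"]) == {"superpathway", "cell_type", "gene"}
    frame.to_csv(tmp_path / "rep.tsv", sep="\t", index=False)
    back = pd.read_csv(tmp_path / "rep.tsv", sep="\t")
    assert back.loc[back["level"] == "superpathway", "fraction"].iloc[0] == \
        pytest.approx(rep.omega_frac)
    summary = rep.summary()
    assert summary["omega_frac_pct"] == pytest.approx(100.0)
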