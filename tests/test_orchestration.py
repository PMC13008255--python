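"""End-to-end pipeline runs and the command-line interface."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from singist.cli import main as cli_main
from singist.orchestration import ModelSpec, RunConfig, run_full
from singist.simulate import SimulationConfig, simulate_human, simulate_model


@pytest.fixture(scope="module")
def sim_dir(tmp_path_factory):
    """A simulated dataset on disk, written through the CLI, with an extra
    pure-noise pathway appended to the GMT."""
    outdir = tmp_path_factory.mktemp("sim")
    runner = CliRunner()
    res = runner.invoke(cli_main, ["simulate", "--seed", "3", "--outdir", str(outdir)])
    assert res.exit_code == 0, res.output
    with open(outdir / "pathways.gmt", "a") as fh:
        noise_genes = "\t".join(f"BKG{i:04d}" for i in range(1, 31))
        fh.write(f"NOISE_PATHWAY\tno signal here\t{noise_genes}\n")
    return outdir


def _config(sim_dir, outdir, models=None, seed=5, n_perm=150):
    if models is None:
        models = [ModelSpec(name="simmodel",
                            fc_table=str(sim_dir / "fc_table.tsv"),
                            orthology=str(sim_dir / "orthologs.tsv"),
                            celltype_map=str(sim_dir / "celltype_map.tsv"))]
    return RunConfig(
        seed=seed, outdir=str(outdir),
        human_counts=str(sim_dir / "human.mtx"),
        human_cells_meta=str(sim_dir / "human.cells.tsv"),
        human_genes_meta=str(sim_dir / "human.genes.tsv"),
        human_samples_meta=str(sim_dir / "human.samples.tsv"),
        gmt=str(sim_dir / "pathways.gmt"),
        models=models,
        J_grid=[1], lambda_grid=[0.0, 0.5, 0.9], n_perm=n_perm,
    )


def test_run_full_perfect_mode_headline(sim_dir, tmp_path):
    out = run_full(_config(sim_dir, tmp_path / "out"))
    headline = out["headline"].set_index("pathway")

    sig = headline.loc["SIM_PATHWAY"]
    assert bool(sig["valid"])
    # perfect concordance: recapitulation near 100% (count noise only)
    assert sig["omega_frac_pct"] == pytest.approx(100.0, abs=25.0)

    # a no-signal pathway fails the permutation gate: flagged, fractions
    # suppressed from the headline but its report still written
    noise = headline.loc["NOISE_PATHWAY"]
    assert not bool(noise["valid"])
    assert np.isnan(noise["omega_frac_pct"])
    assert (tmp_path / "out" / "reports" /
            "NOISE_PATHWAY__simmodel.recapitulation.tsv").exists()

    manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
    assert manifest["seed"] == 5 and manifest["n_perm"] == 150


def test_run_full_two_models_independent_reports(sim_dir, tmp_path):
    null_fc = pd.read_csv(sim_dir / "fc_table.tsv", sep="\t")
    null_fc["log2FC"] = 0.0
    null_fc["adj_p"] = 1.0
    null_path = tmp_path / "null_fc.tsv"
    null_fc.to_csv(null_path, sep="\t", index=False)
    models = [
        ModelSpec(name="concordant", fc_table=str(sim_dir / "fc_table.tsv"),
                  orthology=str(sim_dir / "orthologs.tsv"),
                  celltype_map=str(sim_dir / "celltype_map.tsv")),
        ModelSpec(name="nullmodel", fc_table=str(null_path),
                  orthology=str(sim_dir / "orthologs.tsv"),
                  celltype_map=str(sim_dir / "celltype_map.tsv")),
    ]
    out = run_full(_config(sim_dir, tmp_path / "out", models=models))
    results = {(r.pathway_id, r.model_name): r for r in out["results"]}
    assert ("SIM_PATHWAY", "concordant") in results
    assert ("SIM_PATHWAY", "nullmodel") in results
    # the null model induces no shift at all
    assert results[("SIM_PATHWAY", "nullmodel")].report.omega_pred == 0.0
    assert results[("SIM_PATHWAY", "concordant")].report.omega_pred != 0.0


def test_run_full_reproducible_under_seed(sim_dir, tmp_path):
    cfg1 = _config(sim_dir, tmp_path / "o1", n_perm=50)
    cfg2 = _config(sim_dir, tmp_path / "o2", n_perm=50)
    h1 = run_full(cfg1)["headline"].drop(columns=["valid"])
    h2 = run_full(cfg2)["headline"].drop(columns=["valid"])
    pd.testing.assert_frame_equal(h1, h2)


def test_run_full_with_model_counts_input(tmp_path):
    """Disease model given as raw counts: fold changes computed internally."""
    from singist.io import write_counts

    cfg_h = SimulationConfig(seed=21, n_per_class=3, cells_per_sample=50,
                             n_genes=20, n_background_genes=60, shift=2.5,
                             dispersion=20.0, signal_genes_per_celltype=5)
    human = simulate_human(cfg_h)
    model_sim = simulate_model(cfg_h, human)

    # the "disease model" is a second count simulation sharing the human
    # generative truth (same seed selects the same signal genes and base
    # means) but with independent count noise from its different cell count,
    # relabelled to model symbols and model cell types
    cfg_m = SimulationConfig(seed=21, n_per_class=3, cells_per_sample=80,
                             n_genes=20, n_background_genes=60, shift=2.5,
                             dispersion=20.0, signal_genes_per_celltype=5)
    mouse = simulate_human(cfg_m)
    mouse.data.genes = pd.Index([g.capitalize() for g in mouse.data.genes])
    mouse.data.cells["cell_type"] = "m" + mouse.data.cells["cell_type"]

    sim = tmp_path / "data"
    write_counts(human.data, sim, prefix="human")
    write_counts(mouse.data, sim, prefix="mouse")
    (sim / "pathways.gmt").write_text(
        "SIM_PATHWAY\tdesc\t" + "\t".join(human.truth["pathway_genes"]) + "\n")
    model_sim.orthology.records.astype({"one_to_one": int}).to_csv(
        sim / "orthologs.tsv", sep="\t", index=False)
    pd.DataFrame([
        {"human_cell_type": h, "model_cell_type": m or "ABSENT"}
        for h, m in model_sim.ctmap.mapping.items()
    ]).to_csv(sim / "ctmap.tsv", sep="\t", index=False)

    cfg = RunConfig(
        seed=9, outdir=str(tmp_path / "out"),
        human_counts=str(sim / "human.mtx"),
        human_cells_meta=str(sim / "human.cells.tsv"),
        human_genes_meta=str(sim / "human.genes.tsv"),
        human_samples_meta=str(sim / "human.samples.tsv"),
        gmt=str(sim / "pathways.gmt"),
        models=[ModelSpec(name="mouse", counts=str(sim / "mouse.mtx"),
                          cells_meta=str(sim / "mouse.cells.tsv"),
                          genes_meta=str(sim / "mouse.genes.tsv"),
                          samples_meta=str(sim / "mouse.samples.tsv"),
                          orthology=str(sim / "orthologs.tsv"),
                          celltype_map=str(sim / "ctmap.tsv"))],
        J_grid=[1], lambda_grid=[0.0, 0.5], n_perm=60, min_cells=5,
    )
    out = run_full(cfg)
    rep = out["results"][0].report
    # same generative truth in both species: substantial positive agreement
    assert rep.omega_frac > 25.0


def test_cli_full_stage_pipeline(sim_dir, tmp_path):
    """train -> validate -> treat -> report through the CLI."""
    runner = CliRunner()
    data_opts = [
        "--counts", str(sim_dir / "human.mtx"),
        "--cells", str(sim_dir / "human.cells.tsv"),
        "--genes", str(sim_dir / "human.genes.tsv"),
        "--samples", str(sim_dir / "human.samples.tsv"),
        "--gmt", str(sim_dir / "pathways.gmt"),
        "--pathway", "SIM_PATHWAY",
    ]
    model_path = tmp_path / "model.json"
    res = runner.invoke(cli_main, ["train", *data_opts, "--model-out",
                                   str(model_path), "--j-grid", "1",
                                   "--lambda-grid", "0,0.5"])
    assert res.exit_code == 0, res.output
    assert model_path.exists()

    res = runner.invoke(cli_main, ["validate", *data_opts, "--model",
                                   str(model_path), "--n-perm", "50",
                                   "--seed", "4", "--out",
                                   str(tmp_path / "valid.tsv")])
    assert res.exit_code == 0, res.output

    res = runner.invoke(cli_main, [
        "treat", *data_opts,
        "--fc-table", str(sim_dir / "fc_table.tsv"),
        "--orthologs", str(sim_dir / "orthologs.tsv"),
        "--celltype-map", str(sim_dir / "celltype_map.tsv"),
        "--treated-out", str(tmp_path / "treated.json"),
        "--gating-out", str(tmp_path / "gating.tsv"),
    ])
    assert res.exit_code == 0, res.output

    res = runner.invoke(cli_main, [
        "report", *data_opts, "--model", str(model_path),
        "--treated", str(tmp_path / "treated.json"),
        "--gating", str(tmp_path / "gating.tsv"),
        "--out", str(tmp_path / "report.tsv"),
    ])
    assert res.exit_code == 0, res.output
    rep = pd.read_csv(tmp_path / "report.tsv", sep="\t")
    omega_f = rep.loc[rep["level"] == "superpathway", "fraction"].iloc[0]
    assert omega_f == pytest.approx(100.0, abs=25.0)
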