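"""Rendering invariants, the end-to-end workflow and the CLI."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import frapkit as fk
from frapkit.cli import main
from frapkit.render import render_timeseries


@pytest.fixture(scope="module")
def frozen_render():
    kin = dataclasses.replace(
        fk.default_kinetics(2000), rate_matrix=np.zeros((3, 3)), initial_state="CHROM"
    )
    geo = fk.default_geometry()
    img = dataclasses.replace(fk.default_imaging(), n_frames=20, noise_model="none")
    traj = fk.simulate_molecules(kin, geo, img.duration() + 0.1, seed=0)
    return fk.render_timeseries(traj, geo, img, seed=1), kin, geo, img, traj


class TestRender:
    def test_frozen_noise_free_frames_identical(self, frozen_render):
        rendered, *_ = frozen_render
        data = rendered.timeseries.data
        assert np.allclose(data, data[0])

    def test_integrated_intensity_equals_gain_times_count(self, frozen_render):
        rendered, kin, geo, img, traj = frozen_render
        total = rendered.timeseries.data[0].sum()
        assert np.isclose(total, img.gain * kin.n_molecules, rtol=1e-6)

    def test_seed_determinism(self, frozen_render):
        _, kin, geo, img, traj = frozen_render
        a = fk.render_timeseries(traj, geo, img, seed=3)
        b = fk.render_timeseries(traj, geo, img, seed=3)
        assert np.array_equal(a.timeseries.data, b.timeseries.data)
        assert np.array_equal(a.prestack.data, b.prestack.data)

    def test_drift_attenuates_single_plane_not_stack(self):
        # out-of-plane drift: the single-plane final/initial focus ratio
        # falls below the drift-invariant z-stack ratio
        kin = fk.default_kinetics(20000)
        geo = fk.default_geometry()
        img = dataclasses.replace(
            fk.default_imaging(), z_drift_sigma=0.3, z_drift_tau=3.0, noise_model="none"
        )
        exp = fk.simulate_frap_experiment(kin, geo, img, seed=4, bleach=False)
        trace = fk.extract_trace(exp.rendered.timeseries, exp.locus_roi())
        plane_ratio = trace.raw[-15:].mean() / trace.raw[:10].mean()
        pre = exp.rendered.prestack.data[:, :, :].sum()
        post = exp.rendered.poststack.data[:, :, :].sum()
        assert plane_ratio < 0.9  # locus wandered out of the plane
        assert abs(post / pre - 1.0) < 0.02  # stack sum unaffected

    def test_grid_smaller_than_nucleus_rejected(self, frozen_render):
        _, kin, geo, img, traj = frozen_render
        small = dataclasses.replace(img, fov=1.0)
        with pytest.raises(ValueError, match="nucleus"):
            fk.render_timeseries(traj, geo, small, seed=0)


class TestWorkflow:
    def test_ground_truth_sidesteps(self, small_experiment):
        gt = small_experiment.truth
        assert 0.4 < gt.expected_t_half < 0.6
        assert gt.mobile_fraction == 1.0
        assert 0.8 < gt.occupancies["CHROM"] < 0.95

    def test_recovered_halftime_close_to_truth(self, small_experiment):
        th = fk.recovered_halftime_ms(small_experiment)
        truth = 1000 * small_experiment.truth.expected_t_half
        assert abs(th - truth) / truth < 0.5  # single noisy replicate

    def test_averaged_traces_fit_close_to_meanfield_truth(self):
        kin = fk.default_kinetics(10000)
        geo, img = fk.default_geometry(), fk.default_imaging()
        trs = []
        for s in range(8):
            exp = fk.simulate_frap_experiment(kin, geo, img, seed=210 + s)
            trs.append(fk.analyze_trace(exp))
        mean = fk.average_traces(trs)
        post = mean[mean["time"] >= 0]
        fit = fk.fit_one_component(post["time"].to_numpy(), post["mean"].to_numpy())
        truth_ms = 1000 * fk.simulate_frap_experiment(
            kin, geo, img, seed=0, bleach=False
        ).truth.expected_t_half
        assert abs(fk.halftime_from_curve(fit) - truth_ms) / truth_ms < 0.15


class TestConfigIO:
    def test_yaml_roundtrip(self, tmp_path):
        kin, geo, img = fk.default_kinetics(), fk.default_geometry(), fk.default_imaging()
        fk.save_config(tmp_path / "c.yaml", kin, geo, img)
        k2, g2, i2 = fk.load_config(tmp_path / "c.yaml")
        assert np.allclose(k2.rate_matrix, kin.rate_matrix)
        assert k2.focus_weights == kin.focus_weights
        assert g2.foci == geo.foci
        assert i2 == img

    def test_json_roundtrip(self, tmp_path):
        kin, geo, img = fk.default_kinetics(), fk.default_geometry(), fk.default_imaging()
        fk.save_config(tmp_path / "c.json", kin, geo, img)
        k2, _, _ = fk.load_config(tmp_path / "c.json")
        assert np.allclose(k2.rate_matrix, kin.rate_matrix)


class TestCli:
    def test_simulate_extract_normalize_fit_roundtrip(self, tmp_path):
        runner = CliRunner()
        kin = fk.default_kinetics(3000)
        fk.save_config(
            tmp_path / "c.yaml", kin, fk.default_geometry(), fk.default_imaging()
        )
        out = tmp_path / "sim"
        r = runner.invoke(
            main,
            ["simulate", "frap", "--config", str(tmp_path / "c.yaml"),
             "--out", str(out), "--seed", "5"],
        )
        assert r.exit_code == 0, r.output
        assert (out / "timeseries.tif").exists()
        assert (out / "ground_truth.json").exists()

        r = runner.invoke(
            main,
            ["extract", "--stack", str(out / "timeseries.tif"),
             "--rois", str(out / "rois.json"), "--out", str(tmp_path / "traces.csv")],
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            main,
            ["normalize", "--traces", str(tmp_path / "traces.csv"),
             "--out", str(tmp_path / "norm.csv")],
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            main,
            ["fit", "--traces", str(tmp_path / "norm.csv"), "--model", "auto",
             "--out", str(tmp_path / "fits.json")],
        )
        assert r.exit_code == 0, r.output
        fits = json.loads((tmp_path / "fits.json").read_text())
        entry = next(iter(fits["fits"].values()))
        assert entry["t_half_ms"] > 0
        assert 0 <= entry["r_squared"] <= 1

    def test_fraction_command(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sim"
        fk.save_config(
            tmp_path / "c.yaml",
            fk.default_kinetics(5000),
            fk.default_geometry(),
            fk.default_imaging(),
        )
        runner.invoke(
            main,
            ["simulate", "frap", "--config", str(tmp_path / "c.yaml"),
             "--out", str(out), "--seed", "6"],
        )
        r = runner.invoke(
            main,
            ["fraction", "--stack", str(out / "timeseries.tif"),
             "--pre", str(out / "pre.tif"), "--post", str(out / "post.tif"),
             "--rois", str(out / "rois.json"), "--out", str(tmp_path / "fm.json")],
        )
        assert r.exit_code == 0, r.output
        fm = json.loads((tmp_path / "fm.json").read_text())
        assert 0.8 < fm["mobile_fraction"] < 1.2

    def test_report_command(self, tmp_path):
        rng = np.random.default_rng(0)
        rows = []
        for phase, n in (("G1", 10), ("G2", 12)):
            for i in range(n):
                rows.append(
                    dict(experiment_id=f"{phase}{i}", condition="wt", phase=phase,
                         time_min=float(i), t_half_ms=float(rng.normal(500, 100)),
                         f_m=1.0)
                )
        pd.DataFrame(rows).to_csv(tmp_path / "records.csv", index=False)
        r = CliRunner().invoke(
            main,
            ["report", "--records", str(tmp_path / "records.csv"),
             "--out", str(tmp_path / "rep.json")],
        )
        assert r.exit_code == 0, r.output
        rep = json.loads((tmp_path / "rep.json").read_text())
        assert "G1-G2" in rep["tests"]

    def test_linescan_simulate_and_analyze(self, tmp_path):
        runner = CliRunner()
        kin = fk.reaction_dominant_kinetics(10.0, n_molecules=30000)
        img = dataclasses.replace(fk.default_imaging(), linescan_n_samples=800)
        fk.save_config(tmp_path / "c.yaml", kin, fk.reaction_dominant_geometry(), img)
        out = tmp_path / "ls"
        r = runner.invoke(
            main,
            ["simulate", "linescan", "--config", str(tmp_path / "c.yaml"),
             "--out", str(out), "--seed", "7"],
        )
        assert r.exit_code == 0, r.output
        meta = json.loads((out / "linescan.json").read_text())
        df = pd.read_csv(out / "linescan.csv")
        frap_csv = tmp_path / "frap.csv"
        ctrl_csv = tmp_path / "ctrl.csv"
        df[df.series_id == "frap"].to_csv(frap_csv, index=False)
        df[df.series_id == "ctrl"].to_csv(ctrl_csv, index=False)
        r = runner.invoke(
            main,
            ["linescan", "--frap", str(frap_csv), "--ctrl", str(ctrl_csv),
             "--bleach-interval", *map(str, meta["bleach_interval"]),
             "--bleach-time", str(meta["bleach_time_s"]),
             "--out", str(tmp_path / "ls.json")],
        )
        assert r.exit_code == 0, r.output
        th = json.loads((tmp_path / "ls.json").read_text())["t_half_ms"]
        assert 30 < th < 150


def test_plotting_smoke(tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    from frapkit.plotting import plot_box_summaries, plot_recovery

    t = np.arange(0, 7.2, 0.06)
    fit = fk.fit_one_component(t, 1 - np.exp(-1.3 * t))
    ax = plot_recovery(fit)
    assert ax is not None
    s = fk.summarize_group([1.0, 2.0, 3.0, 4.0])
    ax = plot_box_summaries({"wt": s})
    assert ax is not None
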