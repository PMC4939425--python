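import numpy as np
import pandas as pd
import pytest

from nrlangevin import (DimerParams, ExperimentConfig, alpha_sweep,
                        constant_J_drift, dimer_experiment,
                        dimer_initial_configuration, dimer_J,
                        make_dimer, make_gaussian, make_observable,
                        make_observable_quadratic, make_warped_gaussian,
                        mh_comparison, mse_sweep, reference_mean)
from nrlangevin.cli import main as cli_main

ROT2 = np.array([[0.0, -1.0], [1.0, 0.0]])


@pytest.fixture
def small_config():
    return ExperimentConfig(dt=0.01, n_steps=3000, n_replicas=80,
                            burn_in=500, master_seed=7)


class TestReferenceMean:
    def test_known_mean_short_circuit(self, gaussian2d):
        obs = make_observable("c", lambda x: x[..., 0], known_mean=0.0)
        assert reference_mean(gaussian2d, obs) == 0.0

    def test_gaussian_second_moment_by_quadrature(self, gaussian2d):
        obs = make_observable("abs2", lambda x: float(np.sum(x * x)))
        assert reference_mean(gaussian2d, obs, half_width=10.0) == \
            pytest.approx(2.0, abs=1e-9)

    def test_torus_observable_matches_grid_sum(self, periodic):
        obs = make_observable(
            "f", lambda x: 1.0 + 4.0 * np.sin(4 * np.pi * x[..., 0]) ** 2
            + 4.0 * np.cos(4 * np.pi * x[..., 1]) ** 2)
        val = reference_mean(periodic, obs)
        g = (np.arange(400) + 0.5) / 400
        xx, yy = np.meshgrid(g, g)
        pts = np.stack([xx, yy], axis=-1)
        w = np.exp(periodic.log_density(pts))
        grid = float((obs(pts) * w).sum() / w.sum())
        assert val == pytest.approx(grid, abs=1e-6)


class TestAlphaSweep:
    def test_tracks_closed_form(self, gaussian2d, rotation_field,
                                small_config):
        obs = make_observable_quadratic(np.diag([2.0, 0.0]), k=0.0)
        df = alpha_sweep(gaussian2d, rotation_field, obs,
                         alpha_grid=[0.0, 3.0], config=small_config)
        assert list(df["alpha"]) == [0.0, 3.0]
        # variance reduction visible and in the right direction
        assert df["sigma2"].iloc[1] < df["sigma2"].iloc[0]
        assert (df["n_diverged"] == 0).all()

    def test_reproducible_bit_for_bit(self, gaussian2d, rotation_field,
                                      small_config):
        obs = make_observable_quadratic(np.diag([2.0, 0.0]), k=0.0)
        df1 = alpha_sweep(gaussian2d, rotation_field, obs, [0.0, 2.0],
                          small_config)
        df2 = alpha_sweep(gaussian2d, rotation_field, obs, [0.0, 2.0],
                          small_config)
        pd.testing.assert_frame_equal(df1, df2)

    def test_single_replica_rejected(self, gaussian2d, rotation_field):
        obs = make_observable("f", lambda x: x[..., 0])
        cfg = ExperimentConfig(n_replicas=1)
        with pytest.raises(ValueError):
            alpha_sweep(gaussian2d, rotation_field, obs, [0.0], cfg)

    def test_empty_grid_rejected(self, gaussian2d, rotation_field):
        obs = make_observable("f", lambda x: x[..., 0])
        with pytest.raises(ValueError):
            alpha_sweep(gaussian2d, rotation_field, obs, [])

    def test_csv_written(self, tmp_path, gaussian2d, rotation_field):
        obs = make_observable("f", lambda x: x[..., 0])
        cfg = ExperimentConfig(dt=0.02, n_steps=500, n_replicas=10,
                               burn_in=100, out=str(tmp_path / "sweep.csv"))
        alpha_sweep(gaussian2d, rotation_field, obs, [0.0], cfg)
        back = pd.read_csv(tmp_path / "sweep.csv")
        assert {"alpha", "estimate", "sigma2", "ci_low", "ci_high",
                "n_diverged"} <= set(back.columns)


class TestWarpedGaussianSweep:
    def test_nonreversible_reduces_variance(self):
        """Scaled-down warped-Gaussian study: an order-of-magnitude drop in
        σ̂² from α = 0 to α = 10 (the slow coordinate has relaxation time
        ≈ 50, so the horizon must be several multiples of that)."""
        t = make_warped_gaussian(0.05)
        field = constant_J_drift(ROT2, t)
        obs = make_observable("abs2", lambda x: np.sum(x * x, axis=-1))
        cfg = ExperimentConfig(dt=2e-3, n_steps=250_000, n_replicas=60,
                               burn_in=50_000, master_seed=3)
        df = alpha_sweep(t, field, obs, [0.0, 10.0], cfg)
        assert df["sigma2"].iloc[1] < 0.1 * df["sigma2"].iloc[0]


class TestMHComparison:
    def test_acceptance_decreases_and_mh_variance_increases(self):
        """Metropolising the nonreversible proposal negates its benefit:
        the acceptance rate drops with α and σ̂² grows instead of
        shrinking (fast-mixing Gaussian target, f = 2x₁²)."""
        t = make_gaussian(2)
        field = constant_J_drift(ROT2, t)
        obs = make_observable_quadratic(np.diag([2.0, 0.0]), k=0.0)
        cfg = ExperimentConfig(dt=0.01, n_steps=6000, n_replicas=50,
                               burn_in=1000, master_seed=5)
        df = mh_comparison(t, field, obs, [0.0, 10.0], cfg)
        mh = df[df.scheme == "mh-nonrev"].set_index("alpha")
        assert mh.loc[10.0, "acceptance_rate"] < mh.loc[0.0, "acceptance_rate"]
        assert mh.loc[10.0, "sigma2"] > 1.5 * mh.loc[0.0, "sigma2"]
        # at α = 0 the MH variant is plain reversible MALA: unbiased mean
        assert mh.loc[0.0, "bias"] == pytest.approx(0.0, abs=0.2)


class TestMSESweep:
    def test_u_shape_at_fixed_budget(self):
        """EM on the 1-D OU: MSE in Δt is U-shaped (bias–variance tradeoff)."""
        t = make_gaussian(1)
        obs = make_observable("x2", lambda x: x[..., 0] ** 2, known_mean=1.0)
        dts = [0.004, 0.1, 0.9]
        df = mse_sweep(t, None, obs, reference=1.0, dt_grid=dts,
                       schemes=("em",), budget=30_000, n_replicas=24,
                       master_seed=11, relative=False)
        m = df.set_index("dt")["mse"]
        assert m[0.1] < m[0.004]   # small Δt: sampling error dominates
        assert m[0.1] < m[0.9]     # large Δt: discretisation bias dominates

    def test_budget_equalisation(self):
        t = make_gaussian(2)
        field = constant_J_drift(ROT2, t)
        obs = make_observable("abs2", lambda x: np.sum(x * x, axis=-1),
                              known_mean=2.0)
        df = mse_sweep(t, field, obs, reference=2.0, dt_grid=[0.05],
                       schemes=("em", "splitting"), alpha_grid=[2.0],
                       budget=6000, n_replicas=4, master_seed=1,
                       relative=False)
        steps = df.set_index("scheme")["n_steps"]
        assert steps["em"] == 6000
        assert steps["splitting"] == 1000

    def test_diverged_cells_reported(self):
        t = make_warped_gaussian(0.05)
        field = constant_J_drift(ROT2, t)
        obs = make_observable("abs2", lambda x: np.sum(x * x, axis=-1))
        df = mse_sweep(t, field, obs, reference=50.0, dt_grid=[0.25],
                       schemes=("em",), alpha_grid=[40.0], budget=4000,
                       n_replicas=6, master_seed=2, relative=False)
        assert df["diverged_fraction"].iloc[0] == 1.0
        assert np.isnan(df["mse"].iloc[0])


class TestDimer:
    def test_initial_configuration_is_valid(self, dimer_params):
        t = make_dimer(dimer_params)
        q = dimer_initial_configuration(dimer_params)
        assert t.potential(q) < 1e-6  # lattice start is essentially unstrained

    def test_corner_rotation_leaves_solvent_drift_unchanged(self,
                                                            dimer_params):
        t = make_dimer(dimer_params)
        J2 = dimer_J(dimer_params.n_particles, "corner_rotation")
        field = constant_J_drift(J2, t)
        q = dimer_initial_configuration(dimer_params)
        gamma = field(q)
        np.testing.assert_allclose(gamma[4:], 0.0, atol=1e-12)

    def test_short_run_batch_means(self, tmp_path, dimer_params):
        xyz = tmp_path / "final.xyz"
        ve = dimer_experiment(dimer_params, "block_circulant", alpha=0.0,
                              dt=5e-4, n_steps=6000, burn_in=1000, seed=4,
                              n_batches=10, xyz_path=str(xyz))
        assert ve.method == "batch_means"
        assert ve.ci_low <= ve.estimate <= ve.ci_high
        assert ve.sigma2 >= 0.0
        assert xyz.exists()

    def test_perturbed_run_completes(self, dimer_params):
        ve = dimer_experiment(dimer_params, "corner_rotation", alpha=4.0,
                              dt=5e-5, n_steps=6000, burn_in=1000, seed=4,
                              n_batches=8)
        assert np.isfinite(ve.estimate)


class TestCLI:
    def test_gauss_theory_subcommand(self, tmp_path):
        jfile = tmp_path / "J.txt"
        mfile = tmp_path / "M.txt"
        np.savetxt(jfile, ROT2)
        np.savetxt(mfile, np.diag([2.0, 0.0]))
        out = tmp_path / "theory.csv"
        rc = cli_main(["gauss-theory", "--J", str(jfile), "--M", str(mfile),
                       "--alpha-grid", "0:3:4", "--out", str(out)])
        assert rc == 0
        df = pd.read_csv(out)
        np.testing.assert_allclose(
            df["sigma2"], 4 * (1 + 1 / (1 + df["alpha"] ** 2)), atol=1e-9)

    def test_sample_subcommand(self, tmp_path):
        out = tmp_path / "series.txt"
        rc = cli_main(["sample", "--target", "gaussian", "--dim", "2",
                       "--observable", "abs2", "--scheme", "mala",
                       "--dt", "0.1", "--steps", "500", "--seed", "1",
                       "--out", str(out)])
        assert rc == 0
        series = np.loadtxt(out)
        assert series.shape == (500,)

    def test_alpha_sweep_subcommand(self, tmp_path):
        out = tmp_path / "sweep.csv"
        rc = cli_main(["alpha-sweep", "--target", "gaussian", "--dim", "2",
                       "--observable", "2x1sq", "--dt", "0.02",
                       "--steps", "800", "--replicas", "12",
                       "--burn-in", "100", "--alpha-grid", "0:4:2",
                       "--seed", "9", "--out", str(out)])
        assert rc == 0
        assert len(pd.read_csv(out)) == 2
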