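"""Brownian engine: stationarity, determinism, pulling limits, solvent frames."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from glueforce.landscape import LandscapeModel, stationary_density
from glueforce.simulate import (
    EquilibriumConfig,
    PullingProtocol,
    RestraintSpec,
    UnstableIntegrationWarning,
    approach_to_start,
    equilibrium_distance_stats,
    generate_work_ensemble,
    run_equilibration,
    run_pull,
    sample_solvent_frames,
)


class TestEquilibration:
    def test_zero_temperature_stays_at_minimum(self, model):
        cfg = EquilibriumConfig(duration=0.05, frame_interval=0.001, temperature=0.0)
        eq = run_equilibration(
            model.with_shielding(1.0), RestraintSpec(), cfg, x0=model.eq_distance
        )
        assert np.allclose(eq.distance, model.eq_distance, atol=1e-6)

    def test_restraint_restores_from_outside_window(self, model):
        # started at 4.5 Å with T = 0, the flat-bottom restraint drives the
        # bond back inside the 2.5--3.5 Å window
        cfg = EquilibriumConfig(duration=0.2, frame_interval=0.002, temperature=0.0)
        eq = run_equilibration(model.with_shielding(1.0), RestraintSpec(), cfg, x0=4.5)
        assert eq.distance[0] < 4.5  # immediate inward drift
        assert eq.final_distance <= 3.5 + 1e-3

    def test_long_run_matches_boltzmann_quadrature(self, model):
        # frozen occupancy (full shielding): the stationary law is exactly
        # Boltzmann in U0 + restraint; compare histograms by total variation
        restraint = RestraintSpec()
        cfg = EquilibriumConfig(duration=20.0, frame_interval=0.002, seed=7)
        eq = run_equilibration(model.with_shielding(1.0), restraint, cfg)
        edges = np.arange(2.3, 3.8001, 0.05)
        counts, _ = np.histogram(eq.distance, bins=edges)
        emp = counts / counts.sum()
        x = np.linspace(2.0, 4.2, 4001)
        p = stationary_density(
            model, x, n=0, extra_potential=restraint.energy, temperature=cfg.temperature
        )
        theo = np.empty(edges.size - 1)
        for i in range(theo.size):
            mask = (x >= edges[i]) & (x < edges[i + 1])
            theo[i] = np.trapezoid(p[mask], x[mask])
        theo /= theo.sum()
        tv = 0.5 * np.abs(emp - theo).sum()
        assert tv < 0.05

    def test_fixed_seed_is_bit_reproducible(self, model):
        cfg = EquilibriumConfig(duration=0.5, frame_interval=0.01, seed=3)
        a = run_equilibration(model, RestraintSpec(), cfg)
        b = run_equilibration(model, RestraintSpec(), cfg)
        assert np.array_equal(a.distance, b.distance)
        assert np.array_equal(a.occupancy, b.occupancy)

    def test_oversized_time_step_flagged_unstable(self, model):
        cfg = EquilibriumConfig(duration=0.01, frame_interval=0.01, time_step=5e-3)
        with pytest.warns(UnstableIntegrationWarning):
            run_equilibration(model.with_shielding(1.0), RestraintSpec(), cfg, x0=4.5)


class TestPull:
    def test_flat_landscape_zero_temperature_gives_zero_work(self):
        # free particle tracking the guide: only the vanishing friction work
        flat = LandscapeModel(well_depth=1e-9, shielding=1.0)
        protocol = PullingProtocol(temperature=0.0, seed=1)
        wp = run_pull(flat, protocol)
        assert abs(wp.work[-1]) < 0.05
        assert not wp.lag_warning

    def test_slow_zero_temperature_pull_recovers_energy_difference(self, model):
        # deterministic-integration oracle: at T -> 0 and slow rate the work
        # equals the total-energy difference between the guide endpoints
        frozen = model.with_shielding(1.0)
        protocol = PullingProtocol(temperature=0.0, rate=0.1, seed=1)

        def total_energy(lam):
            res = minimize_scalar(
                lambda x: float(frozen.bond_potential(x))
                + 0.5 * protocol.spring_k * (x - lam) ** 2,
                bounds=(1.5, 7.0),
                method="bounded",
            )
            return res.fun

        expected = total_energy(5.0) - total_energy(2.5)
        wp = run_pull(frozen, protocol)
        assert wp.work[-1] == pytest.approx(expected, abs=0.02)

    def test_work_profile_contract(self, model, shielded_ensemble):
        grid = shielded_ensemble.grid
        assert grid[0] == pytest.approx(2.5)
        assert grid[-1] == pytest.approx(5.0)
        assert grid.size == 5001
        assert np.all(shielded_ensemble.works[:, 0] == 0.0)

    def test_fixed_seed_pull_identical(self, model, fast_protocol):
        a = run_pull(model.with_shielding(1.0), fast_protocol, seed=9)
        b = run_pull(model.with_shielding(1.0), fast_protocol, seed=9)
        assert np.array_equal(a.work, b.work)

    def test_start_distance_precondition(self, model, fast_protocol):
        with pytest.raises(ValueError, match="0.1"):
            run_pull(model, fast_protocol, x0=3.0)

    def test_soft_spring_raises_lag_flag(self, model):
        soft = PullingProtocol(spring_k=5.0, rate=2.5, temperature=0.0, seed=1)
        wp = run_pull(model.with_shielding(1.0), soft)
        assert wp.lag_warning


class TestEnsemble:
    def test_same_seed_identical_ensembles(self, model):
        protocol = PullingProtocol(rate=2.5, n_traj=2, seed=55)
        a = generate_work_ensemble(model, protocol)
        b = generate_work_ensemble(model, protocol)
        assert np.array_equal(a.works, b.works)

    def test_ensemble_composes_the_three_stages(self, model):
        # trajectory 0 of an ensemble reproduces manual stage chaining
        protocol = PullingProtocol(rate=2.5, n_traj=1, seed=77)
        ens = generate_work_ensemble(model, protocol, stage1_ns=2.0)
        cfg = EquilibriumConfig(
            duration=2.0, frame_interval=2.0, temperature=protocol.temperature
        )
        eq = run_equilibration(model, RestraintSpec(), cfg, seed=77)
        x2, n2 = approach_to_start(
            model, protocol, eq.final_distance, eq.final_occupancy, seed=78
        )
        manual = run_pull(model, protocol, x0=x2, n0=n2, seed=79)
        assert np.array_equal(ens.works[0], manual.work)

    def test_shielding_raises_mean_rupture_work(
        self, shielded_ensemble, unshielded_ensemble
    ):
        # paired simulation: blocking water entry makes rupture strictly
        # more expensive on average
        w_sh = shielded_ensemble.works[:, -1].mean()
        w_un = unshielded_ensemble.works[:, -1].mean()
        assert w_sh > w_un


class TestSolventFrames:
    def test_no_exclusion_matches_uniform_shell_counts(self):
        frames = sample_solvent_frames(n_frames=200, box_radius=10.0, seed=5)
        rho = sum(len(s) for s in frames.solvent) / (
            frames.n_frames * 4.0 / 3.0 * np.pi * frames.box_radius**3
        )
        # closed-form expected count in [r, r+dr] with 3-sigma Poisson band
        for r in (2.0, 4.0, 6.0):
            dr = 0.5
            shell = 4.0 / 3.0 * np.pi * ((r + dr) ** 3 - r**3)
            expected = rho * shell * frames.n_frames
            observed = sum(
                np.count_nonzero(
                    (np.linalg.norm(s, axis=1) >= r)
                    & (np.linalg.norm(s, axis=1) < r + dr)
                )
                for s in frames.solvent
            )
            assert abs(observed - expected) < 3 * np.sqrt(expected)

    def test_full_exclusion_empties_the_zone(self):
        frames = sample_solvent_frames(
            n_frames=50, box_radius=10.0, exclusion_radius=5.0, exclusion_prob=1.0,
            seed=6,
        )
        for s in frames.solvent:
            assert np.all(np.linalg.norm(s, axis=1) >= 5.0)

    def test_box_smaller_than_exclusion_rejected(self):
        with pytest.raises(ValueError):
            sample_solvent_frames(n_frames=1, box_radius=4.0, exclusion_radius=5.0)


class TestDistanceStats:
    def test_constant_series_has_zero_std(self):
        stats = equilibrium_distance_stats(np.full(100, 2.9))
        assert stats.std == 0.0
        assert stats.mean == pytest.approx(2.9)

    def test_known_normal_generator_recovered(self):
        rng = np.random.default_rng(11)
        series = rng.normal(2.9, 0.2, size=20000)
        stats = equilibrium_distance_stats(series)
        assert stats.mean == pytest.approx(2.9, abs=3 * 0.2 / np.sqrt(20000))
        assert stats.std == pytest.approx(0.2, rel=0.05)

    def test_shielded_distribution_is_narrower(self, model):
        # qualitative equilibrium claim: the glue stiffens the H-bond
        cfg = EquilibriumConfig(duration=20.0, frame_interval=0.002, seed=21)
        sh = run_equilibration(model.with_shielding(1.0), RestraintSpec(), cfg)
        un = run_equilibration(model.with_shielding(0.0), RestraintSpec(), cfg)
        assert (
            equilibrium_distance_stats(sh.distance).std
            < equilibrium_distance_stats(un.distance).std
        )

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_distance_stats(np.array([]))
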