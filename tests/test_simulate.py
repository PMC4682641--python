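"""Stochastic simulator: stationary behaviour, conservation, bleaching."""

import dataclasses

import numpy as np
import pytest

import frapkit as fk
from frapkit.config import CHROM, FREE, RNA, KineticConfig
from frapkit.meanfield import BleachSpec, meanfield_recovery
from frapkit.simulate import augmented_generator, sphere_intersection_volume


def two_state(k_on, k_off, n=2000, weights=(0.5, 0.5), **kw):
    Q = np.zeros((3, 3))
    Q[FREE, CHROM] = k_on
    Q[CHROM, FREE] = k_off
    return KineticConfig(n_molecules=n, rate_matrix=Q, focus_weights=weights, **kw)


@pytest.fixture(scope="module")
def geometry():
    return fk.default_geometry()


class TestStationaryOccupancy:
    def test_symmetric_two_state_occupancy_is_half(self, geometry):
        cfg = two_state(2.0, 2.0, n=4000, weights=(1 / 3,) * 3)
        traj = fk.simulate_molecules(cfg, geometry, 30.0, seed=0)
        counts = traj.state_counts([20.0, 25.0, 30.0])
        chrom = counts[:, 2:].sum(axis=1) / 4000
        assert np.all(np.abs(chrom - 0.5) < 3 * np.sqrt(0.25 / 4000))

    def test_three_state_cycle_matches_nullspace_oracle(self, geometry):
        # oracle: stationary distribution from the balance equations,
        # solved by brute-force linear algebra on the collapsed 3-state chain
        k1, k2, k3 = 3.0, 1.5, 5.0
        Q3 = np.array([[-k1, k1, 0.0], [0.0, -k2, k2], [k3, 0.0, -k3]])
        ns = np.linalg.svd(Q3.T)[2][-1]
        pi_oracle = np.abs(ns) / np.abs(ns).sum()

        Q = np.zeros((3, 3))
        Q[FREE, CHROM], Q[CHROM, RNA], Q[RNA, FREE] = k1, k2, k3
        cfg = KineticConfig(10000, Q, focus_weights=(1 / 3,) * 3)
        traj = fk.simulate_molecules(cfg, geometry, 12.0, seed=1)
        counts = traj.state_counts([12.0])[0]
        occ = np.array([counts[0], counts[2:].sum(), counts[1]]) / 10000
        se = np.sqrt(pi_oracle * (1 - pi_oracle) / 10000)
        assert np.all(np.abs(occ - pi_oracle) < 3 * se)

    def test_frozen_system_counts_constant(self, geometry):
        cfg = KineticConfig(
            500, np.zeros((3, 3)), focus_weights=(1 / 3,) * 3, initial_state="CHROM"
        )
        traj = fk.simulate_molecules(cfg, geometry, 5.0, seed=2)
        counts = traj.state_counts([0.0, 1.0, 2.5, 5.0])
        assert len(traj.event_times) == 0
        assert np.all(counts == counts[0])
        assert counts[0, 2:].sum() == 500

    def test_frozen_without_initial_state_rejected(self, geometry):
        cfg = KineticConfig(10, np.zeros((3, 3)), focus_weights=(1 / 3,) * 3)
        with pytest.raises(ValueError, match="initial_state"):
            fk.simulate_molecules(cfg, geometry, 1.0, seed=0)

    def test_negative_rate_rejected(self):
        Q = np.zeros((3, 3))
        Q[0, 1] = -1.0
        with pytest.raises(ValueError, match="rates"):
            KineticConfig(10, Q, focus_weights=(1 / 3,) * 3)


class TestConservationAndDeterminism:
    def test_state_counts_always_sum_to_n(self, geometry):
        cfg = fk.default_kinetics(3000)
        traj = fk.simulate_molecules(cfg, geometry, 6.0, seed=3)
        probe = np.sort(np.r_[traj.event_times[::37], [0.0, 3.0, 6.0]])
        counts = traj.state_counts(probe)
        assert np.all(counts.sum(axis=1) == 3000)

    def test_identical_seed_bit_identical(self, geometry):
        cfg = fk.default_kinetics(800)
        a = fk.simulate_molecules(cfg, geometry, 4.0, seed=7)
        b = fk.simulate_molecules(cfg, geometry, 4.0, seed=7)
        assert np.array_equal(a.event_times, b.event_times)
        assert np.array_equal(a.event_mol, b.event_mol)
        assert np.array_equal(a.initial_states, b.initial_states)

    def test_fluorescent_count_non_increasing(self, geometry):
        cfg = fk.default_kinetics(3000)
        img = dataclasses.replace(fk.default_imaging(), bleach_center=geometry.foci[0][0])
        traj = fk.simulate_molecules(cfg, geometry, 6.0, seed=4)
        traj = fk.apply_bleach(traj, geometry, img, 2.0, cfg, seed=5)
        total = traj.total_fluorescent(np.linspace(0, 6, 40))
        assert np.all(np.diff(total) <= 0)
        assert total[0] == 3000 and total[-1] < 3000


class TestApplyBleach:
    def test_whole_nucleus_full_efficiency_bleaches_everything(self, geometry):
        cfg = fk.default_kinetics(1000)
        img = dataclasses.replace(
            fk.default_imaging(),
            bleach_center=(0.0, 0.0, 0.0),
            bleach_radius=2 * geometry.nucleus_radius,
        )
        traj = fk.simulate_molecules(cfg, geometry, 2.0, seed=6)
        traj = fk.apply_bleach(traj, geometry, img, 1.0, cfg, seed=7)
        assert traj.fluorescent.sum() == 0

    def test_focus_share_of_fluorescence_lost(self, geometry):
        # pool negligible: loss ~ bleached focus's share of the bound population
        cfg = dataclasses.replace(
            fk.default_kinetics(20000),
            rate_matrix=two_state(200.0, 1.0).rate_matrix,
            focus_weights=(1 / 3, 1 / 3, 1 / 3),
        )
        img = dataclasses.replace(fk.default_imaging(), bleach_center=geometry.foci[0][0])
        traj = fk.simulate_molecules(cfg, geometry, 2.0, seed=8)
        traj = fk.apply_bleach(traj, geometry, img, 1.0, cfg, seed=9)
        loss = 1.0 - traj.fluorescent.mean()
        share = 1.0 / 3.0  # equal weights, pool ~0.5%
        assert abs(loss - share) < 0.02

    def test_default_single_focus_loss_in_20_35_percent_band(self, geometry):
        cfg = fk.default_kinetics(20000)
        img = dataclasses.replace(fk.default_imaging(), bleach_center=geometry.foci[0][0])
        traj = fk.simulate_molecules(cfg, geometry, 2.0, seed=10)
        traj = fk.apply_bleach(traj, geometry, img, 1.0, cfg, seed=11)
        loss = 1.0 - traj.fluorescent.mean()
        assert 0.20 <= loss <= 0.35

    def test_bleach_outside_nucleus_rejected(self, geometry):
        cfg = fk.default_kinetics(100)
        img = dataclasses.replace(fk.default_imaging(), bleach_center=(5.0, 0.0, 0.0))
        traj = fk.simulate_molecules(cfg, geometry, 1.0, seed=0)
        with pytest.raises(ValueError, match="outside"):
            fk.apply_bleach(traj, geometry, img, 0.5, cfg)


class TestMeanfield:
    def test_two_state_large_pool_closed_form(self, geometry):
        # k_off = ln 2 and a vanishing bound fraction: value 0.5 at t = 1 s
        cfg = two_state(np.log(2) / 200.0, np.log(2), weights=(1.0 / 3,) * 3)
        bleach = BleachSpec(center=geometry.foci[0][0], radius=0.3, duration=0.0)
        mf = meanfield_recovery(cfg, geometry, bleach, [1.0])
        assert abs(mf.normalized[0] - 0.5) < 0.01

    def test_matches_fine_step_integration_oracle(self, geometry):
        cfg = fk.default_kinetics(1000)
        bleach = BleachSpec(center=geometry.foci[0][0], radius=0.3)
        times = np.linspace(0.05, 5.0, 25)
        mf = meanfield_recovery(cfg, geometry, bleach, times, focus=0)

        # oracle: explicit RK4 integration of dp/dt = Q^T p at fine steps
        from frapkit.meanfield import _post_bleach_distribution
        from frapkit.simulate import stationary_distribution

        Q = augmented_generator(cfg, geometry.n_foci)
        pi = stationary_distribution(Q)
        f0, _ = _post_bleach_distribution(cfg, geometry, bleach, Q, pi)
        QT = Q.T

        def rk4(p, t_end, dt=1e-4):
            t = 0.0
            while t < t_end - 1e-12:
                h = min(dt, t_end - t)
                k1 = QT @ p
                k2 = QT @ (p + 0.5 * h * k1)
                k3 = QT @ (p + 0.5 * h * k2)
                k4 = QT @ (p + h * k3)
                p = p + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
                t += h
            return p

        oracle = np.array([rk4(f0, max(t - bleach.duration, 0.0))[2] for t in times])
        assert np.max(np.abs(mf.fraction - oracle)) < 1e-6

    def test_stochastic_mean_agrees_within_three_se(self, geometry):
        cfg = fk.default_kinetics(10000)
        img = dataclasses.replace(fk.default_imaging(), bleach_center=geometry.foci[0][0])
        bleach = BleachSpec.from_imaging(img, cfg)
        traj = fk.simulate_molecules(cfg, geometry, 8.0, seed=12)
        traj = fk.apply_bleach(traj, geometry, img, 0.57, cfg, seed=13)
        times = np.linspace(0.05, 7.0, 30)
        mf = meanfield_recovery(cfg, geometry, bleach, times, focus=0)
        obs = traj.fluorescent_counts(0.57 + times)[:, 2] / 10000
        se = np.sqrt(mf.fraction * (1 - mf.fraction) / 10000)
        assert np.all(np.abs(obs - mf.fraction) <= 3 * se)

    def test_flip_coupling_lowers_other_foci(self, geometry):
        # bleaching one focus must strictly lower the expected asymptote
        # of every other focus (shared pool dilution)
        cfg = fk.default_kinetics(1000)
        bleach = BleachSpec(center=geometry.foci[0][0], radius=0.3)
        for other in (1, 2):
            mf = meanfield_recovery(cfg, geometry, bleach, [30.0], focus=other)
            assert mf.fraction[0] < mf.prebleach * 0.999

    def test_ground_truth_mobile_fraction(self, geometry):
        cfg = dataclasses.replace(fk.default_kinetics(1000), immobile_fraction=0.3)
        bleach = BleachSpec(center=geometry.foci[0][0], radius=0.3)
        gt = fk.ground_truth(cfg, geometry, bleach, focus=0)
        # mobile share of the bleached focus's steady-state signal
        assert 0.0 < gt.mobile_fraction < 1.0
        assert abs(sum(gt.occupancies.values()) - 1.0) < 1e-9


def test_sphere_intersection_volume_limits():
    full = 4 / 3 * np.pi
    assert sphere_intersection_volume(1.0, 1.0, 3.0) == 0.0
    assert np.isclose(sphere_intersection_volume(1.0, 0.3, 0.0), 4 / 3 * np.pi * 0.027)
    assert np.isclose(sphere_intersection_volume(1.0, 5.0, 0.1), full)
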