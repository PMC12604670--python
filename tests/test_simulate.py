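"""Langevin engine: potentials, thermostat, stiffness and observables."""

import numpy as np
import pytest

from kdnatools import network as net
from kdnatools import simulate as sim

from conftest import make_free_ring


def dimer_state(r=0.97):
    return sim.SimState(
        positions=np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]),
        velocities=np.zeros((2, 3)),
        bonds=np.array([[0, 1]], dtype=np.int64),
        angles=np.zeros((0, 3), dtype=np.int64))


@pytest.fixture(scope="session")
def ring_run():
    """Equilibrated isolated semiflexible ring with tangent correlations."""
    state = make_free_ring(n_beads=100)
    params = sim.SimParams(seed=11)
    sim.step(state, params, 50_000)
    corr = np.zeros(12)
    temps = []
    n_samples = 120
    for k in range(n_samples):
        sim.step(state, sim.SimParams(seed=100 + k), 2_000)
        temps.append(state.kinetic_temp)
        tang = state.positions[(np.arange(100) + 1) % 100] - state.positions
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        for s in range(12):
            corr[s] += np.mean(np.einsum("ij,ij->i", tang,
                                         np.roll(tang, -s, axis=0)))
    return corr / n_samples, np.mean(temps), state


class TestPotentials:
    def test_fene_matches_closed_form(self):
        state = dimer_state(r=0.97)
        params = sim.SimParams(wca_epsilon=0.0, bend_kappa=0.0)
        expected = -0.5 * 30.0 * 1.5 ** 2 * np.log(1 - (0.97 / 1.5) ** 2)
        assert sim.potential_energy(state, params)["fene"] == \
            pytest.approx(expected, abs=1e-12)

    def test_fene_diverges_near_r0(self):
        params = sim.SimParams(wca_epsilon=0.0, bend_kappa=0.0)
        # logarithmic divergence: -K R0²/2 · ln(2δ) as r → R0(1-δ)
        e6 = sim.potential_energy(dimer_state(r=1.5 * (1 - 1e-6)), params)["fene"]
        e12 = sim.potential_energy(dimer_state(r=1.5 * (1 - 1e-12)), params)["fene"]
        assert e6 == pytest.approx(-0.5 * 30 * 1.5 ** 2 * np.log(2e-6), rel=1e-5)
        e_eq = sim.potential_energy(dimer_state(0.97), params)["fene"]
        assert e12 > e6 > 10 * e_eq

    def test_fene_overstretched_is_error(self):
        state = dimer_state(r=1.6)
        with pytest.raises(ValueError, match="R0"):
            sim.potential_energy(state, sim.SimParams())

    def test_straight_trimer_zero_bending(self):
        state = sim.SimState(
            positions=np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float),
            velocities=np.zeros((3, 3)),
            bonds=np.array([[0, 1], [1, 2]], dtype=np.int64),
            angles=np.array([[0, 1, 2]], dtype=np.int64))
        e = sim.potential_energy(state, sim.SimParams())
        assert e["bend"] == pytest.approx(0.0, abs=1e-14)

    def test_wca_zero_beyond_cutoff(self):
        state = dimer_state(r=1.3)
        params = sim.SimParams(fene_k=0.0, bend_kappa=0.0)
        assert sim.potential_energy(state, params)["wca"] == pytest.approx(0.0)


class TestThermostat:
    def test_free_bead_equipartition(self):
        state = sim.SimState(positions=np.zeros((1, 3)),
                             velocities=np.zeros((1, 3)),
                             bonds=np.zeros((0, 2), dtype=np.int64),
                             angles=np.zeros((0, 3), dtype=np.int64))
        # stronger coupling decorrelates velocities fast enough for a 2%
        # statistical resolution within 10⁶ steps
        params = sim.SimParams(seed=5, gamma=5.0)
        sim.step(state, params, 1_000_000)
        # <v²>/2 per DOF = T/2, from the half-step velocity statistic
        assert state.kinetic_temp == pytest.approx(1.0, rel=0.02)

    def test_interacting_ring_temperature(self, ring_run):
        _, temp, _ = ring_run
        assert temp == pytest.approx(1.0, rel=0.02)

    def test_dissipative_limit_relaxes_monotonically(self):
        state = make_free_ring(n_beads=30)
        rng = np.random.default_rng(0)
        state.positions += rng.normal(0, 0.05, state.positions.shape)
        params = sim.SimParams(temperature=0.0, gamma=5.0, seed=1)
        energies = [sim.potential_energy(state, params)["total"]]
        for _ in range(6):
            sim.step(state, params, 2000)
            energies.append(sim.potential_energy(state, params)["total"])
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_bitwise_deterministic(self):
        runs = []
        for _ in range(2):
            state = make_free_ring(n_beads=20)
            sim.step(state, sim.SimParams(seed=9), 2000)
            runs.append(state.positions.copy())
        assert np.array_equal(runs[0], runs[1])


class TestPersistenceLength:
    def test_tangent_correlation_decay_matches_lp(self, ring_run):
        """Tangent correlations of an isolated semiflexible ring decay with
        the calibrated persistence length of 4σ ± 15%."""
        corr, _, state = ring_run
        bond = np.linalg.norm(
            state.positions[1:6] - state.positions[0:5], axis=1).mean()
        s = np.arange(12) * bond
        slope = np.polyfit(s[1:9], np.log(corr[1:9]), 1)[0]
        assert -1 / slope == pytest.approx(4.0, rel=0.15)


class TestRunProtocol:
    def test_gaussian_rg_series_passes_95pc_rule(self):
        rng = np.random.default_rng(0)
        report = sim.EquilibrationReport.from_series(rng.normal(10, 1, 20000))
        assert report.frac_within_2sd == pytest.approx(0.954, abs=0.01)
        assert report.passed

    def test_drifting_series_fails(self):
        rng = np.random.default_rng(1)
        series = rng.normal(10, 1, 5000) + np.linspace(0, 10, 5000)
        assert not sim.EquilibrationReport.from_series(series).passed

    def test_small_network_protocol_runs_and_conserves(self):
        mo = net.build_mo(n_rings=6, seed=3)
        params = sim.SimParams(seed=4, equil_steps=10_000, prod_steps=30_000,
                               dump_every=1_000)
        traj, report = sim.run_protocol(mo, params)   # verifies topology
        assert traj.n_frames == 30
        assert report.rg_series.shape == (30,)
        assert report.sd >= 0


class TestObservables:
    def test_rg_of_square(self):
        pos = np.array([[0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]], float)
        assert sim.radius_of_gyration(pos) == pytest.approx(2 / np.sqrt(2))

    def test_rigid_motion_removed_by_alignment(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(30, 3))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = ref @ R.T + [1.0, -2.0, 0.5]
        aligned = sim.align_to_reference(moved, ref)
        assert np.allclose(aligned, ref, atol=1e-10)

    def test_reflection_rejected(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(20, 3))
        mirrored = ref * [1, 1, -1]
        with pytest.raises(sim.AlignmentError):
            sim.align_to_reference(mirrored, ref)

    def test_collinear_falls_back_to_translation(self):
        line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.warns(UserWarning, match="degenerate"):
            aligned = sim.align_to_reference(line + [5, 5, 5], line)
        assert np.allclose(aligned, line)

    def test_observables_and_ring_msd(self):
        mo = net.build_mo(n_rings=4, seed=6)
        frame0 = mo.coords.copy()
        theta = 0.3
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        frame1 = frame0 @ R.T + [3, 0, 0]
        traj = sim.Trajectory(times=np.array([0.0, 1.0]),
                              positions=np.stack([frame0, frame1]))
        obs = sim.observables(traj, mo)
        assert np.allclose(obs.ring_com_aligned[1], obs.ring_com_aligned[0],
                           atol=1e-9)
        curve = sim.ring_msd(obs.ring_com_aligned, 1.0)
        assert curve.values[1] == pytest.approx(0.0, abs=1e-16)

    def test_dump_files_written(self, tmp_path):
        mo = net.build_mo(n_rings=2, seed=1)
        state = sim.SimState.from_network(mo, seed=0)
        sim.relax(state, sim.SimParams())
        traj = sim.run(state, sim.SimParams(seed=2), 2000, dump_every=500)
        xyz = tmp_path / "t.xyz"
        dump = tmp_path / "t.dump"
        traj.write_xyz(xyz)
        traj.write_lammps_dump(dump)
        assert xyz.read_text().count("t=") == traj.n_frames
        assert dump.read_text().count("ITEM: TIMESTEP") == traj.n_frames
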