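"""DPD engine: elementary force laws, integration, thermostat, barostat."""

import math

import numpy as np
import pytest

from dpdsurf import (
    Simulation,
    SimulationConfig,
    SystemState,
    assemble,
    build_cnem,
    measure,
)
from dpdsurf import _kernels
from dpdsurf.engine import angle_energy_force, bond_energy_force, pair_interaction
from dpdsurf.errors import ParameterError
from dpdsurf.fixtures import FixtureSpec, generate
from dpdsurf.topology import WATER, box_edge_for_density, random_initial_state


# ---------------------------------------------------------------------------
# elementary interaction laws
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "r, A, R, energy, force",
    [
        (1.2, 25.0, 1.0, 0.0, 0.0),  # beyond cutoff
        (0.5, 25.0, 1.0, 3.125, 12.5),
        (0.0, 25.0, 1.0, 12.5, 25.0),  # finite at contact
    ],
)
def test_soft_repulsion_convention(r, A, R, energy, force):
    e, f = pair_interaction(r, A, R)
    assert e == pytest.approx(energy) and f == pytest.approx(force)


def test_soft_repulsion_is_consistent_gradient():
    # -dU/dr must equal the force everywhere inside the cutoff
    for r in np.linspace(0.05, 0.95, 10):
        h = 1e-7
        e1, _ = pair_interaction(r - h, 25.0, 1.0)
        e2, f = pair_interaction(r + h, 25.0, 1.0)
        assert (e1 - e2) / (2 * h) == pytest.approx(f, rel=1e-5)


def test_bond_energy_as_printed():
    e0, f0 = bond_energy_force(0.39, 150.0, 0.39)
    assert e0 == 0.0 and f0 == 0.0
    e, f = bond_energy_force(0.45, 150.0, 0.39)
    assert e == pytest.approx(0.54)
    assert f < 0  # stretched bond pulls inward


def test_angle_energy_at_straight_geometry():
    e, _ = angle_energy_force(math.pi, 15.0, math.radians(132.0))
    assert e == pytest.approx(5.263, abs=2e-3)
    e0, g0 = angle_energy_force(math.radians(132.0), 15.0, math.radians(132.0))
    assert e0 == 0.0 and g0 == 0.0


def test_angle_kernel_forces_conserve_momentum_and_torque():
    rng = np.random.default_rng(3)
    box = np.array([50.0, 50.0, 50.0])
    for _ in range(20):
        pos = 10.0 + rng.random((3, 3)) * 2.0
        f = np.zeros((3, 3))
        angles = np.array([[0, 1, 2]], dtype=np.int64)
        _, pe = _kernels.angle_forces(
            pos, box, angles, np.array([15.0]), np.array([math.radians(132.0)]), f
        )
        assert np.allclose(f.sum(axis=0), 0, atol=1e-12)
        torque = np.cross(pos - pos[1], f).sum(axis=0)
        assert np.allclose(torque, 0, atol=1e-10)
        assert pe >= 0


def test_angle_kernel_matches_finite_difference():
    rng = np.random.default_rng(11)
    box = np.array([50.0, 50.0, 50.0])
    pos = 10.0 + rng.random((3, 3)) * 1.5
    angles = np.array([[0, 1, 2]], dtype=np.int64)
    ka, t0 = np.array([15.0]), np.array([math.radians(132.0)])
    f = np.zeros((3, 3))
    _kernels.angle_forces(pos, box, angles, ka, t0, f)
    h = 1e-6
    for bead in range(3):
        for dim in range(3):
            pp, pm = pos.copy(), pos.copy()
            pp[bead, dim] += h
            pm[bead, dim] -= h
            _, ep = _kernels.angle_forces(pp, box, angles, ka, t0, np.zeros((3, 3)))
            _, em = _kernels.angle_forces(pm, box, angles, ka, t0, np.zeros((3, 3)))
            assert f[bead, dim] == pytest.approx(-(ep - em) / (2 * h), abs=1e-4)


def test_collinear_angle_geometry_is_finite():
    pos = np.array([[1.0, 5.0, 5.0], [2.0, 5.0, 5.0], [3.0, 5.0, 5.0]])
    f = np.zeros((3, 3))
    box = np.array([10.0, 10.0, 10.0])
    _, pe = _kernels.angle_forces(
        pos, box, np.array([[0, 1, 2]], dtype=np.int64),
        np.array([15.0]), np.array([math.radians(132.0)]), f,
    )
    assert np.isfinite(f).all() and np.isfinite(pe)


# ---------------------------------------------------------------------------
# neighbour search
# ---------------------------------------------------------------------------

def _brute_conservative(pos, box, types, A, R):
    n = len(pos)
    f = np.zeros((n, 3))
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            d -= box * np.rint(d / box)
            r = np.linalg.norm(d)
            Rij = R[types[i], types[j]]
            if 0 < r < Rij:
                fmag = A[types[i], types[j]] * (1 - r / Rij)
                f[i] += fmag * d / r
                f[j] -= fmag * d / r
    return f


@pytest.mark.parametrize("n_beads", [100, 160])
def test_cell_list_forces_match_all_pairs_oracle(ff, n_beads):
    # 100 beads -> small box exercises the O(n^2) fallback; 160 beads at
    # rho=3 fits 3+ cells per axis and exercises the linked-cell path
    rng = np.random.default_rng(n_beads)
    L = box_edge_for_density(n_beads, 3.0)
    box = np.array([L, L, L])
    pos = rng.random((n_beads, 3)) * L
    types = rng.integers(0, 5, n_beads)
    A, R = ff.pair_tables()
    cap = n_beads * 60
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    ex, ey, ez, pr = (np.empty(cap) for _ in range(4))
    npairs = _kernels.build_pair_list(pos, box, 1.116, pi, pj, ex, ey, ez, pr)
    assert npairs > 0
    f = np.zeros((n_beads, 3))
    _kernels.conservative_random_forces(
        npairs, pi, pj, ex, ey, ez, pr, types, A, R, 0.0, 1.116, 10.0, 0, 0,
        False, f,
    )
    f_ref = _brute_conservative(pos, box, types, A, R)
    assert np.allclose(f, f_ref, atol=1e-10)


def test_pair_list_has_no_duplicates(ff):
    rng = np.random.default_rng(5)
    n = 200
    L = box_edge_for_density(n, 3.0)
    box = np.array([L, L, L])
    pos = rng.random((n, 3)) * L
    cap = n * 60
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    ex, ey, ez, pr = (np.empty(cap) for _ in range(4))
    npairs = _kernels.build_pair_list(pos, box, 1.116, pi, pj, ex, ey, ez, pr)
    keys = {(min(a, b), max(a, b)) for a, b in zip(pi[:npairs], pj[:npairs])}
    assert len(keys) == npairs


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def test_free_bead_moves_ballistically(ff):
    top = assemble([(WATER, 1)], ff)
    st = SystemState(
        box=np.array([10.0, 10.0, 10.0]),
        positions=np.array([[5.0, 5.0, 5.0]]),
        velocities=np.array([[0.3, -0.2, 0.1]]),
        types=top.bead_types.copy(),
        molecule_ids=top.molecule_ids.copy(),
    )
    sim = Simulation(st, top, ff, SimulationConfig(thermostat=False,
                                                   disable_nonbonded=True))
    for _ in range(100):
        sim.step()
    assert np.allclose(st.velocities, [[0.3, -0.2, 0.1]])
    assert np.allclose(st.positions, [[5.3, 4.8, 5.1]], atol=1e-10)


def test_momentum_is_conserved_during_dynamics(ff):
    spec = FixtureSpec("pure_water", seed=9, params=(("n_beads", 300),))
    st, top = generate(spec, ff)
    sim = Simulation(st, top, ff, SimulationConfig(seed=9))
    sim.run(500)
    drift = np.abs(st.velocities.sum(axis=0)).max() / st.n_beads
    assert drift < 1e-9


def test_thermostat_holds_unit_temperature(ff):
    spec = FixtureSpec("pure_water", seed=4, params=(("n_beads", 500),))
    st, top = generate(spec, ff)
    sim = Simulation(st, top, ff, SimulationConfig(seed=4))
    df = sim.run(6000, sample_every=20)
    obs = measure(df, equilibration=10.0)
    assert obs.kinetic_temperature == pytest.approx(1.0, abs=0.02)


def test_ideal_gas_pressure(ff):
    # A=0, no bonds: P = rho kT = 3.0 in reduced units
    spec = FixtureSpec("pure_water", seed=6, params=(("n_beads", 600),))
    st, top = generate(spec, ff)
    sim = Simulation(st, top, ff, SimulationConfig(seed=6, disable_nonbonded=True))
    df = sim.run(3000, sample_every=20)
    obs = measure(df, equilibration=10.0)
    assert obs.pressure == pytest.approx(3.0, abs=0.05)


def test_npt_water_relaxes_to_reference_density(ff):
    spec = FixtureSpec("pure_water", seed=2, params=(("n_beads", 1000),))
    st, top = generate(spec, ff)
    sim = Simulation(st, top, ff, SimulationConfig(seed=2, ensemble="npt",
                                                   pressure=23.7))
    df = sim.run(12000, sample_every=50)
    tail = df[df["time"] >= 60.0]
    assert tail["density"].mean() == pytest.approx(3.0, abs=0.02)
    assert tail["volume"].std() > 0  # the piston genuinely fluctuates


def test_run_reproducible_for_same_seed(ff):
    results = []
    for _ in range(2):
        spec = FixtureSpec("pure_water", seed=3, params=(("n_beads", 200),))
        st, top = generate(spec, ff)
        sim = Simulation(st, top, ff, SimulationConfig(seed=3))
        sim.run(200)
        results.append(st.positions.copy())
    assert np.array_equal(results[0], results[1])


def test_measure_rejects_empty_window(ff):
    import pandas as pd

    with pytest.raises(ParameterError):
        measure(pd.DataFrame())


def test_bond_length_sampling_labels(ff):
    tpl = build_cnem(8, 4)
    top = assemble([(tpl, 10)], ff)
    st = random_initial_state(top, 6.0, seed=0)
    sim = Simulation(st, top, ff, SimulationConfig(seed=0))
    df = sim.run(50, sample_every=10)
    assert "bond_CH2CH2-CH2CH2" in df.columns
    assert "bond_CH2OCH2-CH2OCH2" in df.columns
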