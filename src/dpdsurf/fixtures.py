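"""Seeded generators for synthetic configurations.

These realize the ideal limits of the mesophase taxonomy (flat lamellae,
hexagonally packed cylinders, spherical micelles on an FCC lattice or at
random positions) plus the small reference systems used to verify the
engine (pure water, melts, bonded pair/trimer in a thermostat bath), so
every analysis routine is testable without running long dynamics.  The
same spec + seed always yields the identical configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import SystemState
from .errors import ParameterError
from .forcefield import ForceField
from .topology import (
    MoleculeTemplate,
    Topology,
    WATER,
    assemble,
    box_edge_for_density,
    build_cnem,
    build_solute,
    random_initial_state,
)

FIXTURE_KINDS = (
    "pure_water", "melt", "random_mixture", "ideal_lamellar",
    "ideal_hexagonal", "micellar_random", "micellar_fcc",
    "demixed_biphasic", "bonded_pair", "bonded_trimer",
)


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    seed: int = 0
    params: tuple = ()  # extra (key, value) pairs, kept hashable

    def opt(self, key, default=None):
        return dict(self.params).get(key, default)


def generate(spec: FixtureSpec, ff: ForceField) -> tuple[SystemState, Topology]:
    """Dispatch on ``spec.kind``; returns (state, topology)."""
    if spec.kind not in FIXTURE_KINDS:
        raise ParameterError(f"unknown fixture kind {spec.kind!r}")
    return _BUILDERS[spec.kind](spec, ff)


# ---------------------------------------------------------------------------
# homogeneous systems
# ---------------------------------------------------------------------------

def _pure_water(spec: FixtureSpec, ff: ForceField):
    n = int(spec.opt("n_beads", 3000))
    rho = float(spec.opt("density", 3.0))
    top = assemble({WATER: n}, ff)
    st = random_initial_state(top, box_edge_for_density(n, rho), seed=spec.seed)
    return st, top


def _melt(spec: FixtureSpec, ff: ForceField):
    n_c = int(spec.opt("n", 12))
    m_e = int(spec.opt("m", 6))
    n_mol = int(spec.opt("n_molecules", 250))
    rho = float(spec.opt("density", 3.0))
    tpl = build_cnem(n_c, m_e)
    top = assemble({tpl: n_mol}, ff)
    st = random_initial_state(top, box_edge_for_density(top.n_beads, rho), seed=spec.seed)
    return st, top


def _random_mixture(spec: FixtureSpec, ff: ForceField):
    from .topology import compose_box

    n_c = int(spec.opt("n", 12))
    m_e = int(spec.opt("m", 6))
    wt = float(spec.opt("wt_pct", 50.0))
    total = int(spec.opt("total_beads", 6000))
    rho = float(spec.opt("density", 3.0))
    tpl = build_cnem(n_c, m_e)
    comp = compose_box(tpl, wt, total_beads=total)
    top = assemble([(tpl, comp.n_surfactant), (WATER, comp.n_water_beads)], ff)
    st = random_initial_state(top, box_edge_for_density(top.n_beads, rho), seed=spec.seed)
    return st, top


# ---------------------------------------------------------------------------
# ideal mesophase structures
# ---------------------------------------------------------------------------

def _chain_along(tpl: MoleculeTemplate, origin: np.ndarray, direction: np.ndarray,
                 step: float = 0.5) -> np.ndarray:
    """Straight chain with the tail (bead 0) at ``origin`` growing along
    ``direction``."""
    d = direction / np.linalg.norm(direction)
    return origin[None, :] + np.arange(tpl.n_beads)[:, None] * step * d[None, :]


def _fill_water(rng, pos_list, box, total_beads, n_placed):
    n_water = total_beads - n_placed
    if n_water < 0:
        raise ParameterError("fixture overfilled: surfactant beads exceed density budget")
    return rng.random((n_water, 3)) * box


def _assemble_structured(ff, tpl, mol_positions, box, rho, seed, jitter=0.05):
    """Stack per-molecule coordinate blocks, top up with water to rho."""
    rng = np.random.default_rng(seed)
    n_mol = len(mol_positions)
    total = int(round(rho * np.prod(box)))
    surf_beads = n_mol * tpl.n_beads
    water = _fill_water(rng, mol_positions, box, total, surf_beads)
    top = assemble([(tpl, n_mol), (WATER, len(water))], ff)
    pos = np.vstack(mol_positions + [water]) if len(water) else np.vstack(mol_positions)
    pos = pos + rng.normal(scale=jitter, size=pos.shape)
    pos %= box
    vel = rng.normal(size=pos.shape)
    vel -= vel.mean(axis=0)
    st = SystemState(box=np.asarray(box, float), positions=pos, velocities=vel,
                     types=top.bead_types.copy(), molecule_ids=top.molecule_ids.copy())
    return st, top


def _ideal_lamellar(spec: FixtureSpec, ff: ForceField):
    """Stacked bilayers normal to z, tails inward, water between head layers."""
    n_c = int(spec.opt("n", 8))
    m_e = int(spec.opt("m", 4))
    L = float(spec.opt("box", 12.0))
    n_bilayers = int(spec.opt("n_bilayers", 1))
    spacing = float(spec.opt("area_spacing", 0.8))
    rho = float(spec.opt("density", 3.0))
    tpl = build_cnem(n_c, m_e)
    rng = np.random.default_rng(spec.seed)
    box = np.array([L, L, L])
    nxy = int(L / spacing)
    blocks = []
    for k in range(n_bilayers):
        z_mid = (k + 0.5) * L / n_bilayers
        for ix in range(nxy):
            for iy in range(nxy):
                xy = np.array([(ix + 0.5) * L / nxy, (iy + 0.5) * L / nxy])
                for sgn in (+1.0, -1.0):
                    origin = np.array([xy[0], xy[1], z_mid + sgn * 0.25])
                    blocks.append(_chain_along(tpl, origin, np.array([0, 0, sgn]),
                                               step=0.45))
    return _assemble_structured(ff, tpl, blocks, box, rho, spec.seed)


def _ideal_hexagonal(spec: FixtureSpec, ff: ForceField):
    """Cylinders along z on a (centred-rectangular = hexagonal) lattice."""
    n_c = int(spec.opt("n", 8))
    m_e = int(spec.opt("m", 4))
    a = float(spec.opt("lattice", 8.0))
    ncols = int(spec.opt("ncols", 2))
    nrows = int(spec.opt("nrows", 2))
    lz = float(spec.opt("lz", 16.0))
    rho = float(spec.opt("density", 3.0))
    mols_per_ring = int(spec.opt("mols_per_ring", 10))
    ring_dz = float(spec.opt("ring_dz", 0.5))
    tpl = build_cnem(n_c, m_e)
    box = np.array([ncols * a, nrows * a * math.sqrt(3) / 2.0, lz])
    centers = []
    for i in range(ncols):
        for j in range(nrows):
            centers.append([(i + 0.5 * (j % 2)) * a % box[0],
                            j * a * math.sqrt(3) / 2.0])
    blocks = []
    nrings = int(lz / ring_dz)
    for cx, cy in centers:
        for r in range(nrings):
            z = (r + 0.5) * ring_dz
            for mth in range(mols_per_ring):
                phi = 2 * math.pi * (mth + 0.3 * (r % 2)) / mols_per_ring
                d = np.array([math.cos(phi), math.sin(phi), 0.0])
                origin = np.array([cx, cy, z]) + 0.3 * d
                blocks.append(_chain_along(tpl, origin, d, step=0.45))
    return _assemble_structured(ff, tpl, blocks, box, rho, spec.seed)


def _micelle_blocks(tpl, centers, mols_per_micelle, rng):
    blocks = []
    for c in centers:
        for _ in range(mols_per_micelle):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            blocks.append(_chain_along(tpl, np.asarray(c) + 0.4 * d, d, step=0.42))
    return blocks


def _micellar_fcc(spec: FixtureSpec, ff: ForceField):
    n_c = int(spec.opt("n", 8))
    m_e = int(spec.opt("m", 4))
    a = float(spec.opt("lattice", 9.0))
    ncell = int(spec.opt("ncells", 2))
    mols = int(spec.opt("mols_per_micelle", 30))
    rho = float(spec.opt("density", 3.0))
    tpl = build_cnem(n_c, m_e)
    box = np.array([ncell * a] * 3)
    basis = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
    centers = []
    for i in range(ncell):
        for j in range(ncell):
            for k in range(ncell):
                for b in basis:
                    centers.append((np.array([i, j, k]) + b) * a)
    rng = np.random.default_rng(spec.seed)
    blocks = _micelle_blocks(tpl, centers, mols, rng)
    return _assemble_structured(ff, tpl, blocks, box, rho, spec.seed)


def _micellar_random(spec: FixtureSpec, ff: ForceField):
    n_c = int(spec.opt("n", 8))
    m_e = int(spec.opt("m", 4))
    a = float(spec.opt("lattice", 9.0))
    ncell = int(spec.opt("ncells", 2))
    mols = int(spec.opt("mols_per_micelle", 30))
    rho = float(spec.opt("density", 3.0))
    min_sep = float(spec.opt("min_separation", 4.5))
    tpl = build_cnem(n_c, m_e)
    box = np.array([ncell * a] * 3)
    n_mic = 4 * ncell**3  # same count as the FCC variant
    rng = np.random.default_rng(spec.seed)
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_mic and attempts < 200000:
        c = rng.random(3) * box
        ok = True
        for o in centers:
            d = c - o
            d -= box * np.rint(d / box)
            if np.linalg.norm(d) < min_sep:
                ok = False
                break
        if ok:
            centers.append(c)
        attempts += 1
    if len(centers) < n_mic:
        raise ParameterError("could not place micelles; lower min_separation")
    blocks = _micelle_blocks(tpl, centers, mols, rng)
    return _assemble_structured(ff, tpl, blocks, box, rho, spec.seed)


# ---------------------------------------------------------------------------
# biphasic and bonded reference systems
# ---------------------------------------------------------------------------

def _demixed_biphasic(spec: FixtureSpec, ff: ForceField):
    """Pre-separated water/octanol slabs along z with solutes split between
    the phases (fraction set by ``solute_in_octanol``)."""
    n_oct = int(spec.opt("n_octanol", 330))
    n_wat = int(spec.opt("n_water", 3350))
    solute_name = spec.opt("solute", "water")
    n_sol = int(spec.opt("n_solute", 12))
    frac_oct = float(spec.opt("solute_in_octanol", 0.5))
    aspect = float(spec.opt("aspect", 3.0))
    rho = float(spec.opt("density", 3.0))
    octanol = build_solute("octanol")
    water = build_solute("water")
    solute = build_solute(solute_name)
    top = assemble([(octanol, n_oct), (water, n_wat), (solute, n_sol)], ff)
    volume = top.n_beads / rho
    lx = (volume / aspect) ** (1.0 / 3.0)
    box = np.array([lx, lx, aspect * lx])
    # octanol slab occupies the z-fraction matching its bead share
    z_oct = box[2] * (n_oct * octanol.n_beads) / top.n_beads
    rng = np.random.default_rng(spec.seed)
    pos = np.empty((top.n_beads, 3))
    i = 0
    for _ in range(n_oct):
        anchor = rng.random(3) * [box[0], box[1], max(z_oct - 2.0, 0.1)]
        for k in range(octanol.n_beads):
            pos[i] = anchor + [0, 0, 0.4 * k]
            i += 1
    for _ in range(n_wat):
        pos[i] = rng.random(3) * [box[0], box[1], box[2] - z_oct] + [0, 0, z_oct]
        i += 1
    uniform = spec.opt("solute_uniform", False)
    n_in_oct = int(round(frac_oct * n_sol))
    for s in range(n_sol):
        if uniform:
            z0 = rng.random() * box[2]
        elif s < n_in_oct:
            z0 = rng.random() * (z_oct - 3.0) + 1.0
        else:
            z0 = z_oct + 1.0 + rng.random() * (box[2] - z_oct - 3.0)
        anchor = np.array([rng.random() * box[0], rng.random() * box[1], z0])
        for k in range(solute.n_beads):
            pos[i] = anchor + [0.3 * k, 0, 0]
            i += 1
    pos %= box
    vel = rng.normal(size=pos.shape)
    vel -= vel.mean(axis=0)
    st = SystemState(box=box, positions=pos, velocities=vel,
                     types=top.bead_types.copy(), molecule_ids=top.molecule_ids.copy())
    return st, top


def _bonded_chain(spec: FixtureSpec, ff: ForceField, beads: tuple[str, ...]):
    """One bonded chain plus a water bath at rho=3.

    The bath thermalizes all degrees of freedom of the chain through the
    pairwise thermostat; without it an isolated dimer conserves angular
    momentum and never samples the Boltzmann bond distribution.  Runs that
    want a pure-thermostat bath disable the nonbonded forces in the
    simulation config.
    """
    bonds = tuple((i, i + 1) for i in range(len(beads) - 1))
    angles = tuple((i, i + 1, i + 2) for i in range(len(beads) - 2))
    tpl = MoleculeTemplate("chain", beads, bonds, angles, {"C": 1})
    L = float(spec.opt("box", 4.0))
    rho = float(spec.opt("density", 3.0))
    n_bath = max(0, int(round(rho * L**3)) - len(beads))
    top = assemble([(tpl, 1), (WATER, n_bath)], ff)
    st = random_initial_state(top, L, seed=spec.seed)
    return st, top


def _bonded_pair(spec: FixtureSpec, ff: ForceField):
    beads = spec.opt("beads", ("CH2CH2", "CH2CH2"))
    return _bonded_chain(spec, ff, tuple(beads))


def _bonded_trimer(spec: FixtureSpec, ff: ForceField):
    beads = spec.opt("beads", ("CH2OCH2", "CH2OCH2", "CH2OCH2"))
    return _bonded_chain(spec, ff, tuple(beads))


_BUILDERS = {
    "pure_water": _pure_water,
    "melt": _melt,
    "random_mixture": _random_mixture,
    "ideal_lamellar": _ideal_lamellar,
    "ideal_hexagonal": _ideal_hexagonal,
    "micellar_random": _micellar_random,
    "micellar_fcc": _micellar_fcc,
    "demixed_biphasic": _demixed_biphasic,
    "bonded_pair": _bonded_pair,
    "bonded_trimer": _bonded_trimer,
}
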