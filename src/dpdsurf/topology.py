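"""Bead-level molecular templates and box composition.

A CnEm surfactant maps to the linear bead sequence

    CH3, (CH2CH2) x (n/2 - 1), (CH2OCH2) x (m - 1), CH2OH

i.e. n/2 + m beads, with bonds between adjacent beads and one angle centred
on every interior bead.  Since bead counts are integers, n must be even.
Water is supermolecular: one 2H2O bead represents two water molecules
(mapping number N_m = 2), so a water bead weighs 2 x 18.015 g/mol.

Weight fractions are chemical: they use the real molar mass of the species
(from its molecular formula), not bead-count fractions, because the phase
axes of interest are experimental wt %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CompositionError, ParameterError, UnsupportedSpeciesError
from .forcefield import ForceField

ATOMIC_WEIGHTS = {"C": 12.011, "H": 1.008, "O": 15.999}

#: molar mass of one water bead (two H2O molecules), g/mol
WATER_BEAD_MASS = 2 * (2 * ATOMIC_WEIGHTS["H"] + ATOMIC_WEIGHTS["O"])


@dataclass(frozen=True)
class MoleculeTemplate:
    """Bead sequence, connectivity and chemical identity of one species."""

    name: str
    beads: tuple[str, ...]
    bonds: tuple[tuple[int, int], ...]
    angles: tuple[tuple[int, int, int], ...]
    formula: dict[str, int] = field(default_factory=dict, compare=False)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def molar_mass(self) -> float:
        return molar_mass(self)


def molar_mass(template: MoleculeTemplate) -> float:
    """Molar mass in g/mol from the template's atomic composition."""
    if not template.formula:
        raise ParameterError(f"template {template.name!r} has no atomic composition")
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in template.formula.items())


def _linear_connectivity(n: int) -> tuple[tuple, tuple]:
    bonds = tuple((i, i + 1) for i in range(n - 1))
    angles = tuple((i, i + 1, i + 2) for i in range(n - 2))
    return bonds, angles


def build_cnem(n: int, m: int) -> MoleculeTemplate:
    """Template for a CnEm surfactant (n even >= 2, m >= 1)."""
    if n < 2 or n % 2 != 0:
        raise UnsupportedSpeciesError(
            f"C{n}E{m}: the two-carbon alkyl bead mapping requires an even "
            f"number of carbon atoms (n={n})"
        )
    if m < 1:
        raise UnsupportedSpeciesError(f"C{n}E{m}: need at least one ethoxylate unit")
    beads = ("CH3",) + ("CH2CH2",) * (n // 2 - 1) + ("CH2OCH2",) * (m - 1) + ("CH2OH",)
    bonds, angles = _linear_connectivity(len(beads))
    # real molecular formula CnH(2n+1)-(OC2H4)m-OH
    formula = {"C": n + 2 * m, "H": 2 * (n + 2 * m) + 2, "O": m + 1}
    return MoleculeTemplate(f"C{n}E{m}", beads, bonds, angles, formula)


_SOLUTES: dict[str, tuple[tuple[str, ...], dict[str, int]]] = {
    "water": (("2H2O",), {"H": 4, "O": 2}),
    "octanol": (("CH3", "CH2CH2", "CH2CH2", "CH2CH2", "CH2OH"), {"C": 8, "H": 18, "O": 1}),
    "diglyme": (("CH2OCH2", "CH2OCH2", "CH2OCH2"), {"C": 6, "H": 14, "O": 3}),
    "diethyl ether": (("CH3", "CH2OCH2", "CH3"), {"C": 4, "H": 10, "O": 1}),
    "2-hexyloxyethanol": (
        ("CH3", "CH2CH2", "CH2CH2", "CH2OCH2", "CH2OH"),
        {"C": 8, "H": 18, "O": 2},
    ),
}


def build_solute(name: str) -> MoleculeTemplate:
    """Template for a parameterised solute (or water)."""
    key = name.lower()
    if key not in _SOLUTES:
        raise UnsupportedSpeciesError(
            f"solute {name!r} is not parameterised; known: {sorted(_SOLUTES)}"
        )
    beads, formula = _SOLUTES[key]
    bonds, angles = _linear_connectivity(len(beads))
    return MoleculeTemplate(key, beads, bonds, angles, formula)


WATER = build_solute("water")


@dataclass
class Topology:
    """Per-bead and per-interaction arrays for an assembled system."""

    bead_types: np.ndarray  # (N,) int, indices into ForceField.type_index()
    molecule_ids: np.ndarray  # (N,) int
    bead_names: tuple[str, ...]  # index -> name
    bonds: np.ndarray  # (nb, 2) int
    bond_r0: np.ndarray  # (nb,)
    angles: np.ndarray  # (na, 3) int
    angle_ka: np.ndarray  # (na,)
    angle_theta0: np.ndarray  # (na,)
    species_of_molecule: list[str] = field(default_factory=list)
    templates: dict[str, MoleculeTemplate] = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return len(self.bead_types)

    @property
    def n_molecules(self) -> int:
        return len(self.species_of_molecule)

    def hydrophobic_mask(self, ff: ForceField) -> np.ndarray:
        hydro = {ff.type_index()[n] for n in ff.hydrophobic_beads()}
        return np.isin(self.bead_types, list(hydro))


def assemble(counts: dict[MoleculeTemplate, int] | list[tuple[MoleculeTemplate, int]],
             ff: ForceField) -> Topology:
    """Concatenate ``count`` copies of each template into flat arrays.

    Every emitted angle triple is resolved against the force field here, so
    a missing table entry fails loudly at build time rather than silently
    defaulting during dynamics.
    """
    if isinstance(counts, dict):
        counts = list(counts.items())
    tindex = ff.type_index()
    types: list[int] = []
    mols: list[int] = []
    bonds: list[tuple[int, int]] = []
    bond_r0: list[float] = []
    angles: list[tuple[int, int, int]] = []
    angle_ka: list[float] = []
    angle_t0: list[float] = []
    species: list[str] = []
    templates: dict[str, MoleculeTemplate] = {}
    offset = 0
    mol_id = 0
    for tpl, count in counts:
        if count < 0:
            raise CompositionError(f"negative count for {tpl.name}")
        if count:
            templates[tpl.name] = tpl
        bparams = [ff.bond(tpl.beads[i], tpl.beads[j]) for i, j in tpl.bonds]
        aparams = [ff.angle(tpl.beads[i], tpl.beads[j], tpl.beads[k]) for i, j, k in tpl.angles]
        for _ in range(count):
            types.extend(tindex[b] for b in tpl.beads)
            mols.extend([mol_id] * tpl.n_beads)
            for (i, j), bp in zip(tpl.bonds, bparams):
                bonds.append((offset + i, offset + j))
                bond_r0.append(bp.r_0)
            for (i, j, k), ap in zip(tpl.angles, aparams):
                angles.append((offset + i, offset + j, offset + k))
                angle_ka.append(ap.k_a)
                angle_t0.append(ap.theta0)
            species.append(tpl.name)
            offset += tpl.n_beads
            mol_id += 1
    return Topology(
        bead_types=np.asarray(types, dtype=np.int64),
        molecule_ids=np.asarray(mols, dtype=np.int64),
        bead_names=tuple(sorted(tindex, key=tindex.get)),
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        bond_r0=np.asarray(bond_r0),
        angles=np.asarray(angles, dtype=np.int64).reshape(-1, 3),
        angle_ka=np.asarray(angle_ka),
        angle_theta0=np.asarray(angle_t0),
        species_of_molecule=species,
        templates=templates,
    )


@dataclass(frozen=True)
class BoxComposition:
    """Integer molecule counts realizing a target surfactant weight fraction."""

    surfactant: MoleculeTemplate
    n_surfactant: int
    n_water_beads: int
    target_wt_pct: float

    @property
    def total_beads(self) -> int:
        return self.n_surfactant * self.surfactant.n_beads + self.n_water_beads

    @property
    def realized_wt_pct(self) -> float:
        m_s = self.n_surfactant * self.surfactant.molar_mass
        m_w = self.n_water_beads * WATER_BEAD_MASS
        if m_s + m_w == 0:
            return 0.0
        return 100.0 * m_s / (m_s + m_w)


def compose_box(
    surfactant: MoleculeTemplate,
    wt_pct: float,
    total_beads: int | None = None,
    n_molecules: int | None = None,
) -> BoxComposition:
    """Integer composition closest to a target weight fraction.

    Either ``total_beads`` is fixed (molecule count rounded to hit the target
    wt %, water beads filling the remainder), or ``n_molecules`` is fixed and
    the water-bead count follows from the mass balance -- the CMC protocol,
    where the molecule count is 4 x the experimental aggregation number.
    """
    if not (0.0 <= wt_pct <= 100.0):
        raise CompositionError(f"wt % must be in [0, 100], got {wt_pct}")
    m_s = surfactant.molar_mass
    b_s = surfactant.n_beads
    w = wt_pct / 100.0
    if n_molecules is not None:
        if n_molecules < 1:
            raise CompositionError("need at least one surfactant molecule")
        if w <= 0:
            raise CompositionError("molecule-count mode needs wt % > 0")
        n_w = int(round(n_molecules * m_s * (1.0 - w) / (w * WATER_BEAD_MASS)))
        return BoxComposition(surfactant, n_molecules, n_w, wt_pct)
    if total_beads is None or total_beads <= 0:
        raise CompositionError("total_beads must be a positive integer")
    if w == 0.0:
        return BoxComposition(surfactant, 0, total_beads, wt_pct)
    # mass balance: w = ns*ms / (ns*ms + nw*mw), nw = total - ns*bs
    denom = m_s * (1.0 - w) + w * WATER_BEAD_MASS * b_s
    ns_real = w * WATER_BEAD_MASS * total_beads / denom
    n_s = int(round(ns_real))
    if w > 0 and n_s < 1:
        raise CompositionError(
            f"target {wt_pct} wt % yields <1 molecule of {surfactant.name} in "
            f"{total_beads} beads; enlarge the box"
        )
    if n_s * b_s > total_beads:
        n_s = total_beads // b_s
    return BoxComposition(surfactant, n_s, total_beads - n_s * b_s, wt_pct)


def random_initial_state(
    topology: Topology,
    box: np.ndarray | float,
    seed: int,
    kT: float = 1.0,
):
    """Ideal-gas random initial configuration (soft potentials tolerate overlap).

    Molecules are seeded at random positions and grown as random walks with
    the nominal bond length, so bonds start near r_0.  Velocities are
    Maxwell-Boltzmann at ``kT`` with the centre-of-mass drift removed.
    """
    from .engine import SystemState  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    box = np.broadcast_to(np.atleast_1d(np.asarray(box, dtype=float)), (3,)).copy()
    n = topology.n_beads
    pos = np.empty((n, 3))
    # grow each molecule as a random walk from a uniform anchor
    mol_ids = topology.molecule_ids
    bond_of = {}
    for (i, j), r0 in zip(topology.bonds, topology.bond_r0):
        bond_of[(int(i), int(j))] = r0
    start = 0
    while start < n:
        mid = mol_ids[start]
        end = start
        while end < n and mol_ids[end] == mid:
            end += 1
        pos[start] = rng.random(3) * box
        for i in range(start + 1, end):
            r0 = bond_of.get((i - 1, i), 0.5)
            step = rng.normal(size=3)
            step *= r0 / np.linalg.norm(step)
            pos[i] = pos[i - 1] + step
        start = end
    pos %= box
    vel = rng.normal(scale=math.sqrt(kT), size=(n, 3))
    vel -= vel.mean(axis=0)
    return SystemState(box=box, positions=pos, velocities=vel,
                       types=topology.bead_types.copy(),
                       molecule_ids=topology.molecule_ids.copy(), time=0.0)


def box_edge_for_density(total_beads: int, rho: float = 3.0) -> float:
    """Cubic box edge giving bead number density rho (DPD units)."""
    if total_beads <= 0 or rho <= 0:
        raise ParameterError("total_beads and rho must be positive")
    return (total_beads / rho) ** (1.0 / 3.0)
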