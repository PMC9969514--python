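"""File formats: extended XYZ trajectories, YAML run configs, provenance.

The trajectory interchange format is extended XYZ: one block per frame,
with the orthorhombic box on the comment line (``Lattice="..."``) plus
per-atom columns species, position, molecule id.  The comment line also
carries the frame time and, on the first frame, the seed and a parameter
digest, so a trajectory is self-describing.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, TextIO

import numpy as np
import yaml

from .engine import SystemState, Trajectory
from .errors import ParameterError
from .forcefield import ForceField
from .topology import Topology


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def _lattice_string(box: np.ndarray) -> str:
    b = np.asarray(box, float)
    return f'Lattice="{b[0]} 0.0 0.0 0.0 {b[1]} 0.0 0.0 0.0 {b[2]}"'


def write_extxyz_frame(
    fh: TextIO,
    box: np.ndarray,
    positions: np.ndarray,
    species: list[str],
    molecule_ids: np.ndarray,
    time: float = 0.0,
    extra_comment: str = "",
) -> None:
    n = len(positions)
    fh.write(f"{n}\n")
    comment = (
        f"{_lattice_string(box)} "
        'Properties=species:S:1:pos:R:3:mol:I:1 '
        f"Time={time:.6g}"
    )
    if extra_comment:
        comment += " " + extra_comment
    fh.write(comment + "\n")
    for i in range(n):
        x, y, z = positions[i]
        fh.write(f"{species[i]} {x:.8g} {y:.8g} {z:.8g} {int(molecule_ids[i])}\n")


def write_trajectory(
    path: str | Path,
    trajectory: Trajectory,
    provenance: dict | None = None,
) -> None:
    top = trajectory.topology
    species = [top.bead_names[t] for t in top.bead_types]
    with open(path, "w") as fh:
        for k in range(len(trajectory)):
            t, box, pos = trajectory.frame(k)
            extra = ""
            if k == 0 and provenance:
                extra = " ".join(f"{key}={val}" for key, val in provenance.items())
            write_extxyz_frame(fh, box, pos, species, top.molecule_ids, t, extra)


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"Time=([0-9eE.+-]+)")


@dataclass
class XYZFrame:
    box: np.ndarray
    positions: np.ndarray
    species: list[str]
    molecule_ids: np.ndarray
    time: float
    comment: str


def read_extxyz(path: str | Path) -> Iterator[XYZFrame]:
    """Stream frames from an extended-XYZ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                return
            n = int(header)
            comment = fh.readline().rstrip("\n")
            m = _LATTICE_RE.search(comment)
            if not m:
                raise ParameterError("frame comment lacks Lattice=")
            lat = np.fromstring(m.group(1), sep=" ").reshape(3, 3)
            box = np.diag(lat).copy()
            tm = _TIME_RE.search(comment)
            t = float(tm.group(1)) if tm else 0.0
            species, mols = [], np.empty(n, dtype=np.int64)
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                species.append(parts[0])
                pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
                mols[i] = int(parts[4]) if len(parts) > 4 else 0
            yield XYZFrame(box, pos, species, mols, t, comment)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Declarative description of one simulation run."""

    species: dict = field(default_factory=dict)  # {"surfactant": "C12E6", "wt_pct": 50}
    forcefield_variant: str = "revised"
    ensemble: str = "npt"
    pressure: float = 23.7
    total_beads: int = 81000
    equilibration_tau: float = 1.0e5
    production_tau: float = 2.0e5
    dt: float = 0.01
    sample_every_tau: float = 1.0
    traj_every_tau: float = 10.0
    seed: int = 0
    analysis: dict = field(default_factory=dict)

    REQUIRED = ("species", "seed")

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "forcefield_variant": self.forcefield_variant,
            "ensemble": self.ensemble,
            "pressure": self.pressure,
            "total_beads": self.total_beads,
            "equilibration_tau": self.equilibration_tau,
            "production_tau": self.production_tau,
            "dt": self.dt,
            "sample_every_tau": self.sample_every_tau,
            "traj_every_tau": self.traj_every_tau,
            "seed": self.seed,
            "analysis": self.analysis,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ParameterError("config must be a mapping")
        known = set(cls().to_dict())
        unknown = set(raw) - known
        missing = [k for k in cls.REQUIRED if k not in raw]
        problems = []
        if unknown:
            problems.append(f"unknown keys: {sorted(unknown)}")
        if missing:
            problems.append(f"missing required keys: {missing}")
        if problems:
            raise ParameterError("config schema error: " + "; ".join(problems))
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def provenance_block(config: RunConfig, ff: ForceField) -> dict:
    from . import __version__

    ff_digest = hashlib.sha256(
        json.dumps(ff.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]
    return {
        "dpdsurf_version": __version__,
        "config_digest": config.digest(),
        "forcefield_digest": ff_digest,
        "seed": config.seed,
    }


def topology_from_frame(frame: XYZFrame, ff: ForceField) -> Topology:
    """Reconstruct a minimal topology from one extended-XYZ frame.

    Bead types and molecule ids come straight from the columns; linear
    connectivity is assumed within each molecule (the bead order in the
    file is the chain order).  Species names are recovered by matching the
    bead sequence against the known templates (CnEm, water, solutes).
    """
    from .forcefield import BEAD_NAMES
    from .topology import _SOLUTES, build_cnem

    tindex = ff.type_index()
    try:
        types = np.array([tindex[s] for s in frame.species], dtype=np.int64)
    except KeyError as exc:
        raise ParameterError(f"unknown bead species in file: {exc}") from None
    mols = frame.molecule_ids
    order = np.argsort(mols, kind="stable")
    if not np.array_equal(order, np.arange(len(mols))):
        raise ParameterError("beads must be grouped by molecule id")
    bonds, bond_r0, angles, angle_ka, angle_t0, species_names = [], [], [], [], [], []
    solute_by_beads = {tuple(v[0]): k for k, v in _SOLUTES.items()}
    start = 0
    n = len(mols)
    while start < n:
        end = start
        while end < n and mols[end] == mols[start]:
            end += 1
        beads = tuple(frame.species[i] for i in range(start, end))
        name = solute_by_beads.get(beads)
        if name is None:
            n_alkyl = sum(1 for b in beads if b in ("CH3", "CH2CH2"))
            n_head = len(beads) - n_alkyl
            name = f"C{2 * n_alkyl}E{n_head}" if n_head else "alkane"
        species_names.append(name)
        for i in range(start, end - 1):
            bonds.append((i, i + 1))
            bond_r0.append(ff.bond(frame.species[i], frame.species[i + 1]).r_0)
        for i in range(start, end - 2):
            ap = ff.angle(frame.species[i], frame.species[i + 1], frame.species[i + 2])
            angles.append((i, i + 1, i + 2))
            angle_ka.append(ap.k_a)
            angle_t0.append(ap.theta0)
        start = end
    return Topology(
        bead_types=types,
        molecule_ids=mols.copy(),
        bead_names=BEAD_NAMES,
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        bond_r0=np.asarray(bond_r0),
        angles=np.asarray(angles, dtype=np.int64).reshape(-1, 3),
        angle_ka=np.asarray(angle_ka),
        angle_theta0=np.asarray(angle_t0),
        species_of_molecule=species_names,
    )
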