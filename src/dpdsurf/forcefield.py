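"""Interaction parameter set for the CnEm surfactant DPD model.

Five bead types (2H2O, CH3, CH2CH2, CH2OCH2, CH2OH) interact through soft
pairwise repulsions U_ij = (A_ij R_ij / 2)(1 - r/R_ij)^2, harmonic bonds
U_b = k_b (r - r_0)^2 with the heavy-atom rule r_0 = 0.1(n_i + n_j) - 0.01,
and harmonic angles U_a = 1/2 k_a (theta - theta0)^2.  Cross cutoffs follow
the arithmetic mixing rule R_ij = (R_ii + R_jj)/2; the dissipative/random
cutoff is the global maximum self-cutoff (1.1160) with friction gamma = 4.5.

Two variants are shipped: ``revised`` (the model proper) and ``original``
(its antecedent: alkyl-ether A_ij = 28.5, all angles 180 deg with k_a = 5).
Parameters live in a version-controlled YAML table (``data/forcefield.yaml``)
rather than in code, so the transcription is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .errors import AngleLookupError, BeadLookupError, ParameterError

BEAD_NAMES = ("2H2O", "CH3", "CH2CH2", "CH2OCH2", "CH2OH")

PairKey = tuple[str, str]
AngleKey = tuple[str, str, str]


def mix_cutoff(r_ii: float, r_jj: float) -> float:
    """Arithmetic mixing rule for cross-interaction cutoffs."""
    if r_ii <= 0 or r_jj <= 0:
        raise ParameterError(f"self-cutoffs must be positive, got {r_ii}, {r_jj}")
    return 0.5 * (r_ii + r_jj)


def nominal_bond_length(n_i: int, n_j: int) -> float:
    """Heavy-atom rule r_0 = 0.1(n_i + n_j) - 0.01 in DPD length units."""
    if n_i < 1 or n_j < 1:
        raise ParameterError(f"heavy-atom counts must be >= 1, got {n_i}, {n_j}")
    return 0.1 * (n_i + n_j) - 0.01


def _pair_key(i: str, j: str) -> PairKey:
    return (i, j) if i <= j else (j, i)


def _angle_key(i: str, j: str, k: str) -> AngleKey:
    return (i, j, k) if (i, k) <= (k, i) else (k, j, i)


@dataclass(frozen=True)
class BeadSpec:
    name: str
    heavy_atom_count: int
    self_cutoff: float
    hydrophobic: bool


@dataclass(frozen=True)
class PairParams:
    A: float
    R: float


@dataclass(frozen=True)
class BondParams:
    k_b: float
    r_0: float


@dataclass(frozen=True)
class AngleParams:
    k_a: float
    theta0: float  # radians

    @property
    def theta0_deg(self) -> float:
        return math.degrees(self.theta0)


@dataclass
class ForceField:
    """Complete, validated interaction parameter set."""

    beads: dict[str, BeadSpec]
    pairs: dict[PairKey, PairParams]
    k_b: float
    angles: dict[AngleKey, AngleParams]
    gamma: float = 4.5
    variant: str = "revised"
    #: triplet keys that belong to the core angle table (used by validate())
    core_angles: frozenset = field(default_factory=frozenset)

    # -- lookups ---------------------------------------------------------
    def bead(self, name: str) -> BeadSpec:
        try:
            return self.beads[name]
        except KeyError:
            raise BeadLookupError(f"unknown bead type {name!r}") from None

    def pair(self, i: str, j: str) -> PairParams:
        self.bead(i), self.bead(j)
        return self.pairs[_pair_key(i, j)]

    def bond(self, i: str, j: str) -> BondParams:
        bi, bj = self.bead(i), self.bead(j)
        return BondParams(self.k_b, nominal_bond_length(bi.heavy_atom_count, bj.heavy_atom_count))

    def angle(self, i: str, j: str, k: str) -> AngleParams:
        for n in (i, j, k):
            self.bead(n)
        try:
            return self.angles[_angle_key(i, j, k)]
        except KeyError:
            raise AngleLookupError(
                f"no angle parameters for triplet ({i}, {j}, {k}) in variant "
                f"{self.variant!r}"
            ) from None

    @property
    def dissipative_cutoff(self) -> float:
        return max(b.self_cutoff for b in self.beads.values())

    @property
    def bead_names(self) -> tuple[str, ...]:
        return tuple(self.beads)

    def hydrophobic_beads(self) -> tuple[str, ...]:
        return tuple(n for n, b in self.beads.items() if b.hydrophobic)

    # -- validation ------------------------------------------------------
    def validate(self) -> list[str]:
        """Check completeness and internal consistency; return violations."""
        problems: list[str] = []
        names = list(self.beads)
        if sorted(names) != sorted(BEAD_NAMES):
            problems.append(f"expected bead types {BEAD_NAMES}, got {tuple(names)}")
        n_pairs = len(names) * (len(names) + 1) // 2
        if len(self.pairs) != n_pairs:
            problems.append(f"pair table has {len(self.pairs)} entries, expected {n_pairs}")
        for (i, j), p in self.pairs.items():
            if p.A <= 0 or p.R <= 0:
                problems.append(f"pair ({i},{j}): non-positive A or R")
            if i in self.beads and j in self.beads:
                r_mix = mix_cutoff(self.beads[i].self_cutoff, self.beads[j].self_cutoff)
                if abs(p.R - r_mix) > 5e-5:
                    problems.append(
                        f"pair ({i},{j}): R_ij={p.R:.4f} violates mixing rule "
                        f"({r_mix:.4f})"
                    )
        core = self.core_angles or frozenset(self.angles)
        missing = core - set(self.angles)
        if missing:
            problems.append(f"missing core angle triplets: {sorted(missing)}")
        if self.variant == "revised" and self.core_angles and len(self.core_angles) != 6:
            problems.append(f"revised variant should carry 6 core triplets, got {len(self.core_angles)}")
        for key, a in self.angles.items():
            if not (0 < a.theta0 <= math.pi + 1e-12):
                problems.append(f"angle {key}: theta0 out of (0, pi]")
            if a.k_a <= 0:
                problems.append(f"angle {key}: non-positive k_a")
        if self.k_b <= 0:
            problems.append("k_b must be positive")
        if self.gamma <= 0:
            problems.append("gamma must be positive")
        return problems

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "gamma": self.gamma,
            "beads": {
                n: [b.heavy_atom_count, b.self_cutoff, b.hydrophobic]
                for n, b in self.beads.items()
            },
            "bond": {"k_b": self.k_b},
            "pairs": [[i, j, p.A, p.R] for (i, j), p in sorted(self.pairs.items())],
            "angles": [
                [i, j, k, a.k_a, a.theta0_deg] for (i, j, k), a in sorted(self.angles.items())
            ],
            "core_angles": sorted(list(k) for k in self.core_angles),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForceField":
        beads = {
            n: BeadSpec(n, int(v[0]), float(v[1]), bool(v[2])) for n, v in d["beads"].items()
        }
        pairs = {
            _pair_key(i, j): PairParams(float(A), float(R)) for i, j, A, R in d["pairs"]
        }
        angles = {
            _angle_key(i, j, k): AngleParams(float(ka), math.radians(float(t0)))
            for i, j, k, ka, t0 in d["angles"]
        }
        core = frozenset(_angle_key(*t) for t in d.get("core_angles", []))
        return cls(
            beads=beads,
            pairs=pairs,
            k_b=float(d["bond"]["k_b"]),
            angles=angles,
            gamma=float(d["gamma"]),
            variant=d.get("variant", "revised"),
            core_angles=core,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ForceField":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- dense tables for the engine ------------------------------------
    def type_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(BEAD_NAMES)}

    def pair_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """(A, R) as dense symmetric arrays indexed by ``type_index`` order."""
        nt = len(BEAD_NAMES)
        A = np.zeros((nt, nt))
        R = np.zeros((nt, nt))
        for ia, na in enumerate(BEAD_NAMES):
            for ib, nb in enumerate(BEAD_NAMES):
                p = self.pair(na, nb)
                A[ia, ib], R[ia, ib] = p.A, p.R
        return A, R


def _load_raw(path: str | Path | None = None) -> dict:
    if path is not None:
        return yaml.safe_load(Path(path).read_text())
    text = resources.files("dpdsurf").joinpath("data/forcefield.yaml").read_text()
    return yaml.safe_load(text)


def load_forcefield(
    variant: str = "revised",
    path: str | Path | None = None,
    include_extensions: bool = True,
) -> ForceField:
    """Load the shipped (or a user-supplied) parameter file.

    Parameters
    ----------
    variant
        ``"revised"`` for the model proper or ``"original"`` for its
        antecedent parameterisation.
    include_extensions
        Whether solute-only angle triplets (documented terminal analogs that
        are not part of the core angle table) are included in lookups.
    """
    if variant not in ("revised", "original"):
        raise ParameterError(f"unknown force-field variant {variant!r}")
    raw = _load_raw(path)
    beads = {
        n: BeadSpec(n, int(v[0]), float(v[1]), bool(v[2])) for n, v in raw["beads"].items()
    }
    pairs = {_pair_key(i, j): PairParams(float(A), float(R)) for i, j, A, R in raw["pairs"]}
    core_entries = [
        (_angle_key(i, j, k), float(ka), float(t0)) for i, j, k, ka, t0 in raw["angles"]
    ]
    ext_entries = [
        (_angle_key(i, j, k), float(ka), float(t0))
        for i, j, k, ka, t0 in raw.get("angle_extensions", [])
    ]
    if variant == "original":
        ov = raw["original_overrides"]
        for i, j, A in ov["pairs"]:
            key = _pair_key(i, j)
            pairs[key] = PairParams(float(A), pairs[key].R)
        ka0 = float(ov["angles_all"]["k_a"])
        t0 = float(ov["angles_all"]["theta0_deg"])
        core_entries = [(key, ka0, t0) for key, _, _ in core_entries]
        ext_entries = [(key, ka0, t0) for key, _, _ in ext_entries]
    angles = {key: AngleParams(ka, math.radians(t0)) for key, ka, t0 in core_entries}
    core = frozenset(angles)
    if include_extensions:
        for key, ka, t0 in ext_entries:
            angles.setdefault(key, AngleParams(ka, math.radians(t0)))
    return ForceField(
        beads=beads,
        pairs=pairs,
        k_b=float(raw["bond"]["k_b"]),
        angles=angles,
        gamma=float(raw["gamma"]),
        variant=variant,
        core_angles=core,
    )
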