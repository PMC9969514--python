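"""Brute-force water-octanol partition coefficients.

A single elongated box containing water, octanol and a small number of
solute molecules is started from a random mixture; water and octanol demix
into two slabs, and log P is estimated directly from the steady-state
solute concentrations in the two bulk regions:

    log P = log10( <c_octanol-rich> / <c_water-rich> )

with c a molar concentration (solute molecules per unit phase volume; the
common unit volume cancels in the ratio).  A buffer (default 2 r_c) on
each side of the interfaces is excluded from both phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import SystemState, Trajectory
from .errors import CompositionError, NotDemixedError, ParameterError
from .forcefield import ForceField
from .topology import Topology, assemble, build_solute, random_initial_state


@dataclass
class BiphasicSpec:
    """Composition of an elongated water/octanol/solute box."""

    solute: str
    n_solute: int = 12
    n_octanol: int = 330
    n_water: int = 3350
    aspect: float = 3.0  # long axis (z) over transverse edges
    density: float = 3.0

    def __post_init__(self):
        if self.aspect < 2.0:
            raise ParameterError("partition box aspect ratio must be >= 2")


def build_biphasic(
    spec: BiphasicSpec, ff: ForceField, seed: int = 0
) -> tuple[SystemState, Topology]:
    """Random mixed initial state in an elongated box at the target density.

    Default counts give ~5000 beads with roughly equal water and octanol
    volumes and a solute load small enough not to perturb either phase.
    """
    octanol = build_solute("octanol")
    water = build_solute("water")
    solute = build_solute(spec.solute)
    counts = [(octanol, spec.n_octanol), (water, spec.n_water), (solute, spec.n_solute)]
    top = assemble(counts, ff)
    volume = top.n_beads / spec.density
    lx = (volume / spec.aspect) ** (1.0 / 3.0)
    box = np.array([lx, lx, spec.aspect * lx])
    state = random_initial_state(top, box, seed=seed)
    return state, top


@dataclass
class PhaseMasks:
    """Per-frame partition of the long axis into phase slabs."""

    edges: np.ndarray  # histogram bin edges along z
    octanol_rich: np.ndarray  # (nbins,) bool
    water_rich: np.ndarray
    buffer: np.ndarray
    threshold: float


def _profile(z: np.ndarray, lz: float, nbins: int) -> np.ndarray:
    hist, _ = np.histogram(z % lz, bins=nbins, range=(0.0, lz))
    return hist.astype(float)


def phase_regions(
    positions: np.ndarray,
    box: np.ndarray,
    octanol_bead_mask: np.ndarray,
    nbins: int = 60,
    buffer_width: float = 2.0,
    bimodality_ratio: float = 4.0,
) -> PhaseMasks:
    """Slab masks from the octanol-bead density profile along the long axis.

    The threshold is the midpoint of the two bulk plateaus (the 10th and
    90th percentile of the smoothed profile).  Raises NotDemixedError when
    the profile is not bimodal (plateau ratio below ``bimodality_ratio``).
    """
    lz = float(box[2])
    prof = _profile(positions[octanol_bead_mask, 2], lz, nbins)
    # light smoothing over 3 bins, periodic
    prof = (np.roll(prof, 1) + prof + np.roll(prof, -1)) / 3.0
    lo, hi = np.percentile(prof, [10, 90])
    if hi < bimodality_ratio * max(lo, 1e-3 * hi) or hi <= 0:
        raise NotDemixedError(
            "octanol density profile is not bimodal; the box has not demixed"
        )
    thr = 0.5 * (lo + hi)
    oct_bins = prof > thr
    dz = lz / nbins
    nbuf = max(1, int(round(buffer_width / dz)))
    octanol_rich = oct_bins.copy()
    water_rich = ~oct_bins
    # erode both phases by the buffer around every interface
    for _ in range(nbuf):
        shrink = octanol_rich & np.roll(octanol_rich, 1) & np.roll(octanol_rich, -1)
        octanol_rich = shrink
        shrinkw = water_rich & np.roll(water_rich, 1) & np.roll(water_rich, -1)
        water_rich = shrinkw
    buffer = ~(octanol_rich | water_rich)
    edges = np.linspace(0.0, lz, nbins + 1)
    return PhaseMasks(edges, octanol_rich, water_rich, buffer, thr)


@dataclass
class LogPEstimate:
    log_p: float | None
    error: float
    c_octanol: float
    c_water: float
    bound: str | None = None  # ">= x" / "<= x" when one phase has zero counts
    per_frame: pd.DataFrame | None = None


def solute_molecule_positions(
    positions: np.ndarray,
    box: np.ndarray,
    molecule_ids: np.ndarray,
    solute_molecules: np.ndarray,
) -> np.ndarray:
    """Wrapped centroid (z only matters) of each solute molecule."""
    from .mesophase import unwrap_cluster

    out = []
    for m in solute_molecules:
        pts = positions[molecule_ids == m]
        out.append(unwrap_cluster(pts, box).mean(axis=0) % box)
    return np.asarray(out)


def estimate_logp(
    trajectory: Trajectory,
    solute_name: str,
    octanol_name: str = "octanol",
    buffer_width: float = 2.0,
    nbins: int = 60,
    n_blocks: int = 5,
    start_fraction: float = 0.3,
) -> LogPEstimate:
    """Brute-force log P from a demixed trajectory.

    Solute molecules are assigned per frame to the octanol-rich slab, the
    water-rich slab or the interface buffer by their centroid; concentrations
    use the corresponding slab volumes.  The error is a block average over
    ``n_blocks`` contiguous chunks of the analysis window.
    """
    top = trajectory.topology
    species = np.asarray(top.species_of_molecule)
    sol_mols = np.flatnonzero(species == solute_name)
    oct_mols = np.flatnonzero(species == octanol_name)
    if len(sol_mols) == 0:
        raise ParameterError(f"no molecules of species {solute_name!r} in trajectory")
    if len(oct_mols) == 0:
        raise ParameterError("no octanol in trajectory")
    oct_bead_mask = np.isin(top.molecule_ids, oct_mols)
    first = int(len(trajectory) * start_fraction)
    rows = []
    for fi in range(first, len(trajectory)):
        t, box, pos = trajectory.frame(fi)
        masks = phase_regions(pos, box, oct_bead_mask, nbins=nbins,
                              buffer_width=buffer_width)
        dz = box[2] / nbins
        area = box[0] * box[1]
        v_oct = masks.octanol_rich.sum() * dz * area
        v_wat = masks.water_rich.sum() * dz * area
        cent = solute_molecule_positions(pos, box, top.molecule_ids, sol_mols)
        bins = np.clip((cent[:, 2] / dz).astype(int), 0, nbins - 1)
        in_oct = int(masks.octanol_rich[bins].sum())
        in_wat = int(masks.water_rich[bins].sum())
        rows.append(
            {"time": t, "in_oct": in_oct, "in_wat": in_wat,
             "in_buffer": len(sol_mols) - in_oct - in_wat,
             "v_oct": v_oct, "v_wat": v_wat}
        )
    df = pd.DataFrame(rows)
    c_oct = float((df["in_oct"] / df["v_oct"]).mean())
    c_wat = float((df["in_wat"] / df["v_wat"]).mean())
    # block error on log10 ratio
    vals = []
    for idx in np.array_split(np.arange(len(df)), min(n_blocks, len(df))):
        chunk = df.iloc[idx]
        co = (chunk["in_oct"] / chunk["v_oct"]).mean()
        cw = (chunk["in_wat"] / chunk["v_wat"]).mean()
        if co > 0 and cw > 0:
            vals.append(math.log10(co / cw))
    err = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
    if c_oct == 0.0 and c_wat == 0.0:
        raise ParameterError("no solute observations in either phase")
    if c_wat == 0.0:
        # all mass in octanol: report a lower bound from one virtual count
        c_wat_min = 1.0 / (len(df) * df["v_wat"].mean())
        return LogPEstimate(None, err, c_oct, 0.0,
                            bound=f">= {math.log10(c_oct / c_wat_min):.2f}",
                            per_frame=df)
    if c_oct == 0.0:
        c_oct_min = 1.0 / (len(df) * df["v_oct"].mean())
        return LogPEstimate(None, err, 0.0, c_wat,
                            bound=f"<= {math.log10(c_oct_min / c_wat):.2f}",
                            per_frame=df)
    return LogPEstimate(float(math.log10(c_oct / c_wat)), err, c_oct, c_wat,
                        per_frame=df)
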