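"""Frame-level analysis pipeline and the concentration phase scan.

`analyse_frame` turns one configuration into the evidence the classifier
needs: order tensor of the hydrophobic density isosurface, aggregate
partition, aggregate shape classes and the positional-order score of the
micelle centroids.  `phase_scan` orchestrates a run-and-classify sweep over
a weight-percent grid (the production protocol: 81000-bead boxes, >= 2e5
DPD time units per point, with optional midpoint refinement at detected
transitions), and supports a dry-run mode that only reports the planned
simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mesophase as mp
from . import micelles as mi
from .engine import Simulation, SimulationConfig, SystemState, Trajectory
from .errors import DpdsurfError
from .forcefield import ForceField
from .topology import Topology, build_cnem


@dataclass
class FrameAnalysis:
    order: mp.OrderTensor
    aggregates: mi.AggregateSet
    summary: mp.AggregateSummary


def analyse_frame(
    positions: np.ndarray,
    box: np.ndarray,
    topology: Topology,
    ff: ForceField,
    time: float = 0.0,
    r_cl: float = 1.0,
    n_cut: int = 6,
    spacing: float = 0.25,
    sigma: float = 0.4,
    level: float | None = None,
    with_positional_order: bool = True,
) -> FrameAnalysis:
    """Order tensor + aggregate evidence for a single frame."""
    hyd = topology.hydrophobic_mask(ff)
    species = np.asarray(topology.species_of_molecule)
    surf_mols = np.flatnonzero(species != "water")
    field = mp.density_field(positions[hyd], box, spacing=spacing, sigma=sigma)
    order = mp.isosurface_moment(field, level=level, time=time)
    aggs = mi.cluster_frame(positions, box, topology.molecule_ids, hyd,
                            surf_mols, r_cl=r_cl, time=time, n_cut=n_cut)
    sizes = aggs.sizes
    largest = int(sizes.argmax())
    largest_mols = aggs.members(largest)
    sel = hyd & np.isin(topology.molecule_ids, largest_mols)
    largest_frac = float(sizes.max() / sizes.sum())
    spans = mp.spans_box(positions[sel], box, r_cl)
    shapes = []
    order_ids = np.argsort(sizes)[::-1]
    for a in order_ids[:8]:
        if sizes[a] <= n_cut:
            continue
        m_sel = hyd & np.isin(topology.molecule_ids, aggs.members(int(a)))
        shapes.append(mp.shape_class(positions[m_sel], box))
    score = None
    micellar = np.flatnonzero(sizes > n_cut)
    if with_positional_order and len(micellar) >= 4 and largest_frac < 0.5:
        cents = mi.aggregate_centroids(aggs, positions, box,
                                       topology.molecule_ids, hyd)
        cents = cents[micellar]
        score = mp.positional_order_score(cents, box)
    summary = mp.AggregateSummary(
        n_aggregates=int(len(sizes)),
        n_molecules=int(sizes.sum()),
        largest_fraction=largest_frac,
        largest_spans_box=bool(spans),
        shape_classes=shapes,
        positional_order=score,
    )
    return FrameAnalysis(order=order, aggregates=aggs, summary=summary)


def classify_state(
    state: SystemState, topology: Topology, ff: ForceField, **kw
) -> mp.PhaseCall:
    """One-frame classification (no equilibration test): fixture workflows."""
    fa = analyse_frame(state.positions, state.box, topology, ff,
                       time=state.time, **kw)
    return mp.classify_frame(fa.order.eigenvalues, fa.summary)


@dataclass
class ScanPoint:
    wt_pct: float
    planned_steps: int
    total_beads: int
    label: str | None = None
    error: str | None = None
    evidence: dict = field(default_factory=dict)


@dataclass
class PhaseScanProtocol:
    """Protocol constants for one scan (defaults = the production protocol)."""

    total_beads: int = 81000
    duration_tau: float = 2.0e5  # minimum production per concentration
    equilibration_tau: float = 1.0e5
    frame_every_tau: float = 10.0
    pressure: float = 23.7
    refine_transitions: bool = True


def phase_scan(
    n: int,
    m: int,
    wt_grid: list[float],
    ff: ForceField,
    protocol: PhaseScanProtocol | None = None,
    seed: int = 0,
    dry_run: bool = False,
) -> pd.DataFrame:
    """Run-and-classify sweep over surfactant concentration.

    With ``dry_run=True`` no dynamics is executed; the returned table lists
    the planned simulations (wt % grid, box sizes, step counts).  Runs are
    independent per point; a failure at one concentration is recorded and
    the scan continues.
    """
    from .topology import WATER, assemble, box_edge_for_density, compose_box, random_initial_state

    proto = protocol or PhaseScanProtocol()
    tpl = build_cnem(n, m)
    points: list[ScanPoint] = []
    steps = int(round((proto.duration_tau + proto.equilibration_tau) / 0.01))
    for wt in wt_grid:
        points.append(ScanPoint(wt, steps, proto.total_beads))
    if dry_run:
        return _scan_table(points)
    for pt in points:
        try:
            comp = compose_box(tpl, pt.wt_pct, total_beads=proto.total_beads)
            top = assemble([(tpl, comp.n_surfactant), (WATER, comp.n_water_beads)], ff)
            st = random_initial_state(top, box_edge_for_density(top.n_beads, 3.0),
                                      seed=seed + int(pt.wt_pct))
            sim = Simulation(st, top, ff, SimulationConfig(
                ensemble="npt", pressure=proto.pressure, seed=seed + int(pt.wt_pct)))
            eq_steps = int(round(proto.equilibration_tau / sim.config.dt))
            sim.run(eq_steps)
            tensors = []
            frame_steps = int(round(proto.frame_every_tau / sim.config.dt))
            n_frames = int(round(proto.duration_tau / proto.frame_every_tau))
            last_fa = None
            for _ in range(n_frames):
                sim.run(frame_steps)
                last_fa = analyse_frame(sim.state.positions, sim.state.box,
                                        top, ff, time=sim.state.time)
                tensors.append(last_fa.order)
            series = mp.eigen_series(tensors)
            call = mp.classify(series, last_fa.summary)
            pt.label = call.label
            pt.evidence = call.evidence
        except DpdsurfError as exc:
            pt.error = str(exc)
    return _scan_table(points)


def _scan_table(points: list[ScanPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "wt_pct": p.wt_pct,
                "steps": p.planned_steps,
                "total_beads": p.total_beads,
                "label": p.label,
                "error": p.error,
                **{f"ev_{k}": str(v) for k, v in p.evidence.items()},
            }
            for p in points
        ]
    )
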