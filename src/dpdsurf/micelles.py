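"""Aggregate detection, size statistics, CMC and equilibration monitoring.

Two surfactant molecules belong to the same aggregate when any pair of
their hydrophobic beads (CH3, CH2CH2) lies within the contact cutoff r_cl
(default 1.0 r_c) under minimum image, transitively closed.  Aggregates
with N <= N_cut (default 6) count as "free" surfactant -- monomers and
submicellar aggregates -- and the steady-state free-surfactant weight
fraction is the CMC estimate.  The weight-average aggregation number is

    N_agg = sum N^2 p(N) / sum N p(N)   over N > N_cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import NotEquilibratedError, ParameterError
from .topology import WATER_BEAD_MASS, Topology


@dataclass
class AggregateSet:
    """Partition of surfactant molecules into aggregates at one frame."""

    time: float
    labels: np.ndarray  # (n_molecules,) aggregate id per surfactant molecule
    molecule_indices: np.ndarray  # global molecule ids, aligned with labels
    n_cut: int = 6
    r_cl: float = 1.0

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)

    @property
    def n_aggregates(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def members(self, agg_id: int) -> np.ndarray:
        return self.molecule_indices[self.labels == agg_id]


def cluster_frame(
    positions: np.ndarray,
    box: np.ndarray,
    molecule_ids: np.ndarray,
    hydrophobic_mask: np.ndarray,
    surfactant_molecules: np.ndarray,
    r_cl: float = 1.0,
    time: float = 0.0,
    n_cut: int = 6,
) -> AggregateSet:
    """Single-linkage clustering of surfactant molecules by tail contacts.

    Parameters
    ----------
    surfactant_molecules
        Sorted array of molecule ids that are surfactant (clustered); other
        molecules (water, solutes) are ignored.
    """
    if r_cl <= 0:
        raise ParameterError("contact cutoff r_cl must be positive")
    if len(surfactant_molecules) == 0:
        raise ParameterError("no surfactant molecules in frame")
    surf_set = np.asarray(surfactant_molecules)
    mol_to_row = {int(m): i for i, m in enumerate(surf_set)}
    sel = hydrophobic_mask & np.isin(molecule_ids, surf_set)
    pts = positions[sel] % box
    mols = molecule_ids[sel]
    n = len(surf_set)
    if len(pts) == 0:
        labels = np.arange(n)
        return AggregateSet(time, labels, surf_set, n_cut, r_cl)
    # periodic KD-tree needs points strictly inside the box
    eps = 1e-9
    pts = np.clip(pts, 0.0, np.asarray(box) * (1 - eps))
    tree = cKDTree(pts, boxsize=box)
    pairs = tree.query_pairs(r_cl, output_type="ndarray")
    rows_i = np.array([mol_to_row[int(m)] for m in mols[pairs[:, 0]]]) if len(pairs) else np.empty(0, int)
    rows_j = np.array([mol_to_row[int(m)] for m in mols[pairs[:, 1]]]) if len(pairs) else np.empty(0, int)
    adj = coo_matrix(
        (np.ones(len(rows_i)), (rows_i, rows_j)), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return AggregateSet(time, labels, surf_set, n_cut, r_cl)


def aggregation_stats(sizes: np.ndarray, n_cut: int = 6):
    """(N_agg, N_mic, p(N)) with sums restricted to N > N_cut.

    N_agg is None (undefined, not zero) when no aggregate exceeds N_cut.
    """
    sizes = np.asarray([s for s in np.asarray(sizes).ravel() if s > 0], dtype=int)
    if sizes.size == 0:
        raise ParameterError("empty aggregate size list")
    hist = np.bincount(sizes)
    p_of_n = hist / hist.sum()
    micellar = sizes[sizes > n_cut]
    n_mic = len(micellar)
    if n_mic == 0:
        return None, 0, p_of_n
    n_agg = float((micellar.astype(float) ** 2).sum() / micellar.sum())
    return n_agg, n_mic, p_of_n


@dataclass
class MicelleReport:
    """Steady-state micelle statistics over an equilibrated window."""

    series: pd.DataFrame  # per-frame time, n_mic, n_agg, free_wt_pct
    cmc_wt_pct: float
    cmc_error: float
    n_agg: float | None
    window_start: float
    size_histogram: np.ndarray


def frame_statistics(
    aggset: AggregateSet,
    surfactant_molar_mass: float,
    n_water_beads: int,
) -> dict:
    """Per-frame micelle count, N_agg and free-surfactant weight percent."""
    sizes = aggset.sizes
    n_agg, n_mic, _ = aggregation_stats(sizes, aggset.n_cut)
    free_mols = int(sizes[sizes <= aggset.n_cut].sum())
    total_mols = int(sizes.sum())
    m_free = free_mols * surfactant_molar_mass
    m_total = total_mols * surfactant_molar_mass + n_water_beads * WATER_BEAD_MASS
    return {
        "time": aggset.time,
        "n_mic": n_mic,
        "n_agg": np.nan if n_agg is None else n_agg,
        "free_wt_pct": 100.0 * m_free / m_total,
        "n_free": free_mols,
    }


def block_means(values: np.ndarray, times: np.ndarray, block: float) -> np.ndarray:
    """Means of non-overlapping time blocks of width ``block``."""
    t0 = times.min()
    idx = np.floor((times - t0) / block).astype(int)
    out = []
    for b in range(idx.max() + 1):
        m = idx == b
        if m.any():
            out.append(values[m].mean())
    return np.asarray(out)


def detect_steady_state(
    values: np.ndarray, times: np.ndarray, block: float = 1.0e4
) -> float | None:
    """Onset of the steady-state window from non-overlapping block averages.

    The mean of the tail half of the blocks serves as the steady-state
    reference.  The series is judged drifting (returns None) when the first
    and last tail blocks differ significantly; otherwise the onset is the
    first block from which every later block mean stays within tolerance
    (3x the larger of the within-block standard error and the tail block
    scatter) of the reference.
    """
    if times.max() - times.min() < 2 * block:
        raise ParameterError("series shorter than two blocks")
    t0 = times.min()
    idx = np.floor((times - t0) / block).astype(int)
    nblocks = idx.max() + 1
    means, errs = [], []
    for b in range(nblocks):
        m = idx == b
        v = values[m]
        means.append(v.mean())
        errs.append(v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0)
    means = np.asarray(means)
    errs = np.asarray(errs)
    tail_n = max(2, nblocks // 2)
    tail = means[-tail_n:]
    mu_t = tail.mean()
    s_t = tail.std(ddof=1)
    # drift across the tail itself means no steady state was reached
    drift = abs(tail[-1] - tail[0])
    if drift > 3.0 * max(np.hypot(errs[-1], errs[-tail_n]), 1e-12):
        return None
    tol = 3.0 * np.maximum(np.maximum(errs, s_t), 1e-12)
    dev = np.abs(means - mu_t)
    ok = dev <= tol
    for b in range(nblocks):
        if ok[b:].all():
            return t0 + b * block
    return None


def free_surfactant_wt(
    series: pd.DataFrame,
    block: float = 1.0e4,
    window_start: float | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float, float]:
    """(CMC wt %, block-bootstrap error, window start) from a frame series.

    Refuses (NotEquilibratedError) when the free-surfactant concentration
    has not reached a steady state.
    """
    t = series["time"].to_numpy()
    v = series["free_wt_pct"].to_numpy()
    if window_start is None:
        window_start = detect_steady_state(v, t, block)
        if window_start is None:
            raise NotEquilibratedError(
                "free-surfactant concentration is still drifting; not equilibrated"
            )
    m = t >= window_start
    bm = block_means(v[m], t[m], block)
    rng = np.random.default_rng(seed)
    if len(bm) > 1:
        boots = rng.choice(bm, size=(n_boot, len(bm)), replace=True).mean(axis=1)
        err = float(boots.std(ddof=1))
    else:
        err = float("nan")
    return float(v[m].mean()), err, float(window_start)


@dataclass
class EquilibrationReport:
    time_to_steady: dict  # per-observable steady-state onset (None if drifting)
    fusion_fission_events: int
    blocks: float


def equilibration_report(
    series: pd.DataFrame, block: float = 1.0e4
) -> EquilibrationReport:
    """Time-to-steady-state per observable plus micelle-count change events."""
    t = series["time"].to_numpy()
    onsets = {}
    for col in ("n_mic", "n_agg", "free_wt_pct"):
        if col not in series:
            continue
        v = series[col].to_numpy(dtype=float)
        good = np.isfinite(v)
        if good.sum() < 2:
            onsets[col] = None
            continue
        onsets[col] = detect_steady_state(v[good], t[good], block)
    events = 0
    if "n_mic" in series:
        nm = series["n_mic"].to_numpy()
        events = int(np.count_nonzero(np.diff(nm)))
    return EquilibrationReport(onsets, events, block)


def brute_force_cluster(
    positions: np.ndarray,
    box: np.ndarray,
    molecule_ids: np.ndarray,
    hydrophobic_mask: np.ndarray,
    surfactant_molecules: np.ndarray,
    r_cl: float = 1.0,
) -> np.ndarray:
    """O(n^2) union-find oracle returning the same canonical labels."""
    surf = np.asarray(surfactant_molecules)
    mol_to_row = {int(m): i for i, m in enumerate(surf)}
    sel = np.flatnonzero(hydrophobic_mask & np.isin(molecule_ids, surf))
    parent = np.arange(len(surf))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(len(sel)):
        for b in range(a + 1, len(sel)):
            i, j = sel[a], sel[b]
            d = positions[i] - positions[j]
            d -= box * np.rint(d / box)
            if (d @ d) <= r_cl * r_cl:
                ra, rb = find(mol_to_row[int(molecule_ids[i])]), find(
                    mol_to_row[int(molecule_ids[j])]
                )
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(i) for i in range(len(surf))])
    return canonical_labels(roots)


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel cluster ids in order of first appearance."""
    seen: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, l in enumerate(labels):
        out[i] = seen.setdefault(int(l), len(seen))
    return out


def aggregate_centroids(
    aggset: AggregateSet,
    positions: np.ndarray,
    box: np.ndarray,
    molecule_ids: np.ndarray,
    hydrophobic_mask: np.ndarray,
) -> np.ndarray:
    """Unwrapped tail-bead centroid of every aggregate (compact clusters)."""
    from .mesophase import unwrap_cluster

    cents = []
    for a in range(aggset.n_aggregates):
        mols = aggset.members(a)
        sel = hydrophobic_mask & np.isin(molecule_ids, mols)
        pts = unwrap_cluster(positions[sel], box)
        cents.append(pts.mean(axis=0) % box)
    return np.asarray(cents)
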