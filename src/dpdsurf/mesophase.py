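"""Mesophase identification from isosurface-normal statistics.

The hydrophobic (alkane) beads are deposited on a periodic grid, smeared
with a Gaussian, and an isosurface is triangulated through the resulting
density field.  The area-weighted second moment of the isosurface normal
distribution,

    M = <n n>_p,   tr M = 1,

has an eigenvalue pattern (mu_1 <= mu_2 <= mu_3) that fingerprints the
mesophase: (1/3, 1/3, 1/3) for isotropic structures, (~0, 1/2, 1/2) for
hexagonal cylinders, (0, 0, ~1) for lamellae.  Classification combines the
eigenvalue pattern with aggregate count/shape and, for the cubic micellar
phase, a positional-order score on the micelle centroids, since micellar
cubic and isotropic micellar phases share near-equal eigenvalues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as _skmeasure

from .errors import NotEquilibratedError, ParameterError


# ---------------------------------------------------------------------------
# density field
# ---------------------------------------------------------------------------

@dataclass
class DensityField:
    """Gaussian-smeared bead density on a periodic grid (units: beads/r_c^3)."""

    values: np.ndarray  # (nx, ny, nz)
    box: np.ndarray  # (3,)
    spacing: np.ndarray  # (3,) actual spacing per axis
    sigma: float

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacing))

    def integral(self) -> float:
        return float(self.values.sum() * self.cell_volume)


def density_field(
    positions: np.ndarray,
    box: np.ndarray,
    spacing: float = 0.25,
    sigma: float = 0.4,
) -> DensityField:
    """Deposit beads on a periodic grid and smear with a Gaussian.

    ``spacing`` is a target; the actual spacing per axis is the nearest value
    that divides the box edge exactly.  Deposition is cloud-in-cell
    (trilinear), smoothing is a wrapped Gaussian filter; both conserve mass,
    so the field integrates to the bead count.
    """
    if spacing <= 0 or sigma <= 0:
        raise ParameterError("spacing and sigma must be positive")
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ParameterError("empty bead selection")
    box = np.asarray(box, dtype=float)
    shape = np.maximum(2, np.rint(box / spacing).astype(int))
    actual = box / shape
    grid = np.zeros(shape)
    frac = (positions % box) / box * shape  # in cell units
    base = np.floor(frac - 0.5).astype(int)
    t = frac - 0.5 - base  # weight toward the upper neighbour
    for dx in (0, 1):
        wx = t[:, 0] if dx else 1 - t[:, 0]
        ix = (base[:, 0] + dx) % shape[0]
        for dy in (0, 1):
            wy = t[:, 1] if dy else 1 - t[:, 1]
            iy = (base[:, 1] + dy) % shape[1]
            for dz in (0, 1):
                wz = t[:, 2] if dz else 1 - t[:, 2]
                iz = (base[:, 2] + dz) % shape[2]
                np.add.at(grid, (ix, iy, iz), wx * wy * wz)
    sig_cells = sigma / actual
    grid = ndimage.gaussian_filter(grid, sigma=sig_cells, mode="wrap")
    grid /= np.prod(actual)  # counts -> number density
    return DensityField(values=grid, box=box, spacing=actual, sigma=sigma)


def default_isolevel(field: DensityField) -> float:
    """Half the bulk in-aggregate density, with the bulk taken as the modal
    field value among cells denser than the global mean."""
    v = field.values.ravel()
    dense = v[v > v.mean()]
    if dense.size == 0:
        return 0.5 * float(v.max())
    hist, edges = np.histogram(dense, bins=64)
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    return 0.5 * mode


# ---------------------------------------------------------------------------
# isosurface second moment
# ---------------------------------------------------------------------------

@dataclass
class OrderTensor:
    """Second moment of the isosurface normal distribution at one frame."""

    M: np.ndarray  # (3,3)
    eigenvalues: np.ndarray  # ascending (mu_1, mu_2, mu_3)
    time: float = 0.0
    area: float = 0.0
    level: float = 0.0


def isosurface_moment(
    field: DensityField, level: float | None = None, time: float = 0.0
) -> OrderTensor:
    """Triangulate the isosurface (periodic-aware) and average n n^T by area."""
    v = field.values
    if level is None:
        level = default_isolevel(field)
    if not (v.min() < level < v.max()):
        raise ParameterError(
            f"isosurface level {level:.4g} outside density range "
            f"[{v.min():.4g}, {v.max():.4g}]"
        )
    padded = np.pad(v, ((0, 1), (0, 1), (0, 1)), mode="wrap")
    verts, faces, _, _ = _skmeasure.marching_cubes(padded, level=level)
    tri = verts[faces] * field.spacing  # to box coordinates
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    good = areas > 1e-12
    n = cross[good] / (2.0 * areas[good, None])
    w = areas[good]
    M = np.einsum("f,fi,fj->ij", w, n, n) / w.sum()
    mu = np.sort(np.linalg.eigvalsh(M))
    return OrderTensor(M=M, eigenvalues=mu, time=time, area=float(w.sum()), level=level)


@dataclass
class OrderSeries:
    """Per-frame eigenvalues plus running averages over a fixed time window."""

    times: np.ndarray
    raw: np.ndarray  # (nframes, 3) ascending eigenvalues
    smoothed: np.ndarray  # (nframes, 3) running averages
    window: float
    single_window: bool = False  # True when the window exceeded the series

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time": self.times,
                "mu1": self.raw[:, 0], "mu2": self.raw[:, 1], "mu3": self.raw[:, 2],
                "mu1_avg": self.smoothed[:, 0],
                "mu2_avg": self.smoothed[:, 1],
                "mu3_avg": self.smoothed[:, 2],
            }
        )
        return df

    def tail_mean(self, fraction: float = 0.25) -> np.ndarray:
        n = max(1, int(len(self.times) * fraction))
        return self.raw[-n:].mean(axis=0)


def eigen_series(tensors: list[OrderTensor], window: float = 100.0) -> OrderSeries:
    """Running-average eigenvalue series (window in DPD time units)."""
    if not tensors:
        raise ParameterError("need at least one frame")
    times = np.array([t.time for t in tensors])
    raw = np.array([t.eigenvalues for t in tensors])
    smoothed = np.empty_like(raw)
    single = times[-1] - times[0] < window
    for i, t in enumerate(times):
        mask = (times > t - window) & (times <= t)
        smoothed[i] = raw[mask].mean(axis=0)
    if single:
        smoothed[:] = raw.mean(axis=0)
    return OrderSeries(times=times, raw=raw, smoothed=smoothed, window=window,
                       single_window=single)


# ---------------------------------------------------------------------------
# aggregate geometry helpers
# ---------------------------------------------------------------------------

def unwrap_cluster(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Remove periodic jumps within one compact aggregate (minimum-image
    growth from the first bead; adequate for non-percolating clusters)."""
    out = positions.copy()
    ref = out[0].copy()
    for i in range(1, len(out)):
        d = out[i] - ref
        out[i] -= box * np.rint(d / box)
        ref = out[: i + 1].mean(axis=0)
    return out


def gyration_eigenvalues(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Ascending eigenvalues of the gyration tensor of one aggregate."""
    p = unwrap_cluster(positions, box)
    c = p - p.mean(axis=0)
    g = c.T @ c / len(c)
    return np.sort(np.linalg.eigvalsh(g))


def shape_class(
    positions: np.ndarray,
    box: np.ndarray,
    rod_ratio: float = 4.0,
    slab_ratio: float = 4.0,
) -> str:
    """'spherical' | 'rod' | 'slab' from gyration-eigenvalue ratios."""
    lam = gyration_eigenvalues(positions, box)
    lam = np.maximum(lam, 1e-12)
    if lam[2] / lam[1] >= rod_ratio:
        return "rod"
    if lam[1] / lam[0] >= slab_ratio and lam[2] / lam[1] < rod_ratio:
        return "slab"
    return "spherical"


def spans_box(positions: np.ndarray, box: np.ndarray, r_cl: float = 1.0) -> bool:
    """True when the aggregate percolates the box along any axis."""
    p = positions % box
    for ax in range(3):
        nbins = max(3, int(box[ax] / r_cl))
        occ = np.zeros(nbins, dtype=bool)
        occ[(p[:, ax] / box[ax] * nbins).astype(int) % nbins] = True
        if occ.all():
            return True
    return False


def positional_order_score(
    centroids: np.ndarray, box: np.ndarray, kmax: int = 6
) -> float:
    """Height of the tallest off-zero structure-factor peak of the micelle
    centroids, normalized by the centroid count (1 = perfect lattice)."""
    n = len(centroids)
    if n < 2:
        return 0.0
    best = 0.0
    ks = range(-kmax, kmax + 1)
    for hx in ks:
        for hy in ks:
            for hz in ks:
                if hx == hy == hz == 0 or (hx, hy, hz) < (-hx, -hy, -hz):
                    continue
                k = 2.0 * np.pi * np.array([hx, hy, hz]) / box
                s = np.abs(np.exp(1j * centroids @ k).sum()) ** 2 / n
                best = max(best, float(s / n))
    return best


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

PHASE_LABELS = ("L1_low", "L1_high", "I1", "H1", "V1_transitional", "L_alpha")


@dataclass
class PhaseCall:
    label: str
    evidence: dict = field(default_factory=dict)


@dataclass
class ClassifierThresholds:
    """Soft thresholds; the eigenvalue patterns are approximate by design."""

    lamellar_mu3: float = 0.75
    lamellar_mu2: float = 0.15
    hexagonal_mu1: float = 0.18
    hexagonal_split: float = 0.15  # max |mu2 - mu3| for H1
    isotropic_spread: float = 0.12  # max mu3 - mu1 for near-equal eigenvalues
    positional_order: float = 0.5
    space_filling_fraction: float = 0.5


def classify_frame(
    mu: np.ndarray,
    aggregates: "AggregateSummary | None" = None,
    thresholds: ClassifierThresholds | None = None,
) -> PhaseCall:
    """Classify one (equilibrated) eigenvalue triple with aggregate evidence."""
    th = thresholds or ClassifierThresholds()
    mu = np.sort(np.asarray(mu, dtype=float))
    ev: dict = {"eigenvalues": mu.tolist()}
    if aggregates is not None:
        ev.update(aggregates.as_evidence())
    if mu[2] >= th.lamellar_mu3 and mu[1] <= th.lamellar_mu2:
        return PhaseCall("L_alpha", ev)
    if mu[0] <= th.hexagonal_mu1 and abs(mu[2] - mu[1]) <= th.hexagonal_split and mu[1] >= 0.3:
        return PhaseCall("H1", ev)
    if mu[2] - mu[0] <= th.isotropic_spread:
        if aggregates is None:
            return PhaseCall("L1_low", ev)
        if aggregates.space_filling_single(th.space_filling_fraction):
            return PhaseCall("L1_high", ev)
        score = aggregates.positional_order
        ev["positional_order_score"] = score
        if score is not None and score >= th.positional_order:
            return PhaseCall("I1", ev)
        return PhaseCall("L1_low", ev)
    return PhaseCall("V1_transitional", ev)


@dataclass
class AggregateSummary:
    """Aggregate-level evidence used alongside the eigenvalue pattern."""

    n_aggregates: int
    n_molecules: int
    largest_fraction: float
    largest_spans_box: bool
    shape_classes: list[str]
    positional_order: float | None = None

    def space_filling_single(self, fraction: float) -> bool:
        return self.largest_fraction >= fraction and self.largest_spans_box

    def as_evidence(self) -> dict:
        return {
            "n_aggregates": self.n_aggregates,
            "largest_fraction": self.largest_fraction,
            "largest_spans_box": self.largest_spans_box,
            "shape_classes": self.shape_classes[:8],
        }


def check_equilibrated(
    series: OrderSeries, tail_fraction: float = 0.5, drift_tol: float = 0.05
) -> None:
    """Refuse classification when the smoothed eigenvalues still drift.

    Drift = difference of the first- and second-half means of the tail of
    the smoothed series, per eigenvalue.
    """
    n = len(series.times)
    tail = series.smoothed[int(n * (1 - tail_fraction)):]
    if len(tail) < 2:
        return
    h = len(tail) // 2
    drift = np.abs(tail[:h].mean(axis=0) - tail[h:].mean(axis=0)).max()
    if drift > drift_tol:
        raise NotEquilibratedError(
            f"eigenvalue running averages drift by {drift:.3f} (> {drift_tol}); "
            "extend the trajectory before classifying"
        )


def classify(
    series: OrderSeries,
    aggregates: AggregateSummary | None = None,
    thresholds: ClassifierThresholds | None = None,
    drift_tol: float = 0.05,
) -> PhaseCall:
    """Equilibration-checked classification of an eigenvalue time series."""
    check_equilibrated(series, drift_tol=drift_tol)
    return classify_frame(series.tail_mean(), aggregates, thresholds)
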