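"""Density field, isosurface order tensor, and phase classification."""

import numpy as np
import pytest

from dpdsurf import mesophase as mp
from dpdsurf.errors import NotEquilibratedError, ParameterError
from dpdsurf.fixtures import FixtureSpec, generate
from dpdsurf.phasescan import analyse_frame, classify_state


@pytest.fixture(scope="module")
def lamellar(ff):
    return generate(FixtureSpec("ideal_lamellar", seed=1), ff)


@pytest.fixture(scope="module")
def hexagonal(ff):
    return generate(FixtureSpec("ideal_hexagonal", seed=1), ff)


@pytest.fixture(scope="module")
def micellar_fcc(ff):
    return generate(FixtureSpec("micellar_fcc", seed=1), ff)


@pytest.fixture(scope="module")
def micellar_random(ff):
    return generate(FixtureSpec("micellar_random", seed=1), ff)


def _field(state, top, ff):
    hyd = top.hydrophobic_mask(ff)
    return mp.density_field(state.positions[hyd], state.box)


# ---------------------------------------------------------------------------
# density field
# ---------------------------------------------------------------------------

def test_single_bead_field_peaks_at_bead(ff):
    box = np.array([8.0, 8.0, 8.0])
    fld = mp.density_field(np.array([[4.0, 4.0, 4.0]]), box)
    idx = np.unravel_index(np.argmax(fld.values), fld.values.shape)
    center = (idx + np.full(3, 0.5)) * fld.spacing
    assert np.allclose(center, 4.0, atol=0.3)
    assert fld.integral() == pytest.approx(1.0, abs=1e-6)


def test_field_mass_conservation(lamellar, ff):
    state, top = lamellar
    hyd = top.hydrophobic_mask(ff)
    fld = mp.density_field(state.positions[hyd], state.box)
    assert fld.integral() / hyd.sum() == pytest.approx(1.0, abs=1e-6)


def test_smoothing_limit_flattens_uniform_beads(ff):
    rng = np.random.default_rng(0)
    box = np.array([8.0, 8.0, 8.0])
    pts = rng.random((2000, 3)) * box
    cv = []
    for sigma in (0.4, 1.5):
        fld = mp.density_field(pts, box, sigma=sigma)
        cv.append(fld.values.std() / fld.values.mean())
    assert cv[1] < 0.3 * cv[0]


def test_field_parameter_validation():
    with pytest.raises(ParameterError):
        mp.density_field(np.zeros((1, 3)), np.ones(3), spacing=-0.1)
    with pytest.raises(ParameterError):
        mp.density_field(np.zeros((1, 3)), np.ones(3), sigma=0.0)
    with pytest.raises(ParameterError):
        mp.density_field(np.zeros((0, 3)), np.ones(3))


# ---------------------------------------------------------------------------
# order tensor signatures (the phase taxonomy's ideal limits)
# ---------------------------------------------------------------------------

def test_slab_signature(lamellar, ff):
    state, top = lamellar
    mu = mp.isosurface_moment(_field(state, top, ff)).eigenvalues
    assert mu == pytest.approx([0.0, 0.0, 1.0], abs=0.05)


def test_cylinder_signature(hexagonal, ff):
    state, top = hexagonal
    mu = mp.isosurface_moment(_field(state, top, ff)).eigenvalues
    assert mu == pytest.approx([0.0, 0.5, 0.5], abs=0.05)


def test_sphere_signature(micellar_fcc, ff):
    state, top = micellar_fcc
    mu = mp.isosurface_moment(_field(state, top, ff)).eigenvalues
    assert mu == pytest.approx([1 / 3, 1 / 3, 1 / 3], abs=0.05)


def test_trace_is_unity(lamellar, hexagonal, micellar_fcc, ff):
    for state, top in (lamellar, hexagonal, micellar_fcc):
        ot = mp.isosurface_moment(_field(state, top, ff))
        assert np.trace(ot.M) == pytest.approx(1.0, abs=1e-6)
        assert ot.eigenvalues.sum() == pytest.approx(1.0, abs=1e-6)
        assert (ot.eigenvalues >= -1e-9).all() and (ot.eigenvalues <= 1 + 1e-9).all()


def test_eigenvalues_invariant_under_rotation(lamellar, ff):
    state, top = lamellar
    hyd = top.hydrophobic_mask(ff)
    pos = state.positions[hyd]
    mu0 = mp.isosurface_moment(mp.density_field(pos, state.box)).eigenvalues
    # rotate the configuration 90 degrees about x (z -> y)
    rot = pos[:, [0, 2, 1]].copy()
    rot[:, 2] = state.box[2] - rot[:, 2]
    box_r = state.box[[0, 2, 1]]
    mu1 = mp.isosurface_moment(mp.density_field(rot, box_r)).eigenvalues
    assert mu1 == pytest.approx(mu0, abs=0.02)


def test_level_outside_range_raises(lamellar, ff):
    state, top = lamellar
    fld = _field(state, top, ff)
    with pytest.raises(ParameterError, match="outside density range"):
        mp.isosurface_moment(fld, level=fld.values.max() * 2)


# ---------------------------------------------------------------------------
# eigenvalue time series
# ---------------------------------------------------------------------------

def _tensor(mu, t):
    return mp.OrderTensor(M=np.diag(mu), eigenvalues=np.sort(mu), time=t)


def test_running_average_of_constant_series_is_raw():
    ts = [_tensor(np.array([0.1, 0.3, 0.6]), t) for t in np.arange(0, 500, 10)]
    s = mp.eigen_series(ts, window=100.0)
    assert np.allclose(s.smoothed, s.raw)


def test_window_longer_than_series_is_flagged():
    ts = [_tensor(np.array([0.1, 0.3, 0.6]), t) for t in (0.0, 10.0)]
    s = mp.eigen_series(ts, window=100.0)
    assert s.single_window
    assert np.allclose(s.smoothed[0], s.raw.mean(axis=0))


def test_alternating_series_averages_to_midpoint():
    mus = [np.array([0.2, 0.3, 0.5]), np.array([0.4, 0.3, 0.3])]
    ts = [_tensor(mus[i % 2], float(i)) for i in range(200)]
    s = mp.eigen_series(ts, window=10.0)
    assert s.smoothed[-1] == pytest.approx((np.sort(mus[0]) + np.sort(mus[1])) / 2,
                                           abs=1e-12)


def test_drifting_series_refuses_classification():
    ts = [_tensor(np.array([1 / 3 - t / 3000, 1 / 3, 1 / 3 + t / 3000]), t)
          for t in np.arange(0, 1000, 10.0)]
    s = mp.eigen_series(ts)
    with pytest.raises(NotEquilibratedError):
        mp.classify(s)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_classifier_reproduces_taxonomy_on_ideal_fixtures(
    ff, lamellar, hexagonal, micellar_fcc, micellar_random
):
    expectations = [
        (lamellar, "L_alpha"),
        (hexagonal, "H1"),
        (micellar_fcc, "I1"),
        (micellar_random, "L1_low"),
    ]
    for (state, top), expected in expectations:
        call = classify_state(state, top, ff)
        assert call.label == expected, call.evidence


def test_positional_order_separates_fcc_from_random(
    ff, micellar_fcc, micellar_random
):
    scores = {}
    for name, (state, top) in [("fcc", micellar_fcc), ("random", micellar_random)]:
        fa = analyse_frame(state.positions, state.box, top, ff)
        scores[name] = fa.summary.positional_order
    assert scores["fcc"] > 0.8
    assert scores["random"] < 0.5


def test_space_filling_single_aggregate_reads_as_concentrated_isotropic():
    summary = mp.AggregateSummary(
        n_aggregates=1, n_molecules=500, largest_fraction=1.0,
        largest_spans_box=True, shape_classes=["spherical"],
    )
    call = mp.classify_frame(np.array([0.33, 0.33, 0.34]), summary)
    assert call.label == "L1_high"


def test_transitional_pattern_falls_through():
    call = mp.classify_frame(np.array([0.10, 0.30, 0.60]))
    assert call.label == "V1_transitional"


def test_aggregate_shape_classes(ff, lamellar, hexagonal, micellar_fcc):
    state, top = hexagonal
    fa = analyse_frame(state.positions, state.box, top, ff)
    assert set(fa.summary.shape_classes) == {"rod"}
    state, top = lamellar
    fa = analyse_frame(state.positions, state.box, top, ff)
    assert fa.summary.shape_classes[0] == "slab"
    state, top = micellar_fcc
    fa = analyse_frame(state.positions, state.box, top, ff)
    assert set(fa.summary.shape_classes) == {"spherical"}
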