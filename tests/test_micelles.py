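"""Aggregate clustering, size statistics and CMC machinery."""

import numpy as np
import pandas as pd
import pytest

from dpdsurf import micelles as mi
from dpdsurf.errors import NotEquilibratedError, ParameterError
from dpdsurf.fixtures import FixtureSpec, generate


def _toy_frame(mol_positions, box):
    """Molecules of one hydrophobic bead each at given positions."""
    pos = np.asarray(mol_positions, dtype=float)
    n = len(pos)
    return dict(
        positions=pos,
        box=np.asarray(box, dtype=float),
        molecule_ids=np.arange(n),
        hydrophobic_mask=np.ones(n, dtype=bool),
        surfactant_molecules=np.arange(n),
    )


def test_distant_molecules_are_singletons():
    f = _toy_frame([[1, 1, 1], [9, 9, 9]], [20, 20, 20])
    aggs = mi.cluster_frame(**f)
    assert aggs.n_aggregates == 2
    assert sorted(aggs.sizes) == [1, 1]


def test_transitive_closure_joins_chain_of_contacts():
    # A near B, B near C, A far from C -> one aggregate {A, B, C}
    f = _toy_frame([[1.0, 1, 1], [1.9, 1, 1], [2.8, 1, 1]], [20, 20, 20])
    aggs = mi.cluster_frame(**f)
    assert aggs.n_aggregates == 1 and aggs.sizes[0] == 3


def test_clustering_respects_periodic_images():
    f = _toy_frame([[0.2, 1, 1], [19.9, 1, 1]], [20, 20, 20])
    aggs = mi.cluster_frame(**f)
    assert aggs.n_aggregates == 1


def test_invalid_cutoff_rejected():
    f = _toy_frame([[1, 1, 1]], [10, 10, 10])
    f["r_cl"] = -1.0
    with pytest.raises(ParameterError):
        mi.cluster_frame(**f)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_clustering_matches_brute_force_oracle(ff, seed):
    # 50 random surfactant molecules, realistic bead structure
    rng = np.random.default_rng(seed)
    from dpdsurf.topology import assemble, build_cnem, random_initial_state

    tpl = build_cnem(8, 4)
    top = assemble({tpl: 50}, ff)
    st = random_initial_state(top, 10.0, seed=seed)
    # compact the molecules randomly to create nontrivial clusters
    st.positions[:, :] *= 0.8
    hyd = top.hydrophobic_mask(ff)
    surf = np.arange(50)
    fast = mi.cluster_frame(st.positions, st.box, top.molecule_ids, hyd, surf,
                            r_cl=1.0)
    slow = mi.brute_force_cluster(st.positions, st.box, top.molecule_ids, hyd,
                                  surf, r_cl=1.0)
    assert np.array_equal(mi.canonical_labels(fast.labels), slow)
    # partition property: every molecule in exactly one aggregate
    assert fast.sizes.sum() == 50


def test_partition_covers_fixture_micelles(ff):
    state, top = generate(FixtureSpec("micellar_fcc", seed=1), ff)
    species = np.asarray(top.species_of_molecule)
    surf = np.flatnonzero(species != "water")
    aggs = mi.cluster_frame(state.positions, state.box, top.molecule_ids,
                            top.hydrophobic_mask(ff), surf)
    assert aggs.sizes.sum() == len(surf)
    assert aggs.n_aggregates == 32  # 2x2x2 FCC cells x 4 basis sites


@pytest.mark.parametrize(
    "sizes, expected",
    [([10, 10], 10.0), ([8, 12], 10.4), ([3, 5, 10], 10.0)],
)
def test_weight_average_aggregation_number(sizes, expected):
    n_agg, n_mic, p = mi.aggregation_stats(np.array(sizes), n_cut=6)
    assert n_agg == pytest.approx(expected)
    # independent check straight from the histogram definition
    ns = np.arange(len(p))
    mask = ns > 6
    direct = (ns[mask] ** 2 * p[mask]).sum() / (ns[mask] * p[mask]).sum()
    assert n_agg == pytest.approx(direct)


def test_no_micelle_reports_undefined_not_zero():
    n_agg, n_mic, _ = mi.aggregation_stats(np.array([1, 2, 3]), n_cut=6)
    assert n_agg is None and n_mic == 0


def test_frame_statistics_mass_conservation():
    aggs = mi.AggregateSet(
        time=0.0, labels=np.array([0, 0, 0, 0, 0, 0, 0, 1, 2]),
        molecule_indices=np.arange(9),
    )
    stats = mi.frame_statistics(aggs, surfactant_molar_mass=450.65, n_water_beads=1000)
    # one 7-mer micelle + two free monomers
    m_total = 9 * 450.65 + 1000 * 36.03
    assert stats["free_wt_pct"] == pytest.approx(100 * 2 * 450.65 / m_total)
    assert stats["n_mic"] == 1 and stats["n_agg"] == pytest.approx(7.0)


def _series(values, dt=500.0):
    t = np.arange(len(values)) * dt
    return pd.DataFrame({"time": t, "free_wt_pct": values})


def test_cmc_of_all_monomeric_series_is_total():
    s = _series(np.full(100, 0.744))
    cmc, err, start = mi.free_surfactant_wt(s)
    assert cmc == pytest.approx(0.744)
    assert start == 0.0


def test_cmc_zero_when_everything_micellar():
    s = _series(np.zeros(100))
    cmc, _, _ = mi.free_surfactant_wt(s)
    assert cmc == 0.0


def test_drifting_cmc_series_is_refused():
    s = _series(np.linspace(1.0, 0.1, 100))
    with pytest.raises(NotEquilibratedError):
        mi.free_surfactant_wt(s)


def test_steady_state_detection_finds_step():
    rng = np.random.default_rng(0)
    vals = np.concatenate([
        np.full(40, 1.0), np.full(160, 0.3)
    ]) + rng.normal(scale=0.01, size=200)
    t = np.arange(200) * 500.0
    onset = mi.detect_steady_state(vals, t, block=1.0e4)
    assert onset == pytest.approx(2.0e4, abs=1.01e4)


def test_equilibration_report_on_synthetic_series():
    rng = np.random.default_rng(1)
    n = 200
    t = np.arange(n) * 500.0
    df = pd.DataFrame({
        "time": t,
        "n_mic": np.concatenate([np.full(50, 8), np.full(n - 50, 4)]),
        "n_agg": np.full(n, 30.0) + rng.normal(scale=0.1, size=n),
        "free_wt_pct": np.full(n, 0.25) + rng.normal(scale=0.005, size=n),
    })
    rep = mi.equilibration_report(df)
    assert rep.time_to_steady["free_wt_pct"] == 0.0
    assert rep.time_to_steady["n_mic"] == pytest.approx(2.5e4, abs=1.01e4)
    assert rep.fusion_fission_events == 1


def test_equilibration_report_needs_two_blocks():
    df = pd.DataFrame({"time": [0.0, 100.0], "n_mic": [1, 1],
                       "n_agg": [5.0, 5.0], "free_wt_pct": [0.1, 0.1]})
    with pytest.raises(ParameterError):
        mi.equilibration_report(df)
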