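"""Aggregate detection and micelle statistics on a synthetic configuration.

Clusters a box of pre-built spherical micelles by hydrophobic-bead contacts
(single linkage, cutoff 1 r_c) and reports the aggregate-size distribution,
the micelle count and the weight-average aggregation number
N_agg = sum N^2 p(N) / sum N p(N) over micelles (N > N_cut = 6).
"""

import numpy as np

from dpdsurf import micelles as mi
from dpdsurf.fixtures import FixtureSpec, generate
from dpdsurf.forcefield import load_forcefield

ff = load_forcefield()
state, top = generate(FixtureSpec("micellar_random", seed=2), ff)
species = np.asarray(top.species_of_molecule)
surf = np.flatnonzero(species != "water")
aggs = mi.cluster_frame(state.positions, state.box, top.molecule_ids,
                        top.hydrophobic_mask(ff), surf, r_cl=1.0)
n_agg, n_mic, p_of_n = mi.aggregation_stats(aggs.sizes, n_cut=6)
print(f"{len(surf)} surfactant molecules -> {aggs.n_aggregates} aggregates")
print(f"micelles (N > 6): {n_mic},  N_agg = {n_agg:.1f}")
sizes = aggs.sizes
print(f"size range: {sizes.min()}..{sizes.max()}")
print("N_agg is the weight average, i.e. the mean micelle size a molecule")
print("finds itself in; the fixture builds 30-molecule micelles, so ~30.")
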