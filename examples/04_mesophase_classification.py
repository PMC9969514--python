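"""Mesophase fingerprints from isosurface normals.

For each ideal structure the hydrophobic density field is triangulated at
an isosurface and the second moment M = <n n> of the facet normals is
diagonalised.  The eigenvalue pattern identifies the phase:
lamellar (0,0,1), hexagonal (0, 1/2, 1/2), micellar (1/3, 1/3, 1/3); the
cubic micellar phase I1 is separated from the dilute isotropic phase by
positional order of the micelle centroids.
"""

import numpy as np

from dpdsurf.fixtures import FixtureSpec, generate
from dpdsurf.forcefield import load_forcefield
from dpdsurf.phasescan import analyse_frame, classify_state

ff = load_forcefield()
for kind in ("ideal_lamellar", "ideal_hexagonal", "micellar_fcc", "micellar_random"):
    state, top = generate(FixtureSpec(kind, seed=1), ff)
    fa = analyse_frame(state.positions, state.box, top, ff)
    call = classify_state(state, top, ff)
    mu = np.round(fa.order.eigenvalues, 3)
    score = fa.summary.positional_order
    extra = f", positional order {score:.2f}" if score is not None else ""
    print(f"{kind:18s} mu = {mu}  ->  {call.label}{extra}")
print("\nThe two micellar boxes have identical eigenvalues; only the")
print("structure-factor peak of the centroids tells the cubic (I1) lattice")
print("from the disordered micellar liquid (L1).")
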