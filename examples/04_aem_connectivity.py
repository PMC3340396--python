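"""Asymmetric eigenvector maps from the directional station graph.

Builds the sites x edges incidence matrix (which upstream edges influence
each station), extracts orthonormal spatial eigenfunctions by SVD, and
forward-selects the ones a response actually loads on.
"""

import numpy as np

from riverscape import synthetic as syn
from riverscape.aem import aem_basis_from_graph, select_eigenvectors

river = syn.simulate_river(syn.demo_config(seed=42))
basis = aem_basis_from_graph(river.graph)
print(f"{len(basis.sites)} stations -> {basis.k} AEM eigenfunctions")
print("leading singular values:", np.round(basis.singular_values[:5], 2))

y = np.log(river.station_table["cyano_euk"].to_numpy())
sel = select_eigenvectors(basis, y, alpha=0.05, n_permutations=199, seed=42)
print(f"\nretained for ln(cyano/euk): {sel.indices}")
print("cumulative adjusted R^2:", np.round(sel.cum_adj_r2, 3))
print(
    "\nEigenfunction 1 is the broad downstream gradient; later ones encode "
    "finer\nconnectivity structure. The retained set is the spatial model "
    "used as covariates\nin the partitioning stage."
)
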