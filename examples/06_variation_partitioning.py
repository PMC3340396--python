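"""Spatial vs environmental variation partitioning and lmg importance.

Splits the explained variance of ln(cyano/euk) between the retained AEM
eigenfunctions (upstream connectivity) and local environmental predictors,
then ranks the environmental predictors by lmg shares once the spatial
signal has been removed from both sides (despatialized importance).
"""

import numpy as np
import pandas as pd

from riverscape import synthetic as syn
from riverscape.aem import aem_basis_from_graph, select_eigenvectors
from riverscape.partition import despatialized_importance, partition

river = syn.simulate_river(syn.demo_config(seed=42, n_transects=40, rho=0.6))
t = river.station_table
y = np.log(t["cyano_euk"].to_numpy())
X_env = pd.DataFrame({"blue_red": np.log(t["blue_red"]), "srp": np.log(t["srp"])})

basis = aem_basis_from_graph(river.graph)
sel = select_eigenvectors(basis, y, n_permutations=199, seed=42)
X_sp = basis.vectors[:, sel.indices]

venn = partition(y, X_sp, X_env.to_numpy(), adjusted=True)
print("Venn fractions (adjusted R^2):")
print(f"  pure environmental {venn.pure_environmental:6.3f}")
print(f"  pure spatial       {venn.pure_spatial:6.3f}")
print(f"  shared             {venn.shared:6.3f}")
print(f"  residual           {venn.residual:6.3f}")

imp = despatialized_importance(y, X_sp, X_env)
print("\nDespatialized lmg shares (% of the environmental fraction):")
for name, pct in zip(imp.predictors, imp.pct_of_environmental):
    print(f"  {name:<10} {pct:5.1f}%")
print(
    "\nThe shared fraction is environmental signal that is itself spatially "
    "structured\n(advected from upstream); the pure spatial fraction here "
    "comes from the rho=0.6\nspatially propagated community noise."
)
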