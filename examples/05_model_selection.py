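"""Best-subsets regression with AIC ranking for the community ratio.

After VIF screening, an exhaustive search returns the minimum-RSS predictor
subset of each size; the Akaike Information Criterion then arbitrates
across sizes (delta_i = AIC - min AIC, with delta_i <= 2 conventionally
indistinguishable from the best model).
"""

import numpy as np
import pandas as pd

from riverscape import synthetic as syn
from riverscape.selection import aic_rank, best_subsets, vif_screen

river = syn.simulate_river(syn.demo_config(seed=42, n_transects=30))
t = river.station_table

X = pd.DataFrame(
    {
        "ln_blue_red": np.log(t["blue_red"]),
        "ln_green_red": np.log(t["green_red"]),
        "ln_srp": np.log(t["srp"]),
        "tripton": t["tripton"],
    }
)
y = np.log(t["cyano_euk"].to_numpy())

vif = vif_screen(X, threshold=5.0)
print("VIF screening dropped:", vif.dropped or "nothing")

ranked = aic_rank(list(best_subsets(X[vif.retained], y, max_size=3).values()))
for mfit in ranked:
    print(
        f"  {' + '.join(mfit.predictors):<38} AIC {mfit.aic:8.2f}  "
        f"delta {mfit.delta_i:6.2f}  R2 {mfit.r2:.3f}"
    )
print(
    "\nIn this river the two color ratios and SRP are nearly collinear — "
    "the same\ntributaries set all three — so screening keeps one color "
    "ratio and the search\nranks it top, matching the planted response "
    "structure."
)
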