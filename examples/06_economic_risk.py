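"""Municipality-level economic risk from concentration indices.

Computes the location quotient (specialization), modified
Hirschman-Herfindahl index (concentration), and relative participation
(national share) for each municipality, combines them into the
PCA-weighted normalized Concentration Index (nCI), and crosses five
Jenks classes of nCI with five classes of mean climate suitability in
the two-dimensional risk matrix.
"""

import warnings

import numpy as np
import pandas as pd

import riskpipe as rp
from riskpipe import synthetic as syn

warnings.filterwarnings("ignore")

# production table: 3 of 25 municipalities hold 70% of national value
table = syn.generate_production_table(25, 3, 0.7, seed=45)
indices, theta = rp.economic_indices(table)
print(f"PCA weights theta (LQ, RP, HHI): {np.round(theta, 3)} (sum 1)")
print("top municipalities by nCI:")
print(indices.nlargest(3, "nCI").round(3).to_string(index=False))
print(f"conservation: sum RP = {indices.RP.sum():.12f}, "
      f"sum HHI = {indices.HHI.sum():.2e}")

# mean suitability per municipality from a fitted map
spec = syn.WorldSpec(n_rows=60, n_cols=60, cell_size_deg=0.1,
                     origin_lon=-55.0, origin_lat=-20.0, n_predictors=5,
                     smoothness=5.0, seed=42)
stack = syn.generate_climate_stack(spec)
niche = syn.NicheSpec(optimum=(0.6, 0.0, -0.4, 0.2, 0.0),
                      tolerance=(0.8, 1.2, 1.0, 1.5, 2.5), max_prob=0.9)
occ = syn.sample_presences(syn.generate_virtual_species(stack, niche),
                           200, seed=43)
zones = syn.generate_zone_raster(stack, 4, seed=44)
bg = rp.select_background(occ, zones, stack, n_points=2000, seed=46)
model = rp.fit_occurrence_model(occ, bg, stack, classes="LQ",
                                reg_multiplier=1.0)
suitability = rp.predict_surface(model, stack, "cloglog")

ancillary = syn.generate_ancillary_surfaces(spec, seed=46, n_muni_x=5,
                                            n_muni_y=5)
zonal = rp.zonal_mean(suitability, ancillary.municipalities)
risk = rp.classify_economic_risk(
    zonal.set_index("muni_id")["mean_suitability"],
    indices.set_index("muni_id")["nCI"],
)
print(risk["risk_level"].value_counts().to_string())
print("risk level = mean of the suitability class (1-5) and nCI class "
      "(1-5): very low <=1.5 < low <=2.0 < moderate <=3.0 < high")
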