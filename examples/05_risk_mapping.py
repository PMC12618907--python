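"""Combine suitability with introduction likelihood and classify the map.

The invasion-risk surface is the cellwise product of the (cloglog)
suitability map and a min-max normalized introduction-likelihood layer;
the suitability map is then split into four Jenks natural-breaks
classes and intersected with plantation polygons.
"""

import warnings

import numpy as np

import riskpipe as rp
from riskpipe import synthetic as syn

warnings.filterwarnings("ignore")

spec = syn.WorldSpec(n_rows=40, n_cols=40, n_predictors=4,
                     smoothness=4.0, seed=1)
stack = syn.generate_climate_stack(spec)
niche = syn.NicheSpec(optimum=(0.5, 0.0, -0.3, 0.1),
                      tolerance=(1.0, 1.5, 1.2, 2.0), max_prob=0.9)
occ = syn.sample_presences(syn.generate_virtual_species(stack, niche),
                           60, seed=2)
zones = syn.generate_zone_raster(stack, 3, seed=3)
background = rp.select_background(occ, zones, stack, n_points=800, seed=4)
masked = rp.crop_mask(stack, background)
model = rp.fit_occurrence_model(occ, background, masked, classes="LQ",
                                reg_multiplier=1.0)
suitability = rp.predict_surface(model, stack, "cloglog")

ancillary = syn.generate_ancillary_surfaces(spec, seed=8)
intro = rp.normalize_surface(ancillary.introduction)
risk = rp.invasion_risk(suitability, intro)
print(f"suitability range {np.nanmin(suitability.data):.3f}.."
      f"{np.nanmax(suitability.data):.3f}; introduction normalized to [0,1]")
print(f"invasion risk = product, range {np.nanmin(risk.data):.3f}.."
      f"{np.nanmax(risk.data):.3f} (high only where both factors are high)")

class_map = rp.classify(suitability, k=4)
print("Jenks breaks:", np.round(class_map.breaks, 3),
      "-> classes", class_map.label_names)
print("cells per class:", class_map.class_counts())

overlap = rp.plantation_overlap(class_map, ancillary.plantations)
print(overlap.to_string(index=False))
print("area_fraction = share of plantation cells in each suitability "
      "class (sums to 1)")
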