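"""Spatially thin occurrence records and delimit the training background.

Thinning enforces a 20-km minimum great-circle distance between records
(the standard guard against spatial autocorrelation in presence-only
data); the background is the union of climate zones holding at least
one occurrence, from which background points are drawn uniformly.
"""

import riskpipe as rp
from riskpipe import synthetic as syn

spec = syn.WorldSpec(n_rows=60, n_cols=60, cell_size_deg=0.1,
                     origin_lon=-55.0, origin_lat=-20.0, n_predictors=5,
                     smoothness=5.0, seed=42)
stack = syn.generate_climate_stack(spec)
niche = syn.NicheSpec(optimum=(0.6, 0.0, -0.4, 0.2, 0.0),
                      tolerance=(0.8, 1.2, 1.0, 1.5, 2.5), max_prob=0.9)
occ_raw = syn.sample_presences(syn.generate_virtual_species(stack, niche),
                               300, seed=43)
zones = syn.generate_zone_raster(stack, 4, seed=44)

occ = rp.thin_occurrences(
    occ_raw, rp.ThinningConfig(min_distance_km=20.0, n_replicates=10, seed=7)
)
rep = occ.thinning_report
print(f"thinning: {rep['n_input']} -> {rep['n_retained']} records "
      f"(min distance {rep['min_distance_km']} km, method {rep['method']})")
if rep["replicate_retention_counts"]:
    print(f"replicate retention counts: {rep['replicate_retention_counts']}")

background = rp.select_background(occ, zones, stack, n_points=2000, seed=8)
print(f"occupied zones: {sorted(background.selected_zone_ids)} "
      f"of {len(zones.zone_ids())}; background mask covers "
      f"{background.mask.sum()} cells, {background.n_background_points} "
      "points sampled")
print("a record pair closer than 20 km would violate the thinning "
      "postcondition; the retained count is the largest subset satisfying it")
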