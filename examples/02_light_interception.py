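"""Trace a sky dome over a canopy and read the energy budget.

Builds a 40-day canopy, a Hannover spring sky (half diffuse, half
direct), and traces 50k rays. Every ray ends absorbed by a leaflet,
absorbed by the ground, escaped, or cut off at the scatter-depth limit,
so the budget closes exactly.
"""

import saltcanopy as sc

params = sc.GrowthParams()
climate = sc.generate_climate(40, regime="LT", seed=1)
canopy = sc.init_canopy(params, seed=0)
for day in climate:
    sc.step_day(canopy, day, sc.Treatment("LT", 0.0), params)

mesh = sc.to_mesh(canopy)
sky = sc.build_sky(latitude=52.38, longitude=9.62, day_of_year=130,
                   diffuse_fraction=0.5)
amap = sc.trace(mesh, sky, n_rays=50_000, seed=7, daily_par_mj=8.0)

inc = amap.incident
print(f"leaf absorption   {100 * amap.leaf_absorbed / inc:5.1f} % of emitted")
print(f"ground absorption {100 * amap.ground_absorbed / inc:5.1f} %")
print(f"escaped           {100 * amap.escaped / inc:5.1f} %")
print(f"depth residual    {100 * amap.residual / inc:5.1f} %")
print(f"budget closure error: {amap.energy_residual():.2e} (exact bookkeeping)")
print(f"canopy transmittance Q_T/Q_0 = {sc.canopy_transmittance(amap):.3f}")
# Transmittance is the flux density reaching the ground relative to the
# flux incident above the canopy: ~1 for a bare plot, ->0 as the canopy
# closes.
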