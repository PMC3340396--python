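"""Structural riverscape indices from the bundled PDZ morphometry table.

Mean depth (volume/area), confluence density (tributaries per km of
channel), cumulated watershed area in flow order, and wetland proportion
for six physical discontinuity zones of a large river.
"""

from riverscape import metrics as m

report = m.pdz_report()
cols = [
    "pdz", "mean_depth_m", "confluence_density",
    "cumulated_watershed_km2", "wetland_pct",
]
print(report[cols].round(3).to_string(index=False))
print(
    "\nFluvial lakes are shallow (3-5 m) with dense tributary confluences; "
    "the estuary\nsegments are deep with sparse inflows. Cumulated watershed "
    "area grows monotonically\ndownstream as each zone adds its drainage."
)
print(f"\nTHI for a 500 m^3/s tributary entering the 3.11 m deep lake: "
      f"{m.thi(500.0, 3.11):.0f}")
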