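"""Generate a small synthetic river and inspect the downstream mixing.

Five tributaries with contrasting source waters (brownwater, agricultural,
clear) attach along a 16-transect main stem; conservative discharge-weighted
mixing propagates CDOM, tripton and SRP downstream.
"""

from riverscape import synthetic as syn

cfg = syn.demo_config(seed=42)
river = syn.simulate_river(cfg)

t = river.station_table
print(f"{len(t)} stations, {river.graph.number_of_edges()} directed edges")
print("\nDownstream of the first brownwater tributary (lane 0):")
lane0 = t[t["lane"] == 0][["station", "transect", "acdom340", "srp", "blue_red"]]
print(lane0.head(8).to_string(index=False))
print(
    "\naCDOM340 (m^-1) jumps where the tributary attaches and dilutes "
    "downstream;\nthe blue/red penetration ratio falls as CDOM rises — "
    "stained water turns red."
)
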