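"""Vegetation response index from raw pollen counts.

The VRI contrasts shade-tolerant (Pseudotsuga, Notholithocarpus) against
shade-intolerant (Quercus, Pinus) pollen: positive = closed canopy,
negative = open canopy. Computed here for a hand-made three-layer core.
"""

from sedfire.chronology import AgeDepthModel
from sedfire.influx import LayerSample
from sedfire.vegindex import vri_series


def layer(depth, counts):
    return LayerSample(depth=depth, volume=0.625, taxon_counts=counts,
                       tracer_counted=150, tracer_added=20_000)


model = AgeDepthModel(depths=[0.0, 30.0], ages=[-58.0, 542.0])
core = [
    layer(5.0, {"Pseudotsuga": 45, "Notholithocarpus": 20,
                "Quercus": 10, "Pinus": 15}),   # closed modern canopy
    layer(15.0, {"Pseudotsuga": 20, "Notholithocarpus": 15,
                 "Quercus": 25, "Pinus": 30}),  # mixed
    layer(25.0, {"Pseudotsuga": 8, "Notholithocarpus": 7,
                 "Quercus": 35, "Pinus": 40}),  # open, fire-maintained
]
series = vri_series(core, model=model)

print(f"{'age calBP':>10} {'VRI':>7}  interpretation")
for age, v in zip(series.ages, series.values):
    state = "closed canopy" if v > 0 else "open canopy"
    print(f"{age:10.0f} {v:7.2f}  {state}")
# The downcore trend from negative to positive VRI mirrors the shift from a
# frequently burned, open forest to a dense fire-suppressed one.
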