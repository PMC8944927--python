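import numpy as np
import pytest

from sedfire.chronology import AgeDepthModel
from sedfire.firehistory import FireScarDataset, TreeRecord
from sedfire.influx import LayerSample


@pytest.fixture
def linear_model():
    """Uniform chronology: 100 cm over 1000 years, top at -58 calBP."""
    return AgeDepthModel(depths=np.array([0.0, 100.0]),
                         ages=np.array([-58.0, 942.0]))


@pytest.fixture
def uneven_model():
    """Four segments with hand-computable slopes (yr/cm): 5, 10, 20, 40."""
    return AgeDepthModel(depths=np.array([0.0, 20.0, 50.0, 80.0, 100.0]),
                         ages=np.array([0.0, 100.0, 400.0, 1000.0, 1800.0]))


@pytest.fixture
def toy_layer():
    """The worked tracer example: 50 grains vs 100 tracer spores from a
    20,000-spore spike in 0.625 cm3 -> 16,000 grains/cm3."""
    return LayerSample(depth=10.0, volume=0.625,
                       taxon_counts={"Pinus": 50, "Quercus": 0},
                       tracer_counted=100, tracer_added=20_000,
                       charcoal_count=120)


@pytest.fixture
def three_tree_dataset():
    """Trees A{1700,1720,1750}, B{1720,1750,1790}, C{1750}, all spanning
    1690-1800; the (2,2) composite is {1720, 1750}."""
    return FireScarDataset(trees=(
        TreeRecord("A", "PSME", 1690, 1800,
                   {1700: "latewood", 1720: "dormant", 1750: "latewood"}),
        TreeRecord("B", "PILA", 1690, 1800,
                   {1720: "latewood", 1750: "dormant", 1790: "late-earlywood"}),
        TreeRecord("C", "PSME", 1690, 1800, {1750: "latewood"}),
    ))


# ---- independent brute-force oracles (kept dead simple on purpose) --------

def brute_composite(trees, min_trees, min_depth, recording="span"):
    """Exhaustive year-by-year enumeration of a composite chronology."""
    years = range(min(t.inner_year for t in trees),
                  max(t.outer_year for t in trees) + 1)
    out = []
    for y in years:
        scarred = sum(y in t.scars for t in trees)
        if recording == "span":
            depth = sum(t.inner_year <= y <= t.outer_year for t in trees)
        else:
            depth = sum(t.scars and min(t.scars) <= y <= t.outer_year for t in trees)
        if scarred >= min_trees and depth >= min_depth:
            out.append(y)
    return out


def brute_median(values):
    """Sort-and-pick median, mean of middle two when even."""
    s = sorted(values)
    n = len(s)
    if n == 0:
        return None
    if n % 2:
        return float(s[n // 2])
    return (s[n // 2 - 1] + s[n // 2]) / 2.0


def brute_pearson(x, y):
    """Textbook Pearson r."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
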