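import numpy as np
import pytest

from sarpheno.descriptors import compute_descriptor_field
from sarpheno.phenology import StageRules, build_time_series
from sarpheno.preprocess import PreprocessConfig, preprocess_scene
from sarpheno.raster_io import RadarScene
from sarpheno.synthetic import make_plot_layout, simulate_campaign
from sarpheno.zoning import assign_zones, derive_zone_thresholds


@pytest.fixture(scope="session")
def thresholds():
    return derive_zone_thresholds()


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def homogeneous_scene():
    """10x10 scene with vv = 1, vh = 0.1 everywhere (q = 0.1)."""
    shape = (10, 10)
    return RadarScene(
        vv=np.full(shape, 1.0),
        vh=np.full(shape, 0.1),
        mask=np.ones(shape, bool),
        doy=126,
        scene_id="homog",
    )


@pytest.fixture(scope="session")
def small_campaign(thresholds):
    """A small simulated season run through the full chain once.

    100x160 grid (12 plots of ~1,300 px), 13 dates, L = 9, 5x5 boxcar.
    Returns (truth, series, triples, layout).
    """
    layout = make_plot_layout(shape=(100, 160))
    scenes, truth = simulate_campaign(layout=layout, looks=9, seed=11)
    triples = []
    for doy, scene in scenes:
        pre = preprocess_scene(scene, PreprocessConfig())
        dfield = compute_descriptor_field(pre)
        triples.append((doy, dfield, assign_zones(dfield, thresholds)))
    regions = {str(p): layout.plot_mask(p) for p in layout.plot_ids}
    series = build_time_series(triples, regions, rules=StageRules())
    return truth, series, triples, layout
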