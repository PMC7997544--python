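import numpy as np
import pytest

from vogquant import ConstructModel, FieldParams, RunConfig, simulate_field
from vogquant.pipeline import deconvolve_and_project, detect_channels


@pytest.fixture(scope="session")
def standard_field():
    """One default-condition VOG field: gag-anchored green label at 85%
    incorporation plus the mature-capsid reference stain."""
    params = FieldParams(seed=1)
    construct = ConstructModel(name="optiGag-IN", channel="green", incorporation_prob=0.85)
    field, truth = simulate_field(params, [construct])
    return params, field, truth


@pytest.fixture(scope="session")
def standard_detections(standard_field):
    """Deconvolved, projected and detected channels of the standard field."""
    params, field, truth = standard_field
    cfg = RunConfig()
    projected = deconvolve_and_project(field, cfg)
    tables = detect_channels(projected, field.pixel_size_um, cfg)
    return field, truth, projected, tables


def interior_truth(truth, field, channel, margin_px=3.5):
    """Ground-truth particles emitting in a channel, away from the border."""
    m = margin_px * field.pixel_size_um
    sel = truth[truth[f"photons_{channel}"] > 0]
    return sel[
        (sel.x_um > m)
        & (sel.x_um < field.width_um - m)
        & (sel.y_um > m)
        & (sel.y_um < field.height_um - m)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
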