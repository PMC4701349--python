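"""Shared fixtures: templates, trained classifiers and rendered cards.

Everything is generated programmatically and seeded; heavyweight pieces
(classifier training, template ORB extraction) are session-scoped.
"""

import numpy as np
import pytest

from lfareader import (
    CardGeometry,
    build_template,
    generate_card_image,
    generate_histogram_dataset,
    generate_template_image,
)
from lfareader.mlp import train
from lfareader.pipeline import PanelConfig, ReaderModels
from lfareader.synthetic import CardSpec

PANEL4 = ("AMP", "KET", "COC", "MET")
PANEL_ALC = ("OPI", "THC", "ALC")

# dataset sizes mirroring the published evaluation splits
N_ALCOHOL = 338
N_CONTROL = 2358
N_TESTLINE = 1955


@pytest.fixture(scope="session")
def geometry():
    return CardGeometry()


@pytest.fixture(scope="session")
def template4():
    image, quad = generate_template_image(PANEL4)
    return image, quad, build_template(image, quad)


@pytest.fixture(scope="session")
def template_alc():
    image, quad = generate_template_image(PANEL_ALC)
    return image, quad, build_template(image, quad)


@pytest.fixture(scope="session")
def alcohol_dataset():
    return generate_histogram_dataset("alcohol", N_ALCOHOL, seed=11)


@pytest.fixture(scope="session")
def control_dataset():
    return generate_histogram_dataset("control", N_CONTROL, seed=12)


@pytest.fixture(scope="session")
def testline_dataset():
    return generate_histogram_dataset("testline", N_TESTLINE, seed=13)


@pytest.fixture(scope="session")
def trained(alcohol_dataset, control_dataset, testline_dataset):
    """Models + per-split evaluation reports for all three classifiers."""
    out = {}
    for kind, ds in [("alcohol", alcohol_dataset), ("control", control_dataset),
                     ("testline", testline_dataset)]:
        model, reports = train(ds, kind, seed=1)
        out[kind] = (model, reports)
    return out


@pytest.fixture(scope="session")
def reader_models(trained):
    return ReaderModels(control=trained["control"][0],
                        testline=trained["testline"][0],
                        alcohol=trained["alcohol"][0])


@pytest.fixture(scope="session")
def panel4_config():
    return PanelConfig(PANEL4)


@pytest.fixture(scope="session")
def panel_alc_config():
    return PanelConfig(PANEL_ALC)


def render_roi(spec: CardSpec, geometry: CardGeometry | None = None):
    """Render a card with zero pose and crop the strip region directly.

    Bypasses registration so segmentation/histogram behaviour can be tested
    in isolation from ORB matching.
    """
    geom = geometry or CardGeometry()
    assert spec.pose == (0.0, 0.0, 0.0)
    image, truth = generate_card_image(spec, geom)
    x0, y0, x1, y1 = geom.roi_rect
    return image[y0:y1, x0:x1], truth


@pytest.fixture(scope="session")
def clean_card_roi():
    """Zero-pose 4-strip card ROI with strong control and test lines."""
    spec = CardSpec(panel=PANEL4,
                    control_intensities=(0.8,) * 4,
                    test_classes=("very_negative",) * 4,
                    illumination_gradient=0.0, noise_sd=0.0,
                    pose=(0.0, 0.0, 0.0), seed=0)
    return render_roi(spec)
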