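import numpy as np
import pytest

from saltcard import default_layout, imaging, quantify, simulate

#: global ladder of standard concentrations (ppm) used to calibrate the
#: bundled card design: dense inside the triplicate 0-35 span, sparser above
STANDARD_PPM = [
    0.5, 1.5, 3, 5, 7, 9, 11, 13, 15, 17, 19, 21, 23, 25, 27, 29,
    31, 33, 35, 37.5, 40, 43, 46, 49,
]


def pipeline_signals(img, layout, scale=imaging.DEFAULT_SCALE):
    """Raw image -> 12 zone signals via the full measurement pipeline."""
    det = imaging.detect_fiducials(img, layout)
    corr = imaging.fit_geometric_correction(det, layout)
    rect = imaging.rectify(img, corr, layout, scale=scale)
    rect, _ = imaging.correct_white_balance(rect, layout)
    return imaging.measure_rois(rect, layout)


def render_standards(layout, chems, ppms=STANDARD_PPM):
    return [
        simulate.render_card(layout, chems, simulate.identity_scenario(c))[0]
        for c in ppms
    ]


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def chems(layout):
    return simulate.default_chemistries(layout)


@pytest.fixture(scope="session")
def standard_images(layout, chems):
    """Noiseless face-on photographs of the calibration ladder."""
    return render_standards(layout, chems)


@pytest.fixture(scope="session")
def curves(layout, standard_images):
    """Calibration fitted from the standard cards."""
    return quantify.calibrate_from_images(
        standard_images, STANDARD_PPM, layout, source="synthetic standards"
    )
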