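import numpy as np
import pytest

from hemaquant import (
    DilutionSeries,
    PixelScale,
    PlateGeometry,
    RenderParams,
    RowSpec,
    render_plate,
)


@pytest.fixture(scope="session")
def demo_layout():
    """Reference plate layout: purified positive control, a raw-bean-like
    powder extract whose 200 ng crossing falls between wells 14 and 15, and
    a PBS negative-control row."""
    return [
        RowSpec(
            "PHA-P",
            "positive_control",
            DilutionSeries(start_conc_ng_per_ul=1040.0, n_wells=24),
        ),
        RowSpec(
            "DRK",
            "sample",
            DilutionSeries.from_w_over_v(10.0, n_wells=24),
            analyte_mass_fraction=0.327,
        ),
        RowSpec("PBS", "negative_control", None),
    ]


@pytest.fixture(scope="session")
def demo_render(demo_layout):
    """Deterministic render of the reference layout (hard positivity step)."""
    return render_plate(demo_layout, params=RenderParams(seed=42, logistic_width=0.0))


@pytest.fixture
def small_geometry():
    return PlateGeometry(n_rows=1, n_cols=2, well_pitch_mm=9.0)


@pytest.fixture
def scale01():
    return PixelScale(0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
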