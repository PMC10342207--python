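import pytest
from hypothesis import settings

from flimpheno import (
    FitConfig,
    PhenotypeSpec,
    CellGeometry,
    ChannelDecaySpec,
    TimeGrid,
    make_irf,
    simulate_field,
)
from flimpheno.features import aggregate_features
from flimpheno.fitting import fit_image
from flimpheno.phasor import phasor_image

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid():
    return TimeGrid()


@pytest.fixture(scope="session")
def irf(grid):
    return make_irf(grid)


@pytest.fixture(scope="session")
def small_phenotype():
    """A compact, bright phenotype used by the image-level fixtures."""
    return PhenotypeSpec(
        name="demo",
        nadph=ChannelDecaySpec(0.7, 0.5, 3.0),
        fad=ChannelDecaySpec(0.75, 0.35, 2.8),
        photons_per_pixel=5000.0,
        background_rate=0.0,
        geometry=CellGeometry(n_cells=6, radius_range=(3.0, 4.0), min_separation=2.0),
    )


@pytest.fixture(scope="session")
def demo_field(grid, irf, small_phenotype):
    return simulate_field([small_phenotype], "demo", (48, 48), grid, seed=42, irf=irf)


@pytest.fixture(scope="session")
def demo_analysis(grid, irf, demo_field):
    """Fit and phasor maps plus the aggregated feature table for one field."""
    cfg = FitConfig()
    fit_n = fit_image(demo_field.nadph, irf, cfg)
    fit_f = fit_image(demo_field.fad, irf, cfg)
    ph_n = phasor_image(demo_field.nadph, irf)
    ph_f = phasor_image(demo_field.fad, irf)
    table = aggregate_features(
        fit_n, fit_f, ph_n, ph_f, demo_field.mask, group="demo", field_id=0
    )
    return {
        "fit_nadph": fit_n,
        "fit_fad": fit_f,
        "ph_nadph": ph_n,
        "ph_fad": ph_f,
        "table": table,
    }


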