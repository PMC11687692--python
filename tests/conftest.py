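import numpy as np
import pandas as pd
import pytest

from floeseal import SceneSpec, SegmentedModelSpec, simulate_survey_table


@pytest.fixture(scope="session")
def ref_model() -> SegmentedModelSpec:
    """The reference haul-out model used as simulation truth."""
    return SegmentedModelSpec.default()


@pytest.fixture(scope="session")
def survey_10k(ref_model) -> pd.DataFrame:
    """A mid-sized simulated survey shared across read-only tests."""
    return simulate_survey_table(10_000, ref_model, seed=42)


@pytest.fixture(scope="session")
def small_scene():
    """A small full scene (floes + rasters + colonies) at coarse resolution."""
    from floeseal.synth import gen_bathymetry, gen_colonies, gen_floe_field

    spec = SceneSpec(width=4000, height=4000, pixel_size=8.0, n_floes=120,
                     size_meanlog=np.log(40.0), size_sdlog=1.2,
                     max_area=3000.0, seed=11)
    floes, mask = gen_floe_field(spec)
    bathy = gen_bathymetry(spec, shape=mask.shape)
    colonies = gen_colonies(spec)
    return spec, floes, mask, bathy, colonies


NB_NAMES = ["const", "rough_1000", "sic_750", "colony_dist"]


def nb_design(df: pd.DataFrame, cols=("rough_1000", "sic_750", "colony_dist")):
    """Intercept + covariate design matrix from a survey table."""
    return np.column_stack([np.ones(len(df))] +
                           [df[c].to_numpy(dtype=float) for c in cols])
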