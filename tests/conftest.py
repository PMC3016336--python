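import datetime

import numpy as np
import pandas as pd
import pytest

from pyresed.chemistry import load_properties
from pyresed.field_model import ErosionConfig, FieldConfig, FieldState, build_column
from pyresed.scenario import generate_weather


@pytest.fixture(scope="session")
def props():
    return load_properties()


@pytest.fixture(scope="session")
def bifenthrin(props):
    return props["bifenthrin"]


def make_field_state(
    compartment_thickness_cm: float,
    mode: str = "improved",
    compounds=("bifenthrin",),
    area_ha: float = 10.0,
    total_depth_cm: float = 2.0,
):
    column = build_column(total_depth_cm, compartment_thickness_cm,
                          list(compounds), area_ha=area_ha)
    config = FieldConfig(field_id="f0", area_ha=area_ha,
                         erosion=ErosionConfig(mode=mode))
    return FieldState(config=config, column=column)


def melon_field_applications(n_years: int, start_year: int = 1990,
                             annual_kg: float = 0.8):
    """Two mid-summer applications per year (melon-type schedule)."""
    apps = {}
    for year in range(start_year, start_year + n_years):
        apps[datetime.date(year, 7, 15)] = [("bifenthrin", annual_kg / 2)]
        apps[datetime.date(year, 8, 15)] = [("bifenthrin", annual_kg / 2)]
    return apps


@pytest.fixture(scope="session")
def three_year_weather():
    return generate_weather(seed=7, n_years=3)


def cumulative_eroded_concentration(thickness_cm, mode, weather, props,
                                    n_years=3):
    """Total eroded pesticide / total eroded soil (g/g) over a multi-event
    field simulation; the summary statistic of the erosion-algorithm
    comparison."""
    from pyresed.field_model import run_field

    state = make_field_state(thickness_cm, mode=mode)
    apps = melon_field_applications(n_years)
    out = run_field(state, weather, apps, props)
    soil_g = out["soil_loss_ton"].sum() * 1e6
    return out["eroded_g"].sum() / soil_g
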