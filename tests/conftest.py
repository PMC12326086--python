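"""Shared fixtures: tiny simulated campaigns and a toy habitat map."""

import json

import numpy as np
import pandas as pd
import pytest

from flocktrace.pipeline import PipelineConfig
from flocktrace.synthetic_data import HOME_SITE, SimConfig, simulate_campaign

#: a short corridor (~2.5 km) for fast end-to-end tests
SHORT_RELEASE = (HOME_SITE[0], HOME_SITE[1] + 0.0225)


def small_config(**overrides) -> SimConfig:
    """Two small flocks, two flights, short corridor."""
    defaults = dict(
        flocks={"L": 3, "N": 4},
        n_flights=2,
        release=SHORT_RELEASE,
        seed=42,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def quiet_config(**overrides) -> SimConfig:
    """Small campaign with every stochastic nuisance disabled."""
    defaults = dict(
        gps_noise_sd_m=0.0, gps_jitter_sd_m=0.0, accel_noise_sd_g=0.0,
        accel_drift_amp_g=0.0,
        wobble_sd={"speed": 0.0, "flap": 0.0},
        bird_intercept_sd={"speed": 0.0, "flap": 0.0},
        loft_intercept_sd={"speed": 0.0, "flap": 0.0},
        flight_effect_sd={"speed": 0.0, "flap": 0.0},
        habitat_speed_offsets={"open": 0.0, "wooded": 0.0, "urban": 0.0},
        habitat_flap_offsets={"open": 0.0, "wooded": 0.0, "urban": 0.0},
        preferred_offset_sd_m=0.0, start_jitter_m=0.0, heading_noise_sd=0.0,
        start_time_jitter_s=0.0, split_probability_per_min=0.0,
    )
    defaults.update(overrides)
    return small_config(**defaults)


@pytest.fixture(scope="session")
def small_campaign():
    return simulate_campaign(small_config())


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig(release=SHORT_RELEASE)


@pytest.fixture()
def square_map_geojson(tmp_path):
    """Two files: one urban square and one wooded square, side 0.01 deg."""

    def square(lon0, lat0, side=0.01):
        return [[[lon0, lat0], [lon0 + side, lat0], [lon0 + side, lat0 + side],
                 [lon0, lat0 + side], [lon0, lat0]]]

    urban = {"type": "FeatureCollection", "features": [
        {"type": "Feature", "properties": {"class": "Built-up Areas and Gardens"},
         "geometry": {"type": "Polygon", "coordinates": square(0.0, 0.0)}},
        {"type": "Feature", "properties": {"class": "Built-up Areas and Gardens"},
         "geometry": {"type": "Polygon", "coordinates": square(0.05, 0.0)}},
        {"type": "Feature", "properties": {"class": "Built-up Areas and Gardens"},
         "geometry": {"type": "Polygon", "coordinates": square(0.10, 0.0)}},
    ]}
    wooded = {"type": "FeatureCollection", "features": [
        {"type": "Feature", "properties": {"class": "Coniferous Woodland"},
         "geometry": {"type": "Polygon", "coordinates": square(0.0, 0.05)}},
        {"type": "Feature", "properties": {"class": "Broadleaved, Mixed, and Yew Woodland"},
         "geometry": {"type": "Polygon", "coordinates": square(0.05, 0.05)}},
    ]}
    paths = []
    for name, coll in (("urban", urban), ("wooded", wooded)):
        p = tmp_path / f"{name}.geojson"
        p.write_text(json.dumps(coll))
        paths.append(p)
    return paths


def make_track_df(rng=None, n_lofts=3, birds_per_loft=8, n_per_bird=60,
                  speed_effects=None, bird_sd=0.3, loft_sd=0.2,
                  resid_sd=0.5):
    """Synthetic per-second track rows with known habitat effects on speed.

    A direct (non-simulator) generator for the mixed-model unit tests.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    speed_effects = speed_effects or {"open": 0.0, "wooded": -0.7, "urban": 0.7}
    rows = []
    for li in range(n_lofts):
        loft = "LNR"[li % 3] + str(li // 3 or "")
        le = rng.normal(0, loft_sd)
        for bi in range(birds_per_loft):
            bird = f"{loft}_{bi:02d}"
            be = rng.normal(0, bird_sd)
            hab = rng.choice(["open", "wooded", "urban"], size=n_per_bird)
            ft = rng.uniform(0, 400, size=n_per_bird)
            it = rng.integers(1, 16, size=n_per_bird)
            y = (17.9 + np.vectorize(speed_effects.get)(hab) + 0.001 * ft
                 + le + be + rng.normal(0, resid_sd, size=n_per_bird))
            for k in range(n_per_bird):
                rows.append(dict(loft_id=loft, bird_id=bird, habitat=hab[k],
                                 flight_time=ft[k], iteration=int(it[k]),
                                 speed=y[k]))
    return pd.DataFrame(rows)
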