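"""Synthetic landscapes, flock flights and logger streams with known truth.

The generator emulates the study design this pipeline targets: three flocks
of 6, 10 and 8 homing pigeons housed in adjacent lofts, each released 15
times over a ~9.6 km corridor whose ground cover is a patchwork of open,
wooded and urban polygons.  Every bird carries a 5 Hz GPS logger and a
100 Hz z-axis accelerometer.

Behaviour model
---------------
Birds fly a correlated random walk with homing bias: each bird steers toward
home plus an attractor at the flock centroid offset by a per-bird preferred
position, which produces cohesive cluster flocking with realistic spread.
Instantaneous speed and flap frequency are

    base + habitat offset + loft intercept + bird intercept + AR(1) wobble,

where the habitat offset follows the ground cover currently under the bird.
The habitat spread multiplier scales preferred offsets (and so realised flock
spread) by ground cover, and an optional iteration trend shrinks or grows
spread across successive flights.  Occasional splits steer a minority
subgroup at least 60 m off-axis for a fixed duration (beyond the 40 m
centroid-exclusion radius) before it rejoins.

Signal model
------------
GPS fixes are true positions plus slowly-drifting (AR(1), ~30 s timescale)
isotropic error — consumer-GPS error wanders rather than flickering, which
matters for differentiated speed.  The accelerometer sees

    z(t) = 1 g + A sin(phi(t)) + drift + white noise,

with the wingbeat phase phi accumulated continuously from the instantaneous
flap frequency so frequency changes never produce phase discontinuities.

Everything is deterministic under ``SimConfig.seed``; per-flight substreams
are derived from (seed, flock, flight) so flights are reproducible
independently of simulation order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .habitat_map import HabitatMap, classify_track, load_habitat_geojson
from .trajectory import M_PER_DEG, project_to_plane, unproject

#: representative fine land-cover class written into the GeoJSON per category,
#: so loading a synthetic landscape exercises the class grouping.
_CATEGORY_SOURCE_CLASSES = {
    "open": ["Improved Grassland", "Arable and Horticultural", "Scrub"],
    "wooded": ["Broadleaved, Mixed, and Yew Woodland", "Coniferous Woodland"],
    "urban": ["Built-up Areas and Gardens"],
}

RELEASE_SITE = (-0.584229, 51.500122)   # lon, lat
HOME_SITE = (-0.572615, 51.415368)


@dataclass
class SimConfig:
    """Simulator parameters; defaults reproduce the study conditions."""

    flocks: dict[str, int] = field(
        default_factory=lambda: {"L": 6, "N": 10, "R": 8})
    n_flights: int = 15
    release: tuple[float, float] = RELEASE_SITE
    home: tuple[float, float] = HOME_SITE
    corridor_width_m: float = 2000.0
    band_length_m: tuple[float, float] = (300.0, 800.0)  # habitat patch extent
    base_speed: float = 17.92            # m/s, mean flight speed
    base_flap: float = 6.93              # Hz, mean flap frequency
    habitat_speed_offsets: dict[str, float] = field(
        default_factory=lambda: {"open": 0.0, "wooded": -0.67, "urban": 0.69})
    habitat_flap_offsets: dict[str, float] = field(
        default_factory=lambda: {"open": 0.0, "wooded": 0.03, "urban": -0.10})
    habitat_spread_multipliers: dict[str, float] = field(
        default_factory=lambda: {"open": 1.0, "wooded": 1.25, "urban": 1.0})
    bird_intercept_sd: dict[str, float] = field(
        default_factory=lambda: {"speed": 0.5, "flap": 0.10})
    loft_intercept_sd: dict[str, float] = field(
        default_factory=lambda: {"speed": 0.5, "flap": 0.12})
    wobble_sd: dict[str, float] = field(
        default_factory=lambda: {"speed": 1.5, "flap": 0.25})
    #: flight-to-flight variation of the whole flock's pace and effort
    #: (wind and daily condition); constant within a flight, so it shifts
    #: all habitats equally and cancels out of habitat contrasts
    flight_effect_sd: dict[str, float] = field(
        default_factory=lambda: {"speed": 0.4, "flap": 0.05})
    wobble_ar_per_s: float = 0.7         # AR(1) coefficient of wobble at 1 s
                                         # (~3 s behavioural timescale)
    preferred_offset_sd_m: float = 4.0   # per-bird preferred offset from centroid
    steering_gain_per_m: float = 0.02    # attractor pull per metre of offset
    station_gain_per_s: float = 0.15     # speed correction per metre of
                                         # along-track offset (station-keeping)
    station_max_ms: float = 2.0          # cap on the station-keeping correction
    station_deadband_m: float = 5.0      # no correction inside this offset;
                                         # birds hold their own pace unless
                                         # genuinely out of station
    start_jitter_m: float = 3.0          # scatter of start positions at release
    start_time_jitter_s: float = 45.0    # loggers run before the birds commit
                                         # to the homing leg (release-box
                                         # opening and circling vary per
                                         # flight), so stream clocks start at
                                         # a uniform random offset
    heading_noise_sd: float = 0.1        # radians per step on travel direction
    tortuosity_sd: float = 0.6           # log-sd of per-bird heading-noise
                                         # multipliers; weaving birds fly a
                                         # longer path at higher ground speed
                                         # while holding station, which is
                                         # what real per-bird speed
                                         # heterogeneity inside a cohesive
                                         # flock looks like
    iteration_spread_trend: float = 0.0  # fractional spread change per flight
    split_probability_per_min: float = 0.05
    split_duration_s: float = 40.0
    split_offset_m: float = 80.0         # lateral attractor during a split
    gps_noise_sd_m: float = 1.5          # slow (AR, ~30 s) position drift
    gps_noise_timescale_s: float = 30.0
    gps_jitter_sd_m: float = 0.45        # white epoch-to-epoch scatter; this
                                         # is what dominates differentiated
                                         # 5 Hz ground speed
    gps_rate_hz: float = 5.0
    accel_rate_hz: float = 100.0
    flap_amplitude_g: float = 1.0
    accel_noise_sd_g: float = 0.1
    accel_drift_amp_g: float = 0.05
    accel_drift_period_s: float = 120.0
    speed_bounds: tuple[float, float] = (5.0, 30.0)
    flap_bounds: tuple[float, float] = (3.0, 12.0)
    start_date: str = "2022-11-10"
    seed: int = 0

    def loft_ids(self) -> list[str]:
        return sorted(self.flocks)

    def bird_ids(self, flock_id: str) -> list[str]:
        return [f"{flock_id}{i + 1:02d}" for i in range(self.flocks[flock_id])]


@dataclass
class FlightData:
    """All logger streams of one flock on one flight."""

    flock_id: str
    flight_date: str
    gps: dict[str, pd.DataFrame]     # bird_id -> (t, lon, lat)
    accel: dict[str, pd.DataFrame]   # bird_id -> (t, z)
    splits: list[dict]


@dataclass
class Campaign:
    """A full simulated release campaign plus its ground truth."""

    config: SimConfig
    landscape: HabitatMap
    landscape_geojson: dict
    flights: list[FlightData]
    ground_truth: dict


# ---------------------------------------------------------------------------
# landscape


def _axis_frame(config: SimConfig):
    """Projected release/home positions and the along/across unit vectors."""
    origin = config.home
    rel = project_to_plane(
        pd.DataFrame({"t": [0.0], "lon": [config.release[0]],
                      "lat": [config.release[1]]}), origin)
    rx, ry = float(rel["x"].iloc[0]), float(rel["y"].iloc[0])
    length = float(np.hypot(rx, ry))
    e_u = np.array([-rx, -ry]) / length     # release -> home direction
    e_v = np.array([e_u[1], -e_u[0]])       # right-hand normal
    return (rx, ry), (0.0, 0.0), e_u, e_v, length


def make_landscape(config: SimConfig, seed: int | None = None
                   ) -> tuple[HabitatMap, dict]:
    """Tile the flight corridor with habitat bands crossing the route.

    Bands are slabs perpendicular to the release-home axis with random
    lengths, categories cycling in a seeded random order; each category
    covers at least 15% of the corridor and a straight release-home segment
    crosses all three.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    release_xy, home_xy, e_u, e_v, length = _axis_frame(config)
    band_length_m = config.band_length_m
    margin = 400.0
    total = length + 2 * margin
    for _ in range(50):
        lengths = []
        while sum(lengths) < total:
            lengths.append(float(rng.uniform(*band_length_m)))
        order = list(rng.permutation(["open", "wooded", "urban"]))
        cats = [order[i % 3] for i in range(len(lengths))]
        cover = {c: 0.0 for c in ("open", "wooded", "urban")}
        for ln, c in zip(lengths, cats):
            cover[c] += ln
        if min(cover.values()) / sum(lengths) >= 0.15:
            break
    else:  # pragma: no cover - uniform draws cannot starve a category 50x
        raise ParameterError("could not tile corridor with 15% coverage each")

    half_w = config.corridor_width_m / 2.0
    features = []
    u0 = -margin
    class_cycle = {c: 0 for c in _CATEGORY_SOURCE_CLASSES}
    for ln, cat in zip(lengths, cats):
        u1 = u0 + ln
        corners_uv = [(u0, -half_w), (u1, -half_w), (u1, half_w), (u0, half_w)]
        ring = []
        for u, v in corners_uv:
            xy = np.asarray(release_xy) + e_u * u + e_v * v
            lon, lat = unproject(xy[0], xy[1], config.home)
            ring.append([round(float(lon), 10), round(float(lat), 10)])
        ring.append(ring[0])
        names = _CATEGORY_SOURCE_CLASSES[cat]
        source = names[class_cycle[cat] % len(names)]
        class_cycle[cat] += 1
        features.append({
            "type": "Feature",
            "properties": {"class": source},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
        u0 = u1
    geojson = {"type": "FeatureCollection", "features": features}
    hmap = _map_from_geojson(geojson)
    return hmap, geojson


def _map_from_geojson(geojson: dict) -> HabitatMap:
    import shapely.geometry as sgeom

    from .habitat_map import group_source_classes
    polys = [(sgeom.shape(f["geometry"]), f["properties"]["class"],
              group_source_classes(f["properties"]["class"]))
             for f in geojson["features"]]
    return HabitatMap(polys)


# ---------------------------------------------------------------------------
# intercept draws (stable across flights for a given campaign seed)


def draw_intercepts(config: SimConfig) -> dict:
    """Per-loft and per-bird intercepts for speed and flap, seeded once.

    Loft effects are deterministic, equally spaced with sample SD equal to
    the configured value: the lofts are a fixed design feature, and random
    draws over only three groups would often produce a nearly-zero spread
    that makes the loft variance unidentifiable, which the emulated study's
    non-singular headline models rule out.  Bird intercepts are random.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(config.seed), 901]))
    truth = {"loft": {}, "bird": {}}
    lofts = config.loft_ids()
    scores = np.arange(len(lofts), dtype=float)
    scores -= scores.mean()
    sd = scores.std(ddof=0)
    scores = scores / sd if sd > 0 else scores
    for loft, score in zip(lofts, scores):
        truth["loft"][loft] = {
            "speed": float(score * config.loft_intercept_sd["speed"]),
            "flap": float(score * config.loft_intercept_sd["flap"])}
        for bird in config.bird_ids(loft):
            truth["bird"][bird] = {
                "speed": float(rng.normal(0.0, config.bird_intercept_sd["speed"])),
                "flap": float(rng.normal(0.0, config.bird_intercept_sd["flap"])),
                "tortuosity": float(np.exp(rng.normal(0.0, config.tortuosity_sd)))}
    return truth


# ---------------------------------------------------------------------------
# one flight


def simulate_flight(config: SimConfig, landscape: HabitatMap, flock_id: str,
                    flight_idx: int, intercepts: dict | None = None
                    ) -> FlightData:
    """Simulate one release of one flock; returns all logger streams.

    ``flight_idx`` is 0-based; the flight date advances one day per index so
    the downstream iteration rank equals ``flight_idx + 1``.
    """
    if flock_id not in config.flocks:
        raise ParameterError(f"unknown flock {flock_id!r}")
    intercepts = intercepts or draw_intercepts(config)
    loft_i = config.loft_ids().index(flock_id)
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(config.seed), loft_i, int(flight_idx)]))
    birds = config.bird_ids(flock_id)
    n = len(birds)
    release_xy, home_xy, e_u, e_v, length = _axis_frame(config)
    dt = 1.0 / config.gps_rate_hz
    max_steps = int(3.0 * length / config.base_speed / dt)

    t_start = float(rng.uniform(0.0, config.start_time_jitter_s))
    pos = (np.asarray(release_xy)[None, :]
           + rng.normal(0.0, config.start_jitter_m, size=(n, 2)))
    pref = rng.normal(0.0, config.preferred_offset_sd_m, size=(n, 2))
    if n > 1:
        # centre the preferred offsets: the flock-mean preferred displacement
        # is unidentifiable against the centroid, and leaving it nonzero
        # biases the station-keeping speed correction away from zero mean
        pref -= pref.mean(axis=0)
    iter_mult = (1.0 + config.iteration_spread_trend) ** flight_idx

    rho = config.wobble_ar_per_s ** dt
    innov = np.sqrt(1.0 - rho ** 2)
    wob_speed = rng.normal(0.0, config.wobble_sd["speed"], size=n)
    wob_flap = rng.normal(0.0, config.wobble_sd["flap"], size=n)

    loft_int = intercepts["loft"][flock_id]
    flight_speed_off = float(rng.normal(0.0, config.flight_effect_sd["speed"]))
    flight_flap_off = float(rng.normal(0.0, config.flight_effect_sd["flap"]))
    bird_speed0 = np.array(
        [config.base_speed + loft_int["speed"] + flight_speed_off
         + intercepts["bird"][b]["speed"] for b in birds])
    bird_flap0 = np.array(
        [config.base_flap + loft_int["flap"] + flight_flap_off
         + intercepts["bird"][b]["flap"] for b in birds])
    heading_sd = config.heading_noise_sd * np.array(
        [intercepts["bird"][b].get("tortuosity", 1.0) for b in birds])

    split_until = -1.0
    split_members = np.zeros(n, dtype=bool)
    split_sign = 1.0
    splits_log: list[dict] = []
    p_split_step = config.split_probability_per_min * dt / 60.0

    traj = np.empty((max_steps, n, 2))
    flap_hist = np.empty((max_steps, n))
    n_steps = 0
    home = np.asarray(home_xy)
    for k in range(max_steps):
        t = k * dt
        habitat = classify_track(landscape, *unproject(pos[:, 0], pos[:, 1],
                                                       config.home))
        sp_off = np.array([config.habitat_speed_offsets[h] for h in habitat])
        fl_off = np.array([config.habitat_flap_offsets[h] for h in habitat])
        spread_mult = np.array(
            [config.habitat_spread_multipliers[h] for h in habitat])

        speed = np.clip(bird_speed0 + sp_off + wob_speed, *config.speed_bounds)
        flap = np.clip(bird_flap0 + fl_off + wob_flap, *config.flap_bounds)
        traj[k] = pos
        flap_hist[k] = flap

        centroid = pos.mean(axis=0)
        attract = centroid[None, :] + pref * (spread_mult * iter_mult)[:, None]
        if t < split_until:
            attract[split_members] = (centroid[None, :]
                                      + split_sign * config.split_offset_m * e_v)
        elif split_until < 0 or t >= split_until:
            split_members[:] = False
            if rng.random() < p_split_step and n >= 4:
                m = max(2, n // 4)
                chosen = rng.choice(n, size=m, replace=False)
                split_members[chosen] = True
                split_sign = rng.choice([-1.0, 1.0])
                split_until = t + config.split_duration_s
                splits_log.append({"t_start": float(t_start + t),
                                   "duration_s": config.split_duration_s,
                                   "birds": [birds[i] for i in chosen],
                                   "sign": float(split_sign)})

        to_home = home[None, :] - pos
        dist_home = np.linalg.norm(to_home, axis=1, keepdims=True)
        dirs = (to_home / np.maximum(dist_home, 1e-9)
                + config.steering_gain_per_m * (attract - pos))
        if config.heading_noise_sd > 0:
            ang = rng.normal(0.0, 1.0, size=n) * heading_sd
            cos_a, sin_a = np.cos(ang), np.sin(ang)
            dirs = np.column_stack([dirs[:, 0] * cos_a - dirs[:, 1] * sin_a,
                                    dirs[:, 0] * sin_a + dirs[:, 1] * cos_a])
        dirs /= np.maximum(np.linalg.norm(dirs, axis=1, keepdims=True), 1e-9)
        # station-keeping: birds trailing their attractor along the travel
        # direction speed up, leading birds slow down (keeps the flock from
        # dispersing along-track; zero at equilibrium, so injected speeds are
        # realised exactly once settled)
        along = np.einsum("ij,ij->i", attract - pos, dirs)
        out_of_station = (np.sign(along)
                          * np.maximum(np.abs(along)
                                       - config.station_deadband_m, 0.0))
        speed_eff = speed + np.clip(config.station_gain_per_s * out_of_station,
                                    -config.station_max_ms,
                                    config.station_max_ms)
        pos = pos + dirs * (speed_eff[:, None] * dt)

        wob_speed = rho * wob_speed + rng.normal(
            0.0, config.wobble_sd["speed"] * innov, size=n)
        wob_flap = rho * wob_flap + rng.normal(
            0.0, config.wobble_sd["flap"] * innov, size=n)
        n_steps = k + 1
        if (np.linalg.norm(pos - home, axis=1) < 180.0).all():
            break
    else:
        raise ParameterError(
            f"flight exceeded max duration {max_steps * dt:.0f} s "
            "without reaching home (pathological config)")

    traj = traj[:n_steps]
    flap_hist = flap_hist[:n_steps]
    t_gps = t_start + np.arange(n_steps) * dt
    flight_date = str(np.datetime64(config.start_date) + flight_idx)

    # GPS noise: per-axis AR(1) with ~gps_noise_timescale_s correlation
    gps, accel = {}, {}
    rho_g = float(np.exp(-dt / config.gps_noise_timescale_s))
    for i, bird in enumerate(birds):
        if config.gps_noise_sd_m > 0:
            eps = rng.normal(0.0, config.gps_noise_sd_m
                             * np.sqrt(1 - rho_g ** 2), size=(n_steps, 2))
            noise = np.empty((n_steps, 2))
            noise[0] = rng.normal(0.0, config.gps_noise_sd_m, size=2)
            for k in range(1, n_steps):
                noise[k] = rho_g * noise[k - 1] + eps[k]
        else:
            noise = np.zeros((n_steps, 2))
        if config.gps_jitter_sd_m > 0:
            noise = noise + rng.normal(0.0, config.gps_jitter_sd_m,
                                       size=(n_steps, 2))
        xy = traj[:, i, :] + noise
        lon, lat = unproject(xy[:, 0], xy[:, 1], config.home)
        g = pd.DataFrame({"t": t_gps, "lon": lon, "lat": lat})
        g.attrs.update(bird_id=bird, loft_id=flock_id, flight_date=flight_date)
        gps[bird] = g

        accel[bird] = _make_accel(config, rng, t_gps, flap_hist[:, i],
                                  bird, flight_date)
    return FlightData(flock_id, flight_date, gps, accel, splits_log)


def _make_accel(config: SimConfig, rng, t_gps, flap_inst, bird, flight_date
                ) -> pd.DataFrame:
    """100 Hz z-axis signal with a continuous-phase wingbeat oscillation."""
    dt_a = 1.0 / config.accel_rate_hz
    t_a = t_gps[0] + np.arange(
        0.0, t_gps[-1] - t_gps[0] + dt_a / 2, dt_a)
    f_a = np.interp(t_a, t_gps, flap_inst)
    phase = 2.0 * np.pi * np.cumsum(f_a) * dt_a
    drift = config.accel_drift_amp_g * np.sin(
        2.0 * np.pi * t_a / config.accel_drift_period_s
        + rng.uniform(0, 2 * np.pi))
    z = (1.0 + config.flap_amplitude_g * np.sin(phase) + drift
         + rng.normal(0.0, config.accel_noise_sd_g, size=len(t_a)))
    a = pd.DataFrame({"t": t_a, "z": z})
    a.attrs.update(bird_id=bird, flight_date=flight_date,
                   sample_rate_hz=config.accel_rate_hz)
    return a


# ---------------------------------------------------------------------------
# campaign


def simulate_campaign(config: SimConfig, out_dir=None) -> Campaign:
    """Simulate every flock over every flight; optionally write to disk.

    The ground-truth record mirrors every injected effect (habitat offsets,
    spread multipliers, intercept draws, split events) so recovery tests can
    compare against exactly what went in.
    """
    landscape, geojson = make_landscape(config)
    intercepts = draw_intercepts(config)
    flights = []
    split_events = {}
    for flock_id in config.loft_ids():
        for flight_idx in range(config.n_flights):
            fd = simulate_flight(config, landscape, flock_id, flight_idx,
                                 intercepts)
            flights.append(fd)
            if fd.splits:
                split_events[f"{flock_id}/{fd.flight_date}"] = fd.splits
    truth = {
        "seed": config.seed,
        "habitat_speed_offsets": dict(config.habitat_speed_offsets),
        "habitat_flap_offsets": dict(config.habitat_flap_offsets),
        "habitat_spread_multipliers": dict(config.habitat_spread_multipliers),
        "iteration_spread_trend": config.iteration_spread_trend,
        "base_speed": config.base_speed,
        "base_flap": config.base_flap,
        "intercepts": intercepts,
        "split_events": split_events,
    }
    campaign = Campaign(config, landscape, geojson, flights, truth)
    if out_dir is not None:
        write_campaign(campaign, out_dir)
    return campaign


def write_campaign(campaign: Campaign, out_dir) -> None:
    """Write per-bird per-flight CSVs, the landscape GeoJSON and the truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "landscape.geojson", "w", encoding="utf-8") as fh:
        json.dump(campaign.landscape_geojson, fh, sort_keys=True)
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(campaign.ground_truth, fh, sort_keys=True, indent=1)
    with open(out / "sim_config.json", "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(campaign.config), fh, sort_keys=True,
                  indent=1)
    for fd in campaign.flights:
        base = out / fd.flock_id / fd.flight_date
        (base / "gps").mkdir(parents=True, exist_ok=True)
        (base / "accel").mkdir(parents=True, exist_ok=True)
        for bird, g in fd.gps.items():
            g.rename(columns={"t": "timestamp"}).to_csv(
                base / "gps" / f"{bird}.csv", index=False,
                float_format="%.8f")
        for bird, a in fd.accel.items():
            a.rename(columns={"t": "timestamp"}).to_csv(
                base / "accel" / f"{bird}.csv", index=False,
                float_format="%.5f")


def load_campaign_dir(path) -> tuple[HabitatMap, dict]:
    """Load the landscape and ground truth written by :func:`write_campaign`."""
    path = Path(path)
    hmap = load_habitat_geojson(path / "landscape.geojson")
    with open(path / "ground_truth.json", encoding="utf-8") as fh:
        truth = json.load(fh)
    return hmap, truth
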