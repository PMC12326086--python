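"""End-to-end orchestration: raw streams -> track table -> model reports.

``run_pipeline`` chains the stages in the order the method runs: projection
and trimming of GPS fixes, 5 Hz speeds, per-second medians, habitat
classification, flap-frequency extraction from accelerometry over the
retained time span, flock geometry on per-second positions, stream merging,
flight/iteration indices, autocorrelation subsampling, and finally
habitat-conditioned mixed-model selection per response.  Outputs are plain
CSV/JSON so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (flock_geometry, io_biologger, model_selection, resample_align,
               trajectory, wingbeat)
from .errors import ConfigError, SelectionError
from .habitat_map import HabitatMap, classify_track
from .synthetic_data import Campaign, FlightData, _axis_frame

logger = logging.getLogger(__name__)

RESPONSE_COLUMNS = {
    "flap_frequency": "flap_frequency",
    "absolute_spread": "absolute_spread",
    "distance_to_centroid": "distance_to_centroid",
    "group_size": "group_size",
    "flight_speed": "speed",
    "front_back": "front_back",
    "left_right": "left_right",
}

DEFAULT_TRANSFORMS = {"absolute_spread": "sqrt",
                      "distance_to_centroid": "sqrt"}

#: full fixed-term pool; per-response candidates drop the response itself
FULL_TERM_POOL = [
    "habitat", "flight_time", "iteration", "flap_frequency",
    "absolute_spread", "distance_to_centroid", "group_size", "speed",
    "front_back", "left_right", "position",
    "habitat:flight_time", "habitat:iteration",
]


@dataclass
class PipelineConfig:
    """Validated pipeline settings with the study's constants as defaults."""

    release: tuple[float, float] = (-0.584229, 51.500122)
    home: tuple[float, float] = (-0.572615, 51.415368)
    trim_radius_m: float = 200.0
    link_dist_m: float = 10.0
    excl_dist_m: float = 40.0
    flap_window: int = 15
    subsample_rate: int = 15
    detrend_window_s: float = 1.0
    butter_order: int = 2
    butter_cutoff_hz: float = 1.0
    peak_prominence_factor: float = 0.3
    speed_ceiling_ms: float = 50.0
    vif_threshold: float = 5.0
    cooks_rule: str = "4/n"
    responses: tuple[str, ...] = tuple(RESPONSE_COLUMNS)
    transforms: dict = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    candidate_terms: list | None = None   # None -> full pool minus response
    max_lag: int = 20
    output_dir: str | None = None

    def __post_init__(self):
        for key in ("trim_radius_m", "link_dist_m", "excl_dist_m",
                    "flap_window", "subsample_rate", "detrend_window_s",
                    "butter_order", "butter_cutoff_hz", "vif_threshold"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"constant {key} must be positive")
        unknown = set(self.responses) - set(RESPONSE_COLUMNS)
        if unknown:
            raise ConfigError(f"unknown responses: {sorted(unknown)}")


def validate_config(path) -> PipelineConfig:
    """Load YAML/JSON, fill defaults, reject unknown keys."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("release", "home"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "responses" in raw:
        raw["responses"] = tuple(raw["responses"])
    return PipelineConfig(**raw)


def read_campaign_dir(path) -> Campaign:
    """Rebuild a :class:`Campaign` from a directory written by the simulator.

    Expects ``landscape.geojson``, ``ground_truth.json`` and per-flock
    ``<flock>/<date>/gps/<bird>.csv`` + ``accel/<bird>.csv`` trees; missing
    accelerometry degrades to absent flap fields downstream.
    """
    from .synthetic_data import SimConfig, load_campaign_dir
    path = Path(path)
    landscape, truth = load_campaign_dir(path)
    flights = []
    for flock_dir in sorted(p for p in path.iterdir() if p.is_dir()):
        flock_id = flock_dir.name
        for flight_dir in sorted(p for p in flock_dir.iterdir() if p.is_dir()):
            date = flight_dir.name
            gps, accel = {}, {}
            for f in sorted((flight_dir / "gps").glob("*.csv")):
                bird = f.stem
                gps[bird] = io_biologger.read_gps(f, bird, flock_id, date)
            accel_dir = flight_dir / "accel"
            if accel_dir.is_dir():
                for f in sorted(accel_dir.glob("*.csv")):
                    accel[f.stem] = io_biologger.read_accel(f, f.stem, date)
            if gps:
                flights.append(FlightData(flock_id, date, gps, accel, []))
    with open(path / "sim_config.json", encoding="utf-8") as fh:
        raw = json.load(fh)
    for key in ("release", "home", "speed_bounds", "flap_bounds"):
        raw[key] = tuple(raw[key])
    config = SimConfig(**raw)
    geojson = json.load(open(path / "landscape.geojson", encoding="utf-8"))
    return Campaign(config, landscape, geojson, flights, truth)


# ---------------------------------------------------------------------------
# per-flight processing


def process_flight(flight: FlightData, landscape: HabitatMap,
                   config: PipelineConfig) -> pd.DataFrame:
    """One flight of one flock -> merged per-second records (pre-subsample)."""
    origin = config.home
    sites_ll = pd.DataFrame({
        "t": [0.0, 1.0],
        "lon": [config.release[0], config.home[0]],
        "lat": [config.release[1], config.home[1]]})
    sites_xy = trajectory.project_to_plane(sites_ll, origin)
    sites = list(zip(sites_xy["x"], sites_xy["y"]))

    per_bird = []
    for bird, gps in flight.gps.items():
        track = trajectory.project_to_plane(gps, origin)
        track, span = trajectory.trim_radius(track, sites, config.trim_radius_m)
        if len(track) < 2:
            logger.warning("flight %s/%s bird %s: empty after trimming",
                           flight.flock_id, flight.flight_date, bird)
            continue
        track["speed"] = trajectory.compute_speed(track,
                                                  config.speed_ceiling_ms)
        gps_s = resample_align.to_per_second(track, ["x", "y", "speed"])

        flap_s = None
        accel = flight.accel.get(bird)
        if accel is not None and len(accel):
            a = accel[(accel["t"] >= span[0]) & (accel["t"] <= span[1])]
            rate = accel.attrs.get("sample_rate_hz", 100.0)
            if len(a) > int(rate * config.detrend_window_s):
                z = wingbeat.detrend_z(a["z"].to_numpy(), rate,
                                       config.detrend_window_s)
                f = wingbeat.estimate_flap_frequency(
                    a["t"].to_numpy(), z, rate, config.flap_window,
                    config.peak_prominence_factor)
                f = wingbeat.butterworth_smooth(f, config.butter_order,
                                                config.butter_cutoff_hz)
                flap_s = (wingbeat.aggregate_median_per_second(f)
                          .rename(columns={"f": "flap_frequency"}))

        lon, lat = trajectory.unproject(gps_s["x"], gps_s["y"], origin)
        habitat_s = pd.DataFrame({
            "t": gps_s["t"],
            "habitat": classify_track(landscape, lon, lat)})

        rec = gps_s.assign(bird_id=bird, loft_id=flight.flock_id,
                           flight_date=flight.flight_date)
        rec = resample_align.merge_streams(rec, flap_s, habitat_s)
        if "flap_frequency" not in rec.columns:
            rec["flap_frequency"] = np.nan
        per_bird.append(rec)
    if not per_bird:
        return pd.DataFrame()
    records = pd.concat(per_bird, ignore_index=True)

    # flock geometry on per-second positions, before any subsampling
    _, _, e_u, _, _ = _axis_frame_from(config)
    frames = flock_geometry.compute_flock_frames(
        records[["bird_id", "t", "x", "y"]], flight.flock_id,
        (float(e_u[0]), float(e_u[1])),
        config.link_dist_m, config.excl_dist_m)
    if len(frames):
        flock_cols = frames[["bird_id", "t", "group_size", "absolute_spread",
                             "distance_to_centroid", "front_back",
                             "left_right", "position"]]
        records = records.merge(flock_cols, how="left", on=["bird_id", "t"])
    else:
        for c in ("group_size", "absolute_spread", "distance_to_centroid",
                  "front_back", "left_right"):
            records[c] = np.nan
        records["position"] = None
    return records


def _axis_frame_from(config: PipelineConfig):
    from .synthetic_data import SimConfig
    sim = SimConfig(release=config.release, home=config.home)
    return _axis_frame(sim)


# ---------------------------------------------------------------------------
# full pipeline


def build_track_table(campaign: Campaign, config: PipelineConfig
                      ) -> pd.DataFrame:
    """All flights -> indexed per-second track table (pre-subsample)."""
    tables = [process_flight(fd, campaign.landscape, config)
              for fd in campaign.flights]
    tables = [t for t in tables if len(t)]
    if not tables:
        return pd.DataFrame()
    records = pd.concat(tables, ignore_index=True)
    return trajectory.attach_indices(records)


def model_response(records: pd.DataFrame, response: str,
                   config: PipelineConfig) -> dict:
    """VIF-prune, all-subsets search, selection and Cook's refit for one response."""
    col = RESPONSE_COLUMNS[response]
    transform = config.transforms.get(response, "identity")
    pool = (list(config.candidate_terms) if config.candidate_terms is not None
            else FULL_TERM_POOL)
    data = records
    spec_pool = [t for t in pool if t != col]
    retained, removed = model_selection.vif_prune(
        data.dropna(subset=[col]), spec_pool, config.vif_threshold)
    specs = model_selection.enumerate_subsets(retained, col, transform)
    fits = [model_selection.fit_lmm(s, data) for s in specs]
    report = {
        "response": response,
        "pruned_terms": [t for t, _ in removed],
        "n_candidates": len(specs),
        "n_singular": sum(f.singular for f in fits),
    }
    try:
        best = model_selection.select_best(fits)
    except SelectionError:
        report.update(selected=None, singular=True)
        return report
    final, n_removed = model_selection.cooks_refit(best, data)
    report.update(
        selected=list(best.spec.fixed_terms),
        aic=best.aic, r2=final.r2, n_obs=final.n_obs,
        outliers_removed=n_removed, singular=final.singular,
        coefficients=final.coefficients,
        random_variances=final.random_variances,
    )
    return report


def run_pipeline(config: PipelineConfig, campaign: Campaign) -> dict:
    """Run every stage on an in-memory campaign; optionally write artifacts.

    Returns a dict with the pre- and post-subsample track tables, the
    per-response model reports, diagnostics and a run manifest.
    """
    records = build_track_table(campaign, config)
    subsampled = resample_align.subsample(records, config.subsample_rate)

    diagnostics = {}
    flap = subsampled["flap_frequency"].dropna()
    if len(flap) > config.max_lag + 2 and flap.var() > 0:
        diagnostics["flap_acf"] = resample_align.autocorrelation(
            flap, config.max_lag).tolist()
    for factor in ("bird_id", "loft_id"):
        try:
            dev, dof, p = model_selection.layer_independence_check(
                subsampled, factor)
            diagnostics[f"layer_vs_{factor}"] = {
                "deviance": dev, "df": dof, "p": p}
        except Exception as exc:  # diagnostic only; never fails the run
            diagnostics[f"layer_vs_{factor}"] = {"error": str(exc)}

    reports = {}
    for response in config.responses:
        try:
            reports[response] = model_response(subsampled, response, config)
        except Exception as exc:
            logger.warning("model stage failed for %s: %s", response, exc)
            reports[response] = {"response": response, "error": str(exc)}

    manifest = {
        "config": dataclasses.asdict(config),
        "n_flights": len(campaign.flights),
        "rows_per_second": int(len(records)),
        "rows_subsampled": int(len(subsampled)),
        "seed": campaign.config.seed,
    }
    result = {"track": records, "track_subsampled": subsampled,
              "reports": reports, "diagnostics": diagnostics,
              "manifest": manifest}
    if config.output_dir:
        _write_outputs(result, Path(config.output_dir))
    return result


def recovery_experiment(seed: int, n_replicates: int = 10,
                        n_flights: int = 5) -> pd.DataFrame:
    """Inject known habitat effects, run the full pipeline, measure recovery.

    Each replicate simulates a scaled campaign (3 flocks x ``n_flights``
    flights, measurement noise zeroed, behavioural variability kept), runs
    every stage through model selection for flight speed and flap frequency
    with candidate terms {habitat, flight_time, iteration}, and records the
    selected model's habitat coefficients against the injected effects
    (wooded speed -0.7, urban speed +0.7 m/s; urban flap -0.1 Hz).

    Returns one row per replicate x effect with columns ``replicate, effect,
    truth, estimate, se, sign_ok, within_2se``.
    """
    from .synthetic_data import SimConfig, simulate_campaign
    effects = {
        ("flight_speed", "wooded"): -0.7,
        ("flight_speed", "urban"): 0.7,
        ("flap_frequency", "urban"): -0.1,
    }
    pcfg = PipelineConfig(
        responses=("flight_speed", "flap_frequency"),
        candidate_terms=["habitat", "flight_time", "iteration"])
    rows = []
    for rep in range(n_replicates):
        sim = SimConfig(
            seed=int(seed) + rep, n_flights=n_flights,
            habitat_speed_offsets={"open": 0.0, "wooded": -0.7, "urban": 0.7},
            habitat_flap_offsets={"open": 0.0, "wooded": 0.0, "urban": -0.1},
            gps_noise_sd_m=0.0, accel_noise_sd_g=0.0, accel_drift_amp_g=0.0,
            wobble_sd={"speed": 0.4, "flap": 0.25},
            split_probability_per_min=0.0)
        campaign = simulate_campaign(sim)
        result = run_pipeline(pcfg, campaign)
        for (resp, level), truth in effects.items():
            rep_report = result["reports"][resp]
            coeffs = rep_report.get("coefficients")
            est = se = np.nan
            if coeffs is not None and rep_report.get("selected") \
                    and "habitat" in rep_report["selected"]:
                match = coeffs[coeffs["coefficient"].str.contains(
                    f"T.{level}", regex=False)]
                if len(match):
                    est = float(match["estimate"].iloc[0])
                    se = float(match["se"].iloc[0])
            sign_ok = bool(np.isfinite(est) and np.sign(est) == np.sign(truth))
            within = bool(np.isfinite(est) and np.isfinite(se)
                          and abs(est - truth) <= 2.0 * se)
            rows.append({"replicate": rep, "response": resp, "level": level,
                         "truth": truth, "estimate": est, "se": se,
                         "sign_ok": sign_ok, "within_2se": within})
    return pd.DataFrame(rows)


def _write_outputs(result: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    io_biologger.write_track_table(result["track"], out / "track.csv")
    io_biologger.write_track_table(result["track_subsampled"],
                                   out / "track_subsampled.csv")
    serializable = {}
    for name, rep in result["reports"].items():
        rep = dict(rep)
        coeffs = rep.pop("coefficients", None)
        if coeffs is not None:
            coeffs.to_csv(out / f"model_{name}.csv", index=False)
            rep["coefficients_csv"] = f"model_{name}.csv"
        serializable[name] = rep
    with open(out / "selection_log.json", "w", encoding="utf-8") as fh:
        json.dump(serializable, fh, indent=1, sort_keys=True, default=str)
    with open(out / "diagnostics.json", "w", encoding="utf-8") as fh:
        json.dump(result["diagnostics"], fh, indent=1, sort_keys=True,
                  default=str)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result["manifest"], fh, indent=1, sort_keys=True,
                  default=str)
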