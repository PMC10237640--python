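"""Synthetic coast, population, flight and detection generator.

Every downstream stage of the pipeline (georeferencing, distance
measurement, deduplication, overlap statistics, environmental models) is
driven by data from this module, so each carries ground truth: true subject
positions, true signed distances, true daily rates, and the identity behind
every detection.

Streams of randomness are all derived deterministically from the root seed
in :class:`~nearshore_overlap.config.GeneratorConfig`, keyed by stage, beach
and day, so regenerating any beach-day in isolation reproduces the full-run
records exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .camera import CameraModel, frame_footprint
from .config import GROUPS, HUMAN_GROUPS, CovariateEffect, GeneratorConfig
from .geometry import WaveBreakLine, signed_distances_to_break

__all__ = [
    "Coast",
    "generate_coast",
    "generate_environment",
    "daily_mean",
    "generate_subjects",
    "simulate_flight",
    "render_detections",
    "simulate_survey_day",
    "survey_day_observations",
]

SUBJECT_COLUMNS = ["subject_id", "group", "beach", "day", "x", "y",
                   "signed_distance", "marked"]
DETECTION_COLUMNS = ["survey_id", "beach", "day", "frame_id", "leg", "timestamp",
                     "group", "key", "mark_id", "subject_id", "px_col", "px_row",
                     "x", "y"]


@dataclass
class Coast:
    """One beach's simulated geometry in local metric coordinates.

    x runs alongshore (0..length), y seaward; the shoreline sits near y = 0
    and the wave break a strictly positive offset seaward of it.
    """

    beach: int
    shoreline: np.ndarray  # (n, 2)
    wavebreak: np.ndarray  # (n, 2)
    length: float
    domain_extent: float

    def break_y(self, x) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float),
                         self.wavebreak[:, 0], self.wavebreak[:, 1])

    def shore_y(self, x) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float),
                         self.shoreline[:, 0], self.shoreline[:, 1])

    @property
    def break_line(self) -> WaveBreakLine:
        return WaveBreakLine(beach=str(self.beach), vertices=self.wavebreak,
                             shore_side=-1)


def generate_coast(config: GeneratorConfig, beach: int, vertex_spacing: float = 10.0) -> Coast:
    """Generate a shoreline and wave-break polyline pair for one beach.

    The shoreline is a straight reference line at y = 0; the break sits a
    strictly positive, sinusoidally varying offset seaward (mean and
    amplitude from the config, with a per-beach random phase), echoing how a
    surf line meanders with bars and rips.  The two polylines never cross
    because the offset is positive everywhere.
    """
    if config.beach_length <= 0:
        raise ValueError("degenerate beach length")
    if config.break_offset_amplitude >= config.break_offset_mean:
        raise ValueError("break offset amplitude must be below the mean offset "
                         "(polylines would cross)")
    rng = config.rng_for("coast", beach)
    phase = rng.uniform(0, 2 * np.pi)
    x = np.arange(0.0, config.beach_length + vertex_spacing / 2, vertex_spacing)
    shore = np.column_stack([x, np.zeros_like(x)])
    offset = (config.break_offset_mean
              + config.break_offset_amplitude
              * np.sin(2 * np.pi * x / config.break_offset_wavelength + phase))
    brk = np.column_stack([x, offset])
    return Coast(beach=beach, shoreline=shore, wavebreak=brk,
                 length=config.beach_length, domain_extent=config.offshore_extent)


# ---------------------------------------------------------------------------
# environmental covariates

ENV_COLUMNS = ["wave_direction", "wave_height", "mean_wave_period", "peak_wave_period",
               "air_temp", "sst", "sst_anomaly", "wind_speed", "wind_direction",
               "lunar_illumination", "total_cloud_cover", "cloud_base_height", "uv_b",
               "tidal_range"]


def generate_environment(config: GeneratorConfig) -> pd.DataFrame:
    """One row per beach-day of plausible southern-California conditions.

    Weather is shared across beaches within a day (a coastal synoptic scale)
    with small per-beach perturbations; SST carries an annual cycle plus an
    autocorrelation-free daily anomaly; tides follow a spring-neap cycle and
    the moon a synodic one.
    """
    rng = config.rng_for("environment")
    days = np.arange(config.n_days)
    t = days % 365
    sst_clim = 17.0 + 4.0 * np.sin(2 * np.pi * (t - 120) / 365.0)
    anomaly = rng.normal(0.0, 0.8, size=config.n_days)
    wave_height_day = np.clip(rng.lognormal(np.log(0.9), 0.45, size=config.n_days), 0.2, 3.5)
    mean_period_day = np.clip(rng.normal(8.0, 2.0, size=config.n_days), 4.0, 16.0)
    wind_day = np.clip(rng.gamma(2.0, 1.8, size=config.n_days), 0.2, 7.9)
    cloud_day = rng.beta(1.2, 3.0, size=config.n_days)
    rows = []
    for b in range(config.n_beaches):
        jitter = config.rng_for("environment", b)
        for i, d in enumerate(days):
            sst = sst_clim[i] + anomaly[i] + jitter.normal(0, 0.2)
            wave_height = max(0.15, wave_height_day[i] * jitter.lognormal(0, 0.1))
            mean_period = np.clip(mean_period_day[i] + jitter.normal(0, 0.4), 3.5, 18.0)
            uv_seasonal = 3.5 + 2.5 * np.sin(2 * np.pi * (t[i] - 172) / 365.0 + np.pi / 2)
            rows.append({
                "beach": b,
                "day": int(d),
                "month": int((t[i] // 30.42) % 12) + 1,
                "day_of_week": int(d % 7),
                "hour": int(8 + jitter.integers(0, 9)),
                "wave_direction": float(jitter.uniform(180, 300) % 360),
                "wave_height": float(wave_height),
                "mean_wave_period": float(mean_period),
                "peak_wave_period": float(np.clip(mean_period * 1.25 + jitter.normal(0, 0.5),
                                                  4.0, 22.0)),
                "air_temp": float(sst + jitter.normal(1.5, 1.5)),
                "sst": float(sst),
                "sst_anomaly": float(anomaly[i] + jitter.normal(0, 0.1)),
                "wind_speed": float(np.clip(wind_day[i] + jitter.normal(0, 0.4), 0.1, 8.0)),
                "wind_direction": float(jitter.uniform(0, 360)),
                "lunar_illumination": float((1 + np.sin(2 * np.pi * t[i] / 29.53)) / 2),
                "total_cloud_cover": float(np.clip(cloud_day[i] + jitter.normal(0, 0.05), 0, 1)),
                "cloud_base_height": float(np.clip(jitter.lognormal(np.log(1500), 0.5),
                                                   620, 8000)),
                "uv_b": float(max(0.1, uv_seasonal * (1 - 0.6 * cloud_day[i])
                                  + jitter.normal(0, 0.3))),
                "tidal_range": float(max(0.3, 1.2 + 0.6 * np.sin(2 * np.pi * t[i] / 14.77)
                                         + jitter.normal(0, 0.15))),
            })
    return pd.DataFrame(rows)


def daily_mean(config: GeneratorConfig, group: str, cov_row, beach: int) -> float:
    """Expected count of one group on one beach-day: base_mean x exp(sum of effects).

    Sharks are down-weighted by ``non_aggregation_shark_factor`` away from
    aggregation beaches, producing the clumped coast-wide distribution.
    """
    if group not in config.group_params:
        raise ValueError(f"unknown group {group!r}")
    lam = config.group_params[group].base_mean
    eta = 0.0
    for eff in config.covariate_effects.get(group, []):
        eta += float(eff(cov_row[eff.covariate]))
    lam *= float(np.exp(np.clip(eta, -10, 4)))
    if group == "shark" and beach not in set(config.aggregation_beaches):
        lam *= config.non_aggregation_shark_factor
    return lam


def _sample_alongshore(config: GeneratorConfig, group: str, beach: int, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    scale = config.group_params[group].alongshore_scale
    L = config.beach_length
    if scale is None or n == 0:
        return rng.uniform(0, L, size=n)
    if group == "shark":
        hot_rng = config.rng_for("hotspot", beach)
        centers = np.array([hot_rng.uniform(0.3 * L, 0.7 * L)])
    else:
        centers = np.asarray(config.access_points, dtype=float)
    which = rng.integers(0, len(centers), size=n)
    x = rng.normal(centers[which], scale)
    bad = (x < 0) | (x > L)
    while bad.any():
        nb = int(bad.sum())
        w = rng.integers(0, len(centers), size=nb)
        x[bad] = rng.normal(centers[w], scale)
        bad = (x < 0) | (x > L)
    return x


def generate_subjects(config: GeneratorConfig, beach: int, day: int, cov_row,
                      coast: Coast | None = None) -> pd.DataFrame:
    """Draw the true population present on one beach-day.

    Counts are Poisson with the log-link daily mean; alongshore positions
    cluster on access points (humans) or the beach's aggregation hotspot
    (sharks); cross-shore signed distances follow each group's configured
    law.  Ground positions need the coast's wave-break geometry; with
    ``coast=None`` the break is taken as a straight line at the mean offset.
    """
    rng = config.rng_for("subjects", beach, day)
    frames = []
    for group in GROUPS:
        lam = daily_mean(config, group, cov_row, beach)
        n = int(rng.poisson(lam))
        if n == 0:
            continue
        x = _sample_alongshore(config, group, beach, n, rng)
        d = config.group_params[group].cross_shore.sample(n, rng)
        if coast is not None:
            by = coast.break_y(x)
        else:
            by = np.full(n, config.break_offset_mean)
        y = by + d
        marked = (rng.random(n) < config.mark_fraction) if group == "shark" \
            else np.ones(n, dtype=bool)
        frames.append(pd.DataFrame({
            "subject_id": [f"b{beach}d{day}-{group}-{i}" for i in range(n)],
            "group": group, "beach": beach, "day": day,
            "x": x, "y": y, "signed_distance": d, "marked": marked,
        }))
    if not frames:
        return pd.DataFrame(columns=SUBJECT_COLUMNS)
    return pd.concat(frames, ignore_index=True)[SUBJECT_COLUMNS]


# ---------------------------------------------------------------------------
# flight simulation

def simulate_flight(config: GeneratorConfig, coast: Coast,
                    start_time: float = 0.0) -> pd.DataFrame:
    """Plan one survey's frame poses over a beach.

    The first leg parallels the shoreline for ``first_leg_length`` (1 km) at
    the first-leg altitude, centred so one frame holds both shoreline and
    wave break; subsequent legs step seaward in a lawnmower pattern at 60 m
    altitude until the strip out to ``offshore_extent`` is covered.  Poses
    are spaced survey_speed x frame_interval metres (the 5-s frame
    extraction cadence).
    """
    if config.offshore_extent > coast.domain_extent:
        raise ValueError("offshore_extent exceeds the generated coastal domain")
    ds = config.survey_speed * config.frame_interval
    leg_len = min(config.first_leg_length, coast.length)
    rows = []
    t = start_time
    frame_id = 0

    def emit(xs, ys, altitude, heading, leg):
        nonlocal t, frame_id
        for xx, yy in zip(xs, ys):
            rows.append({"frame_id": frame_id, "leg": leg, "timestamp": t,
                         "x": float(xx), "y": float(yy),
                         "altitude": float(altitude), "heading": float(heading)})
            t += config.frame_interval
            frame_id += 1

    # first leg: shoreline + break both in frame
    s = np.arange(0.0, leg_len + 1e-9, ds)
    y0 = coast.shore_y(s) + config.first_leg_altitude / 2.0
    emit(s, y0, config.first_leg_altitude, 0.0, 0)

    # lawnmower legs seaward at the low, constant identification altitude
    _, fh, _ = frame_footprint(CameraModel(), config.later_leg_altitude)
    half = fh / 2.0
    first_top = config.first_leg_altitude  # first-leg coverage reaches y ~ altitude
    c = first_top + half - 10.0  # 10 m overlap into first-leg coverage
    leg = 1
    while c - half < config.offshore_extent:
        if leg % 2 == 1:  # return leg
            xs = s[::-1]
            heading = 180.0
        else:
            xs = s
            heading = 0.0
        emit(xs, np.full_like(xs, c), config.later_leg_altitude, heading, leg)
        c += config.leg_spacing
        leg += 1
    return pd.DataFrame(rows)


def render_detections(config: GeneratorConfig, camera: CameraModel,
                      frames: pd.DataFrame, subjects: pd.DataFrame,
                      survey_id: str, rng: np.random.Generator | None = None,
                      convention: str = "video_fov") -> pd.DataFrame:
    """Project subjects into every frame whose ground footprint contains them.

    Humans are detected whenever inside a footprint; sharks are additionally
    gated by per-pass surface availability (independent Bernoulli with
    probability ``shark_surface_prob`` per (shark, leg)).  Detections carry
    an appearance key: humans get a unique appearance key (size, clothing
    colour and the like make individuals recognisable within a survey),
    marked sharks their mark id, unmarked sharks a per-pass track key — an
    observer can follow one animal within a pass but not across passes.
    """
    if rng is None:
        rng = config.rng_for("detections", survey_id)
    if not frames["altitude"].between(59.0, 121.0).all():
        raise ValueError("frame poses inconsistent with the survey camera envelope")
    if subjects.empty or frames.empty:
        return pd.DataFrame(columns=DETECTION_COLUMNS)
    if subjects["beach"].nunique() > 1 or subjects["day"].nunique() > 1:
        raise ValueError("subjects span more than one beach-day")
    beach = subjects["beach"].iloc[0]
    day = subjects["day"].iloc[0]

    sx = subjects["x"].to_numpy()
    sy = subjects["y"].to_numpy()
    is_shark = (subjects["group"] == "shark").to_numpy()
    availability: dict[tuple[int, int], bool] = {}
    records = []
    for f in frames.itertuples():
        fw, fh, _ = frame_footprint(camera, f.altitude, convention)
        theta = np.radians(f.heading)
        ct, st = np.cos(theta), np.sin(theta)
        dx = sx - f.x
        dy = sy - f.y
        # rotate ground offsets into the frame's axes (inverse heading rotation)
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
        inside = (np.abs(u) <= fw / 2) & (np.abs(v) <= fh / 2)
        for idx in np.nonzero(inside)[0]:
            if is_shark[idx]:
                k = (idx, f.leg)
                if k not in availability:
                    availability[k] = bool(rng.random() < config.shark_surface_prob)
                if not availability[k]:
                    continue
            row = subjects.iloc[idx]
            if row["group"] == "shark":
                mark = f"mark-{row['subject_id']}" if row["marked"] else None
                key = mark if mark else f"trk-{row['subject_id']}-leg{f.leg}"
            else:
                mark = None
                key = f"app-{row['subject_id']}"
            col = (u[idx] / fw + 0.5) * camera.image_width_px
            prow = (-v[idx] / fh + 0.5) * camera.image_height_px
            records.append({
                "survey_id": survey_id, "beach": beach, "day": day,
                "frame_id": f.frame_id, "leg": f.leg, "timestamp": f.timestamp,
                "group": row["group"], "key": key, "mark_id": mark,
                "subject_id": row["subject_id"],
                "px_col": float(col), "px_row": float(prow),
                "x": float(sx[idx]), "y": float(sy[idx]),
            })
    return pd.DataFrame(records, columns=DETECTION_COLUMNS)


def simulate_survey_day(config: GeneratorConfig, coast: Coast, beach: int, day: int,
                        cov_row, camera: CameraModel | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full per-frame simulation of one beach-day: (frames, subjects, detections)."""
    camera = camera or CameraModel()
    subjects = generate_subjects(config, beach, day, cov_row, coast)
    frames = simulate_flight(config, coast)
    survey_id = f"b{beach}-d{day}-s0"
    detections = render_detections(config, camera, frames, subjects, survey_id)
    return frames, subjects, detections


def survey_day_observations(config: GeneratorConfig, coast: Coast, beach: int,
                            day: int, cov_row,
                            measure_groups: tuple[str, ...] = ("shark",),
                            ) -> pd.DataFrame:
    """Survey-level observation records for one beach-day, without frame rendering.

    Humans present are each observed once; sharks are thinned by per-day
    surface availability.  Signed distances for ``measure_groups`` are
    measured against the coast's wave-break polyline (the pipeline's
    geometric route); other groups carry their construction-truth distance.
    Orders of magnitude faster than :func:`simulate_survey_day`, for
    replicated coast-wide experiments.
    """
    subjects = generate_subjects(config, beach, day, cov_row, coast)
    if subjects.empty:
        return subjects.assign(dist_break_m=pd.Series(dtype=float))
    rng = config.rng_for("availability", beach, day)
    keep = np.ones(len(subjects), dtype=bool)
    shark_mask = (subjects["group"] == "shark").to_numpy()
    keep[shark_mask] = rng.random(int(shark_mask.sum())) < config.shark_surface_prob
    obs = subjects.loc[keep].copy()
    dist = obs["signed_distance"].to_numpy().copy()
    measure = obs["group"].isin(measure_groups).to_numpy()
    if measure.any():
        pts = obs.loc[measure, ["x", "y"]].to_numpy()
        dist[measure] = signed_distances_to_break(pts, coast.break_line)
    obs["dist_break_m"] = dist
    obs["survey_id"] = f"b{beach}-d{day}-s0"
    return obs.reset_index(drop=True)
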