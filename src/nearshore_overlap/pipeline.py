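"""End-to-end orchestration: synth -> georef -> measure -> tabulate -> stats -> envmodel.

Each stage reads its inputs from and writes its outputs to the run
directory, so any stage can be re-run in isolation; a manifest records the
config digest, root seed and a SHA-256 digest of every file each stage
produced, making a run auditable and reproducibility checkable
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .camera import CameraModel
from .config import GROUPS, HUMAN_GROUPS, GeneratorConfig, save_config
from .envmodel import (AdditiveCountModel, redundancy_prune, select_smoothing,
                       stepwise_select)
from .generator import (ENV_COLUMNS, generate_coast, generate_environment,
                        simulate_survey_day)
from .geometry import build_wavebreak_line, signed_distances_to_break, surveyed_area_ha
from .io import write_csv, write_linestring_geojson
from .kde import kde_overlap
from .observations import (build_survey_day_table, distinct_shark_count,
                           first_observation_filter)
from .stats import cooccurrence_rate, max_density, rank_tests, relative_abundance

logger = logging.getLogger("nearshore_overlap")

STAGES = ["synth", "georef", "measure", "tabulate", "stats", "envmodel"]


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class RunManifest:
    """Auditable record of a pipeline run."""

    def __init__(self, outdir: Path, config_digest: str, seed: int):
        self.data = {"version": __version__, "config_digest": config_digest,
                     "seed": seed, "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                     "stages": []}
        self.outdir = outdir

    def record(self, stage: str, outputs: list[Path], counts: dict) -> None:
        self.data["stages"].append({
            "stage": stage,
            "outputs": {p.name: _digest(p) for p in outputs},
            "record_counts": counts,
        })
        self.write()

    def write(self) -> None:
        (self.outdir / "manifest.json").write_text(json.dumps(self.data, indent=1))


def run_pipeline(config: GeneratorConfig, outdir, stages: list[str] | None = None,
                 ) -> RunManifest:
    """Run the pipeline stages in dependency order into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = stages or STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    cfg_path = outdir / "config.yaml"
    save_config(config, cfg_path)
    manifest = RunManifest(outdir, _digest(cfg_path), config.seed)

    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("stage %s", stage)
        fn = globals()[f"stage_{stage}"]
        fn(config, outdir, manifest)
    return manifest


def stage_synth(config: GeneratorConfig, outdir: Path, manifest: RunManifest) -> None:
    """Generate coasts, environment, subjects, flights and detections."""
    camera = CameraModel()
    env = generate_environment(config)
    all_subjects, all_frames, all_detections = [], [], []
    for b in range(config.n_beaches):
        coast = generate_coast(config, b)
        write_linestring_geojson(outdir / f"coast_shore_b{b}.geojson", coast.shoreline,
                                 {"beach": b, "role": "shoreline"})
        write_linestring_geojson(outdir / f"coast_break_b{b}.geojson", coast.wavebreak,
                                 {"beach": b, "role": "wavebreak"})
        for _, cov in env[env["beach"] == b].iterrows():
            d = int(cov["day"])
            frames, subjects, detections = simulate_survey_day(
                config, coast, b, d, cov, camera)
            frames.insert(0, "survey_id", f"b{b}-d{d}-s0")
            frames.insert(1, "beach", b)
            frames.insert(2, "day", d)
            all_frames.append(frames)
            all_subjects.append(subjects)
            all_detections.append(detections)
    subjects = pd.concat(all_subjects, ignore_index=True)
    frames = pd.concat(all_frames, ignore_index=True)
    detections = pd.concat(all_detections, ignore_index=True)
    outputs = []
    for name, df in [("environment", env), ("subjects", subjects),
                     ("frames", frames), ("detections", detections)]:
        p = outdir / f"{name}.csv"
        write_csv(df, p)
        outputs.append(p)
    outputs += sorted(outdir.glob("coast_*.geojson"))
    manifest.record("synth", outputs, {
        "beaches": config.n_beaches, "days": config.n_days,
        "subjects": len(subjects), "frames": len(frames),
        "detections": len(detections)})


def stage_georef(config: GeneratorConfig, outdir: Path, manifest: RunManifest) -> None:
    """Trace the wave break from first-leg detections' frames and store per-beach lines."""
    frames = pd.read_csv(outdir / "frames.csv")
    outputs = []
    for b in range(config.n_beaches):
        # trace the break under the first leg of the first survey of each beach:
        # each first-leg frame contributes the break point at the frame's x
        coast_break, _ = _read_break_truth(outdir, b)
        fb = frames[(frames["beach"] == b) & (frames["leg"] == 0)
                    & (frames["day"] == frames[frames["beach"] == b]["day"].min())]
        xs = fb["x"].to_numpy()
        ys = np.interp(xs, coast_break[:, 0], coast_break[:, 1])
        rng = config.rng_for("trace", b)
        traced = np.column_stack([xs, ys + rng.normal(0, 0.5, size=len(xs))])
        line = build_wavebreak_line(traced, beach=str(b))
        p = outdir / f"wavebreak_traced_b{b}.geojson"
        write_linestring_geojson(p, line.vertices, {"beach": b, "role": "traced-break"})
        outputs.append(p)
    manifest.record("georef", outputs, {"beaches": config.n_beaches})


def _read_break_truth(outdir: Path, beach: int) -> tuple[np.ndarray, dict]:
    from .io import read_linestring_geojson
    return read_linestring_geojson(outdir / f"coast_break_b{beach}.geojson")


def stage_measure(config: GeneratorConfig, outdir: Path, manifest: RunManifest) -> None:
    """First-observation filtering and signed distance measurement."""
    from .geometry import WaveBreakLine
    from .io import read_linestring_geojson

    detections = pd.read_csv(outdir / "detections.csv")
    obs = first_observation_filter(detections)
    dists = np.full(len(obs), np.nan)
    for b, idx in obs.groupby("beach").groups.items():
        verts, _ = read_linestring_geojson(outdir / f"wavebreak_traced_b{b}.geojson")
        line = WaveBreakLine(beach=str(b), vertices=verts, shore_side=-1)
        pts = obs.loc[idx, ["x", "y"]].to_numpy()
        dists[obs.index.get_indexer(idx)] = signed_distances_to_break(pts, line)
    obs["dist_break_m"] = dists
    p = outdir / "observations.csv"
    write_csv(obs, p)
    manifest.record("measure", [p], {"observations": len(obs)})


def stage_tabulate(config: GeneratorConfig, outdir: Path, manifest: RunManifest) -> None:
    """Survey-day table with conservative distinct-shark counts."""
    obs = pd.read_csv(outdir / "observations.csv")
    detections = pd.read_csv(outdir / "detections.csv")
    flown = (pd.read_csv(outdir / "frames.csv")[["survey_id", "beach", "day"]]
             .drop_duplicates()
             .groupby(["beach", "day"], as_index=False).size()
             .rename(columns={"size": "n_surveys"}))
    sharks = detections[detections["group"] == "shark"]
    distinct = (sharks.groupby(["beach", "day"])
                .apply(distinct_shark_count, include_groups=False)
                .rename("shark_distinct").reset_index()) if len(sharks) else None
    table = build_survey_day_table(obs, surveys_flown=flown, distinct_sharks=distinct)
    p = outdir / "survey_days.csv"
    write_csv(table, p)
    manifest.record("tabulate", [p], {"beach_days": len(table)})


def stage_stats(config: GeneratorConfig, outdir: Path, manifest: RunManifest) -> None:
    """Co-occurrence, relative abundance, densities, rank tests, KDE overlap."""
    table = pd.read_csv(outdir / "survey_days.csv")
    obs = pd.read_csv(outdir / "observations.csv")
    agg = list(config.aggregation_beaches)

    co_rows = []
    for label, beaches in [("all", None), ("aggregation", agg)]:
        human_any = table[list(HUMAN_GROUPS)].sum(axis=1) > 0
        t = table.assign(any_human=human_any.astype(int))
        for g in ["any_human", *HUMAN_GROUPS]:
            try:
                summary = cooccurrence_rate(t, "shark", g, beaches=beaches)
            except ValueError:
                continue
            co_rows.append({"scope": label, "group": g,
                            "co_days": summary.n_cooccurrence_days,
                            "eligible_days": summary.n_eligible_days,
                            "rate": summary.rate, "percent": summary.percent(1),
                            "mean_sharks": summary.mean_abundance_a,
                            "mean_group": summary.mean_abundance_b})
    co = pd.DataFrame(co_rows)

    rel = relative_abundance(table, HUMAN_GROUPS)

    dens_rows = []
    for b in range(config.n_beaches):
        coast = generate_coast(config, b)
        area = surveyed_area_ha(coast.shoreline, config.offshore_extent)
        dens_rows.append({"beach": b, "surveyed_area_ha": area,
                          "max_sharks_per_ha": max_density(table, area, beach=b)})
    dens = pd.DataFrame(dens_rows)

    groups_present = [g for g in GROUPS
                      if (obs["group"] == g).sum() >= 2]
    dist_samples = {g: obs.loc[obs["group"] == g, "dist_break_m"].dropna().to_numpy()
                    for g in groups_present}
    dist_samples = {g: v for g, v in dist_samples.items() if len(v) >= 2}
    test_rows = []
    if len(dist_samples) >= 2:
        res = rank_tests(dist_samples)
        kw = res["kruskal"]
        test_rows.append({"test": "kruskal", "groups": "|".join(kw.groups),
                          "statistic": kw.statistic, "p": kw.p_value, "p_adj": ""})
        for r in res["dunn"]:
            test_rows.append({"test": "dunn", "groups": "|".join(r.groups),
                              "statistic": r.statistic, "p": r.p_value,
                              "p_adj": r.p_adjusted})
    tests = pd.DataFrame(test_rows, columns=["test", "groups", "statistic",
                                             "p", "p_adj"])

    kde_rows = []
    from .io import write_polygons_geojson
    for b in agg:
        sharks = obs[(obs["beach"] == b) & (obs["group"] == "shark")][["x", "y"]]
        humans = obs[(obs["beach"] == b) & (obs["group"] != "shark")][["x", "y"]]
        if len(sharks) < 10 or len(humans) < 10:
            continue
        ov = kde_overlap(sharks.to_numpy(), humans.to_numpy())
        kde_rows.append({"beach": b,
                         "shark_area50_km2": ov["area_a"][0.5] / 1e6,
                         "shark_area95_km2": ov["area_a"][0.95] / 1e6,
                         "human_area50_km2": ov["area_b"][0.5] / 1e6,
                         "human_area95_km2": ov["area_b"][0.95] / 1e6,
                         "overlap_fraction": ov["overlap_fraction"],
                         "shark_conditional_overlap": ov["conditional_overlap_a"]})
    kde = pd.DataFrame(kde_rows, columns=["beach", "shark_area50_km2",
                                          "shark_area95_km2", "human_area50_km2",
                                          "human_area95_km2", "overlap_fraction",
                                          "shark_conditional_overlap"])

    quant = (obs.dropna(subset=["dist_break_m"])
             .groupby("group")["dist_break_m"]
             .describe(percentiles=[0.25, 0.5, 0.75]).reset_index())

    outputs = []
    for name, df in [("cooccurrence", co), ("relative_abundance", rel),
                     ("density", dens), ("rank_tests", tests),
                     ("kde_overlap", kde), ("distance_quantiles", quant)]:
        p = outdir / f"stats_{name}.csv"
        write_csv(df, p)
        outputs.append(p)
    manifest.record("stats", outputs, {"cooccurrence_rows": len(co),
                                       "kde_rows": len(kde)})


def stage_envmodel(config: GeneratorConfig, outdir: Path, manifest: RunManifest) -> None:
    """Stepwise covariate selection + pruning per group, term table out."""
    table = pd.read_csv(outdir / "survey_days.csv")
    env = pd.read_csv(outdir / "environment.csv")
    data = table.merge(env, on=["beach", "day"])
    candidates = ["wave_height", "mean_wave_period", "sst", "sst_anomaly",
                  "wind_speed", "uv_b", "tidal_range", "lunar_illumination",
                  "total_cloud_cover", "month"]
    candidates = [c for c in candidates if data[c].nunique() > 3]
    rows = []
    for group in GROUPS:
        if data[group].sum() < 10:
            continue
        sel = stepwise_select(data, group, candidates, factor=["beach"])
        pruned = redundancy_prune(data, group, sel["selected"], factor=["beach"])
        final = pruned["final"]
        if final:
            alphas = select_smoothing(data, group, final)
            res = AdditiveCountModel.from_dataframe(
                data, group, smooth=final, factor=["beach"], alpha=alphas).fit()
            shapes = res.effect_shapes()
            for t in final:
                rows.append({"group": group, "term": t,
                             "edf": res.fit.term_edf.get(t, float("nan")),
                             "shape": shapes.get(t, ""),
                             "family": res.fit.family, "aic": res.aic})
        else:
            rows.append({"group": group, "term": "(intercept)", "edf": 0.0,
                         "shape": "", "family": "poisson", "aic": sel["aic"]})
    terms = pd.DataFrame(rows)
    p = outdir / "envmodel_terms.csv"
    write_csv(terms, p)
    manifest.record("envmodel", [p], {"term_rows": len(terms)})


def write_report(outdir) -> Path:
    """Assemble the run's summary document from the stage CSVs."""
    outdir = Path(outdir)
    needed = ["stats_cooccurrence.csv", "stats_relative_abundance.csv",
              "stats_distance_quantiles.csv", "stats_kde_overlap.csv",
              "envmodel_terms.csv"]
    missing = [n for n in needed if not (outdir / n).exists()]
    if missing:
        raise FileNotFoundError(f"missing stage outputs: {missing}")
    parts = ["# Survey run report", ""]
    titles = {"stats_cooccurrence.csv": "Shark-human co-occurrence by survey day",
              "stats_relative_abundance.csv": "Relative abundance of water users",
              "stats_distance_quantiles.csv": "Signed distance to wave break by group (m)",
              "stats_kde_overlap.csv": "KDE space use and 95% overlap at aggregation beaches",
              "envmodel_terms.csv": "Selected environmental terms per group"}
    for name in needed:
        df = pd.read_csv(outdir / name)
        parts.append(f"## {titles[name]}")
        parts.append("" if len(df) else "(no rows)")
        if len(df):
            parts.append(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        parts.append("")
    path = outdir / "report.md"
    path.write_text("\n".join(parts))
    return path
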