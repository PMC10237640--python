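"""Configuration for the synthetic survey generator.

The generator emulates the statistical structure a nearshore drone survey of
shark-human overlap assumes: a handful of beaches of which a couple host
persistent shark aggregations, water users clumped alongshore around public
beach-access points, group-specific cross-shore placement relative to the
wave break (waders strictly shoreward; surfers and swimmers near the break;
stand-up paddlers farthest seaward; sharks on a long-tailed seaward law with
median 101 m), imperfect surface availability of sharks (~0.7 per pass), and
log-link environmental effects on daily expected counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml

GROUPS = ("wader", "swimmer", "bodyboarder", "surfer", "SUP", "shark")
HUMAN_GROUPS = GROUPS[:-1]


@dataclass
class CrossShoreLaw:
    """Distribution of signed distance to the wave break for one group.

    family: 'uniform' (low, high), 'normal' (mean, sd, optional truncation),
    or 'lognormal' (median, sigma) which is strictly seaward.
    Signed metres: negative shoreward of the break, positive seaward.
    """

    family: str
    params: dict = field(default_factory=dict)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], size=n)
        if self.family == "normal":
            lo = p.get("trunc_low", -np.inf)
            hi = p.get("trunc_high", np.inf)
            out = rng.normal(p["mean"], p["sd"], size=n)
            bad = (out < lo) | (out > hi)
            # rejection sampling for truncation; the laws used are far from degenerate
            while bad.any():
                out[bad] = rng.normal(p["mean"], p["sd"], size=int(bad.sum()))
                bad = (out < lo) | (out > hi)
            return out
        if self.family == "lognormal":
            return rng.lognormal(np.log(p["median"]), p["sigma"], size=n)
        raise ValueError(f"unknown cross-shore family {self.family!r}")


@dataclass
class GroupParams:
    """Per-group placement and abundance parameters.

    base_mean: expected daily count per beach before covariate effects and
    (for sharks) aggregation scaling.  alongshore_scale: sd (m) of the
    Gaussian clusters around access points (humans) or hotspots (sharks);
    None disables clustering (uniform alongshore).
    """

    cross_shore: CrossShoreLaw
    base_mean: float
    alongshore_scale: float | None = 80.0


@dataclass
class CovariateEffect:
    """A smooth effect f(covariate) added to a group's log daily mean.

    shape 'linear': coef * (x - center); shape 'parabola': scale * (x - center)**2
    (scale < 0 gives a single interior peak at `center`).
    """

    covariate: str
    shape: str
    coef: float = 0.0
    center: float = 0.0
    scale: float = 0.0

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.shape == "linear":
            return self.coef * (x - self.center)
        if self.shape == "parabola":
            return self.scale * (x - self.center) ** 2
        raise ValueError(f"unknown effect shape {self.shape!r}")


def default_group_params() -> dict[str, GroupParams]:
    """Cross-shore laws ordered as observed in the field: waders strictly
    shoreward, bodyboarders straddling the inner surf, swimmers and surfers
    around the break, SUP farthest seaward, sharks lognormal with median
    101 m and sigma 1.1 (central 99.9% spanning roughly 2-700 m)."""
    return {
        "wader": GroupParams(CrossShoreLaw("uniform", {"low": -40.0, "high": 0.0}),
                             base_mean=6.0),
        "bodyboarder": GroupParams(CrossShoreLaw("normal", {"mean": -10.0, "sd": 15.0,
                                                            "trunc_high": 0.0}),
                                   base_mean=1.2),
        "swimmer": GroupParams(CrossShoreLaw("normal", {"mean": 10.0, "sd": 25.0}),
                               base_mean=0.8),
        "surfer": GroupParams(CrossShoreLaw("normal", {"mean": 25.0, "sd": 30.0}),
                              base_mean=5.0),
        "SUP": GroupParams(CrossShoreLaw("normal", {"mean": 120.0, "sd": 60.0,
                                                    "trunc_low": 0.0}),
                           base_mean=0.3),
        # ~15 sharks present per aggregation-beach day: daily sighting counts at
        # persistent aggregations run from a handful in winter to tens in summer
        "shark": GroupParams(CrossShoreLaw("lognormal", {"median": 101.0, "sigma": 1.1}),
                             base_mean=15.0, alongshore_scale=150.0),
    }


def default_covariate_effects() -> dict[str, list[CovariateEffect]]:
    """Log-link effects on daily expected counts.

    Humans: warmer water brings more people, wind keeps them away, and board
    sports peak at moderate (~1 m) wave height.  Sharks: abundance peaks at
    low wave height and falls with negative temperature anomalies.
    """
    return {
        "wader": [CovariateEffect("sst", "linear", coef=0.10, center=17.0),
                  CovariateEffect("wind_speed", "linear", coef=-0.08, center=4.0)],
        "swimmer": [CovariateEffect("sst", "linear", coef=0.12, center=17.0)],
        "bodyboarder": [CovariateEffect("sst", "linear", coef=0.10, center=17.0),
                        CovariateEffect("mean_wave_period", "linear", coef=-0.10, center=8.0)],
        "surfer": [CovariateEffect("wave_height", "parabola", center=1.0, scale=-0.8),
                   CovariateEffect("sst", "linear", coef=0.06, center=17.0)],
        "SUP": [CovariateEffect("wind_speed", "linear", coef=-0.15, center=4.0)],
        "shark": [CovariateEffect("wave_height", "parabola", center=0.8, scale=-0.6),
                  CovariateEffect("sst_anomaly", "linear", coef=0.25, center=0.0)],
    }


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic coast-wide survey campaign."""

    seed: int = 0
    n_beaches: int = 12
    beach_length: float = 1000.0  # one survey transect's alongshore span
    offshore_extent: float = 500.0
    access_points: Sequence[float] | None = None  # alongshore metres, shared by beaches
    aggregation_beaches: Sequence[int] = (0, 1)
    group_params: dict[str, GroupParams] = field(default_factory=default_group_params)
    shark_median_distance: float = 101.0
    shark_sigma: float = 1.1
    shark_surface_prob: float = 0.7
    mark_fraction: float = 0.3
    non_aggregation_shark_factor: float = 0.02
    covariate_effects: dict[str, list[CovariateEffect]] = field(
        default_factory=default_covariate_effects)
    n_days: int = 60
    # coast shape
    break_offset_mean: float = 50.0
    break_offset_amplitude: float = 10.0
    break_offset_wavelength: float = 500.0
    # flight
    survey_speed: float = 5.75  # m/s, mid-range of the 5.5-6.0 manual envelope
    frame_interval: float = 5.0  # s
    first_leg_altitude: float = 90.0
    later_leg_altitude: float = 60.0
    first_leg_length: float = 1000.0
    leg_spacing: float = 50.0

    def __post_init__(self) -> None:
        for p in (self.shark_surface_prob, self.mark_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.shark_median_distance <= 0:
            raise ValueError("shark_median_distance must be positive")
        if self.offshore_extent <= 0:
            raise ValueError("offshore_extent must be positive")
        if self.beach_length <= 0:
            raise ValueError("beach_length must be positive")
        bad = [b for b in self.aggregation_beaches if not 0 <= b < self.n_beaches]
        if bad:
            raise ValueError(f"aggregation beaches {bad} outside 0..{self.n_beaches - 1}")
        if self.access_points is None:
            # two public access points, as at a typical low-use beach
            self.access_points = (0.35 * self.beach_length, 0.65 * self.beach_length)
        # keep the configured shark law and the convenience fields coherent
        law = self.group_params["shark"].cross_shore
        if law.family == "lognormal":
            law.params["median"] = self.shark_median_distance
            law.params["sigma"] = self.shark_sigma

    def rng_for(self, *stream: object) -> np.random.Generator:
        """Deterministic child generator for a named stream, derived from the root seed."""
        import zlib

        keys = tuple(zlib.crc32(repr(s).encode()) for s in stream)
        ss = np.random.SeedSequence(self.seed, spawn_key=keys)
        return np.random.default_rng(ss)


def _to_plain(obj):
    if isinstance(obj, (CrossShoreLaw, GroupParams, CovariateEffect, GeneratorConfig)):
        return {k: _to_plain(v) for k, v in vars(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config: GeneratorConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def load_config(path) -> GeneratorConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> GeneratorConfig:
    raw = dict(raw)
    if "group_params" in raw:
        gp = {}
        for name, d in raw["group_params"].items():
            law = d["cross_shore"]
            gp[name] = GroupParams(
                cross_shore=CrossShoreLaw(law["family"], dict(law["params"])),
                base_mean=d["base_mean"],
                alongshore_scale=d.get("alongshore_scale", 80.0),
            )
        raw["group_params"] = gp
    if "covariate_effects" in raw:
        ce = {}
        for name, effects in raw["covariate_effects"].items():
            ce[name] = [CovariateEffect(**e) for e in effects]
        raw["covariate_effects"] = ce
    return GeneratorConfig(**raw)
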