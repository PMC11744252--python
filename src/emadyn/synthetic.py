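"""Synthetic EMA world: ordinal arousal ratings with known ground truth.

The generator emulates a one-day ecological momentary assessment (EMA)
protocol: each participant carries an Insomnia Severity Index (ISI) total
(0-28) and rates four arousal-related items (anxious/nervous, stressed,
sleepy, down) on a 0-8 ordinal scale at six scheduled occasions between
~08:00 and midnight.  The latent trajectory for participant *i*, item *m*,
occasion *j* at clock time ``t_ij`` is

    y*_ijm = baseline_m(t_ij) + level_slope_m * ISI_i
             + interaction_m(ISI_i, t_ij) + b_i + e_ijm

with a person random intercept ``b_i ~ N(0, random_intercept_sd^2)`` shared
across items, and AR(1) residuals across occasions whose innovation SD grows
linearly with ISI (this is what makes high-ISI series more *unstable*, i.e.
raises their MSSD).  Observed ratings are the latent values rounded
half-to-even and clipped to the 0-8 grid; cells are deleted completely at
random with probability ``missing_rate``.

Every stochastic quantity flows from a single :class:`numpy.random.Generator`
so identical config + seed gives byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

ISI_MIN, ISI_MAX = 0, 28
RATING_MIN, RATING_MAX = 0, 8

#: canonical long-format column order
LONG_COLUMNS = [
    "participant_id",
    "isi",
    "assessment_index",
    "time_of_day",
    "item",
    "rating",
]

DEFAULT_ITEMS = ("anxious", "stressed", "sleepy", "down")


class ConfigError(ValueError):
    """Raised for an invalid :class:`SimulationConfig`."""


@dataclass(frozen=True)
class HarmonicCurve:
    """Diurnal baseline as a constant plus low-order 24-h harmonics.

    ``harmonics`` is a sequence of ``(order, amplitude, phase_hours)``;
    each term contributes ``amplitude * cos(2*pi*order*(t - phase)/24)``.
    """

    const: float
    harmonics: tuple[tuple[float, float, float], ...] = ()

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.const, dtype=float)
        for order, amp, phase in self.harmonics:
            out = out + amp * np.cos(2.0 * np.pi * order * (t - phase) / 24.0)
        return out


def _gauss_windows(t, windows: Sequence[tuple[float, float]]) -> np.ndarray:
    """Sum of unit-height Gaussian bumps centred at (center, width) pairs."""
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape, dtype=float)
    for center, width in windows:
        out = out + np.exp(-0.5 * ((t - center) / width) ** 2)
    return out


def _default_baselines() -> dict[str, HarmonicCurve]:
    # Shapes follow the qualitative diurnal pattern of each symptom:
    # anxiety peaks early morning + evening, stress peaks in the evening,
    # sleepiness is U-shaped (high at both ends of the waking day), and
    # feeling down is essentially flat at the group level.
    return {
        "anxious": HarmonicCurve(1.8, ((1, 0.30, 20.0), (2, 0.25, 8.0))),
        "stressed": HarmonicCurve(2.0, ((1, 0.40, 19.0),)),
        "sleepy": HarmonicCurve(3.2, ((1, 1.00, 28.0),)),
        "down": HarmonicCurve(1.5, ()),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of the synthetic EMA world.

    Defaults reproduce the study-scale conditions: 361 participants, ISI
    distribution with mean 9.1 / SD 5.2, six occasions from ~08:30 to ~23:00
    (timestamps may run past midnight, encoded as hours > 24), four items,
    8.8% missing cells, ISI-dependent levels (slopes per item on the order of
    0.12-0.14 rating points per ISI point) and ISI-dependent instability.
    """

    n_participants: int = 361
    isi_mean: float = 9.1
    isi_sd: float = 5.2
    schedule: tuple[float, ...] = (8.5, 11.4, 14.3, 17.2, 20.1, 23.0)
    time_jitter_sd: float = 0.5
    items: tuple[str, ...] = DEFAULT_ITEMS
    baseline_curve: Mapping[str, HarmonicCurve] = field(
        default_factory=_default_baselines
    )
    isi_level_slope: Mapping[str, float] = field(
        default_factory=lambda: {
            "anxious": 0.118,
            "stressed": 0.140,
            "sleepy": 0.115,
            "down": 0.131,
        }
    )
    interaction_amplitude: Mapping[str, float] = field(
        default_factory=lambda: {
            "anxious": 0.5,
            "stressed": 0.5,
            "sleepy": 0.5,
            "down": 0.0,
        }
    )
    interaction_windows: Mapping[str, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: {
            "anxious": ((8.0, 1.2), (19.0, 2.5)),
            "stressed": ((19.0, 2.0),),
            "sleepy": ((13.0, 4.0),),
            "down": (),
        }
    )
    random_intercept_sd: float = 1.0
    innovation_sd_base: float = 0.8
    innovation_sd_isi_slope: float = 0.032
    ar1_coefficient: float = 0.3
    missing_rate: float = 0.088
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        sched = np.asarray(self.schedule, dtype=float)
        if sched.size < 1 or np.any(np.diff(sched) <= 0):
            raise ConfigError("schedule times must be strictly increasing")
        if sched.min() < 8.0 or sched.max() > 24.0:
            raise ConfigError("schedule times must lie in [8, 24] hours")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if not (-1.0 < self.ar1_coefficient < 1.0):
            raise ConfigError("ar1_coefficient must be in (-1, 1)")
        for name in (
            "isi_sd",
            "time_jitter_sd",
            "random_intercept_sd",
            "innovation_sd_base",
            "innovation_sd_isi_slope",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if len(self.items) < 1:
            raise ConfigError("at least one item required")
        for item in self.items:
            for mapping, label in (
                (self.baseline_curve, "baseline_curve"),
                (self.isi_level_slope, "isi_level_slope"),
                (self.interaction_amplitude, "interaction_amplitude"),
                (self.interaction_windows, "interaction_windows"),
            ):
                if item not in mapping:
                    raise ConfigError(f"{label} missing entry for item {item!r}")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    # -- population-level truth ------------------------------------------------

    def conditional_mean(self, item: str, isi, time_of_day) -> np.ndarray:
        """Latent conditional mean surface (random intercept at zero).

        Broadcasts ``isi`` against ``time_of_day``; this is the ground-truth
        surface the diurnal GAM is asked to recover.
        """
        isi = np.asarray(isi, dtype=float)
        t = np.asarray(time_of_day, dtype=float)
        base = self.baseline_curve[item](t)
        level = self.isi_level_slope[item] * isi
        # interaction scales with standardized ISI, so `interaction_amplitude`
        # is the rating-point elevation inside the window per SD of ISI; the
        # window profile is centered over the nominal schedule so the
        # interaction redistributes symptoms across the day without shifting
        # the per-person daily mean (the level effect stays isi_level_slope)
        z = (isi - self.isi_mean) / (self.isi_sd if self.isi_sd > 0 else 1.0)
        windows = self.interaction_windows[item]
        profile = _gauss_windows(t, windows)
        if windows:
            profile = profile - float(
                np.mean(_gauss_windows(np.asarray(self.schedule), windows))
            )
        inter = self.interaction_amplitude[item] * z * profile
        return base + level + inter

    # -- YAML round trip -------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_curve"] = {
            k: {"const": v.const, "harmonics": [list(h) for h in v.harmonics]}
            for k, v in self.baseline_curve.items()
        }
        d["interaction_windows"] = {
            k: [list(w) for w in v] for k, v in self.interaction_windows.items()
        }
        d["schedule"] = list(self.schedule)
        d["items"] = list(self.items)
        d["isi_level_slope"] = dict(self.isi_level_slope)
        d["interaction_amplitude"] = dict(self.interaction_amplitude)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "baseline_curve" in d:
            d["baseline_curve"] = {
                k: HarmonicCurve(
                    float(v["const"]),
                    tuple(tuple(float(x) for x in h) for h in v.get("harmonics", [])),
                )
                for k, v in d["baseline_curve"].items()
            }
        if "interaction_windows" in d:
            d["interaction_windows"] = {
                k: tuple(tuple(float(x) for x in w) for w in v)
                for k, v in d["interaction_windows"].items()
            }
        for key in ("schedule", "items"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyst is not shown.

    Arrays are indexed ``[participant, occasion]`` (and ``item`` last where
    applicable); ``missing_mask`` is True where the emitted record has its
    rating deleted.  ``complete_ratings`` holds the rounded/clipped ratings
    before deletion, so imputation error can be scored exactly.
    """

    participant_ids: np.ndarray  # (n_p,)
    isi: np.ndarray  # (n_p,)
    times: np.ndarray  # (n_p, n_t)
    intercepts: np.ndarray  # (n_p,)
    items: tuple[str, ...]
    latent: np.ndarray  # (n_p, n_t, n_items)
    complete_ratings: np.ndarray  # (n_p, n_t, n_items) ints
    missing_mask: np.ndarray  # (n_p, n_t, n_items) bool


def _truncnorm_params(mean: float, sd: float, lo: float, hi: float):
    """Parent (loc, scale) whose [lo, hi]-truncated normal has the given moments.

    Truncation at 0 alone would inflate the mean of a N(9.1, 5.2^2) by ~0.4
    points, so the parent distribution is moment-matched instead of being
    parameterised directly by the target mean/SD.
    """

    def moments(params):
        loc, log_scale = params
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(moments, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - well-posed for in-range targets
        raise RuntimeError(f"truncated-normal moment matching failed: {sol.message}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def draw_isi(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw integer ISI totals in [0, 28] for every participant.

    Scores come from a truncated normal moment-matched to the configured
    mean/SD, then rounded to the integer grid.  ``isi_sd == 0`` degenerates
    to every participant scoring ``round(isi_mean)``.
    """
    n = config.n_participants
    if n < 1:
        raise ConfigError("n_participants must be >= 1")
    if config.isi_sd == 0:
        return np.full(n, int(np.clip(round(config.isi_mean), ISI_MIN, ISI_MAX)))
    loc, scale = _truncnorm_params(
        config.isi_mean, config.isi_sd, ISI_MIN - 0.5, ISI_MAX + 0.5
    )
    a, b = (ISI_MIN - 0.5 - loc) / scale, (ISI_MAX + 0.5 - loc) / scale
    draws = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
    return np.clip(np.rint(draws), ISI_MIN, ISI_MAX).astype(int)


def simulate_dataset(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one long-format EMA dataset plus its ground truth.

    Returns ``(records, truth)`` where ``records`` has the canonical columns
    ``participant_id, isi, assessment_index, time_of_day, item, rating``
    (rating is float with NaN for deleted cells) sorted by participant,
    occasion, item.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_p = config.n_participants
    n_t = len(config.schedule)
    items = config.items
    n_m = len(items)

    isi = draw_isi(config, rng)

    # occasion times: schedule + Gaussian jitter, forced strictly increasing,
    # floored at 08:00; the last occasion may spill past midnight (> 24 h)
    times = np.asarray(config.schedule, float) + rng.normal(
        0.0, config.time_jitter_sd, size=(n_p, n_t)
    )
    times[:, 0] = np.maximum(times[:, 0], 8.0)
    for j in range(1, n_t):
        times[:, j] = np.maximum(times[:, j], times[:, j - 1] + 1e-3)
    times = np.minimum(times, 25.0)

    intercepts = rng.normal(0.0, config.random_intercept_sd, size=n_p)

    innov_sd = config.innovation_sd_base + config.innovation_sd_isi_slope * isi
    phi = config.ar1_coefficient
    stat_scale = 1.0 / np.sqrt(1.0 - phi**2)

    latent = np.empty((n_p, n_t, n_m))
    for m, item in enumerate(items):
        e = np.empty((n_p, n_t))
        z = rng.normal(0.0, 1.0, size=(n_p, n_t))
        e[:, 0] = z[:, 0] * innov_sd * stat_scale  # stationary start
        for j in range(1, n_t):
            e[:, j] = phi * e[:, j - 1] + z[:, j] * innov_sd
        latent[:, :, m] = (
            config.conditional_mean(item, isi[:, None], times)
            + intercepts[:, None]
            + e
        )

    complete = np.clip(np.rint(latent), RATING_MIN, RATING_MAX).astype(int)
    missing = rng.random(size=(n_p, n_t, n_m)) < config.missing_rate

    participant_ids = np.arange(1, n_p + 1)
    truth = GroundTruth(
        participant_ids=participant_ids,
        isi=isi,
        times=times,
        intercepts=intercepts,
        items=items,
        latent=latent,
        complete_ratings=complete,
        missing_mask=missing,
    )

    rating = complete.astype(float)
    rating[missing] = np.nan
    records = pd.DataFrame(
        {
            "participant_id": np.repeat(participant_ids, n_t * n_m),
            "isi": np.repeat(isi, n_t * n_m),
            "assessment_index": np.tile(np.repeat(np.arange(1, n_t + 1), n_m), n_p),
            "time_of_day": np.repeat(times.reshape(-1), n_m),
            "item": np.tile(np.asarray(items, dtype=object), n_p * n_t),
            "rating": rating.reshape(-1),
        }
    )
    return records, truth


# -- long CSV round trip -------------------------------------------------------


def validate_records(records: pd.DataFrame) -> None:
    """Check the long-format schema and value ranges; raise ValueError."""
    missing_cols = [c for c in LONG_COLUMNS if c not in records.columns]
    if missing_cols:
        raise ValueError(f"records missing columns: {missing_cols}")
    isi = records["isi"].to_numpy()
    bad = np.flatnonzero((isi < ISI_MIN) | (isi > ISI_MAX))
    if bad.size:
        raise ValueError(f"isi out of [0, 28] at row {bad[0]}")
    r = records["rating"].to_numpy(dtype=float)
    obs = ~np.isnan(r)
    bad = np.flatnonzero(obs & ((r < RATING_MIN) | (r > RATING_MAX) | (r != np.rint(r))))
    if bad.size:
        raise ValueError(f"rating not an integer in [0, 8] at row {bad[0]}")
    t = records["time_of_day"].to_numpy(dtype=float)
    bad = np.flatnonzero((t < 8.0) | (t > 25.0))
    if bad.size:
        raise ValueError(f"time_of_day out of [8, 25] at row {bad[0]}")


def write_long_csv(records: pd.DataFrame, path) -> None:
    """Write records to CSV; missing ratings become empty fields."""
    out = records.loc[:, LONG_COLUMNS].copy()
    out["rating"] = pd.Series(
        out["rating"].to_numpy(dtype=float), index=out.index
    ).round().astype("Int64")
    out.to_csv(path, index=False)


def read_long_csv(path) -> pd.DataFrame:
    """Read a long-format ratings CSV written by :func:`write_long_csv`."""
    try:
        df = pd.read_csv(
            path,
            dtype={
                "participant_id": "int64",
                "isi": "int64",
                "assessment_index": "int64",
                "time_of_day": "float64",
                "item": "object",
                "rating": "Int64",
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed long CSV {path}: {exc}") from exc
    missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    df["rating"] = df["rating"].astype("float64")
    df = df.loc[:, LONG_COLUMNS]
    validate_records(df)
    return df
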