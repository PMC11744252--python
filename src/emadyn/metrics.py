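"""Per-person, per-item dynamics statistics for short EMA series.

Four outcomes summarise each participant's within-day series for one item:

* ``mean_level`` — arithmetic mean of the observed ratings;
* ``sd`` — sample standard deviation (n−1 denominator): *variability*;
* ``mssd`` — mean squared successive difference, the average of
  ``(x[t+1] − x[t])**2`` over consecutive observed pairs: *instability*;
* ``acf1`` — lag-1 autocorrelation,
  ``sum((x[t]−m)(x[t+1]−m)) / sum((x[t]−m)**2)``: *inertia* / resistance to
  change.  The divisor-n autocovariance normalisation biases the estimate
  toward zero for very short series (6 points here); that is the estimator
  as defined and is kept.

Undefined statistics (too few observations, zero-variance series for acf1)
are signalled as NaN.  Missing ratings are handled by the *pair policy*:
``skip_gaps`` (default) forms successive pairs between consecutive observed
occasions, bridging gaps; ``adjacent_only`` only pairs occasions whose
assessment indices differ by exactly 1.

A sample-level outlier rule marks metric values more than ``threshold`` SDs
from the column mean (computed once, not iteratively) as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PAIR_POLICIES = ("skip_gaps", "adjacent_only")
METRIC_NAMES = ("mean_level", "sd", "mssd", "acf1")


def _observed(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[~np.isnan(x)]


def mean_level(x) -> float:
    """Mean of observed ratings; NaN if nothing observed."""
    obs = _observed(x)
    return float(obs.mean()) if obs.size >= 1 else float("nan")


def variability_sd(x) -> float:
    """Sample SD (n−1 denominator) of observed ratings; NaN if < 2 observed."""
    obs = _observed(x)
    return float(obs.std(ddof=1)) if obs.size >= 2 else float("nan")


def instability_mssd(
    x, positions=None, pair_policy: str = "skip_gaps"
) -> float:
    """Mean squared successive difference over consecutive observed pairs.

    ``positions`` (assessment indices, same length as ``x``) is required for
    ``pair_policy='adjacent_only'``, where only pairs of occasions with
    consecutive indices are used.
    """
    if pair_policy not in PAIR_POLICIES:
        raise ValueError(f"pair_policy must be one of {PAIR_POLICIES}")
    x = np.asarray(x, dtype=float)
    obs_mask = ~np.isnan(x)
    if obs_mask.sum() < 2:
        return float("nan")
    if pair_policy == "skip_gaps":
        obs = x[obs_mask]
        d = np.diff(obs)
        return float(np.mean(d**2))
    if positions is None:
        positions = np.arange(x.size)
    positions = np.asarray(positions)
    both = obs_mask[:-1] & obs_mask[1:] & (np.diff(positions) == 1)
    if not both.any():
        return float("nan")
    d = (x[1:] - x[:-1])[both]
    return float(np.mean(d**2))


def inertia_acf1(x) -> float:
    """Lag-1 autocorrelation of the observed series.

    Requires >= 3 observed values and a non-constant series; the numerator
    sums lagged cross-products of deviations and the denominator is the
    full-series sum of squared deviations, so |acf1| <= 1 always.
    """
    obs = _observed(x)
    if obs.size < 3:
        return float("nan")
    dev = obs - obs.mean()
    den = float(np.sum(dev**2))
    if den == 0.0:
        return float("nan")
    num = float(np.sum(dev[:-1] * dev[1:]))
    return num / den


def dynamics_wide(x: np.ndarray, pair_policy: str = "skip_gaps") -> dict:
    """Vectorised dynamics statistics over rows of a (series × occasion) array.

    ``x`` holds one series per row (NaN = missing), occasions in time order.
    Returns arrays ``n_obs, mean_level, sd, mssd, acf1`` of length
    ``x.shape[0]``.  Equivalent to looping the scalar functions row-wise.
    """
    if pair_policy not in PAIR_POLICIES:
        raise ValueError(f"pair_policy must be one of {PAIR_POLICIES}")
    x = np.asarray(x, dtype=float)
    nan = np.isnan(x)
    cnt = (~nan).sum(axis=1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(nan, np.nan, x), axis=1)
        sd = np.nanstd(x, axis=1, ddof=1)
    mean = np.where(cnt >= 1, mean, np.nan)
    sd = np.where(cnt >= 2, sd, np.nan)

    # compact observed values to the left, preserving order
    order = np.argsort(nan, axis=1, kind="stable")
    xc = np.take_along_axis(x, order, axis=1)
    col = np.arange(x.shape[1])[None, :]
    valid = col < cnt[:, None]
    xc = np.where(valid, xc, 0.0)

    if pair_policy == "skip_gaps":
        pair_ok = (col[:, :-1] + 1) < cnt[:, None]
        d = xc[:, 1:] - xc[:, :-1]
        n_pairs = pair_ok.sum(axis=1)
    else:
        pair_ok = ~nan[:, :-1] & ~nan[:, 1:]
        d = np.where(pair_ok, np.diff(np.where(nan, 0.0, x), axis=1), 0.0)
        # recompute true diffs only over valid pairs
        d = np.where(pair_ok, x[:, 1:] - x[:, :-1], 0.0)
        n_pairs = pair_ok.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mssd = np.where(
            (cnt >= 2) & (n_pairs >= 1),
            (d**2 * pair_ok).sum(axis=1) / np.maximum(n_pairs, 1),
            np.nan,
        )

    dev = np.where(valid, xc - np.where(np.isnan(mean), 0.0, mean)[:, None], 0.0)
    den = (dev**2).sum(axis=1)
    lag_ok = (col[:, :-1] + 1) < cnt[:, None]
    num = (dev[:, :-1] * dev[:, 1:] * lag_ok).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        acf1 = np.where((cnt >= 3) & (den > 0), num / np.where(den > 0, den, 1.0), np.nan)

    return {
        "n_obs": cnt,
        "mean_level": mean,
        "sd": sd,
        "mssd": mssd,
        "acf1": acf1,
    }


def compute_profiles(
    records: pd.DataFrame, pair_policy: str = "skip_gaps"
) -> pd.DataFrame:
    """One dynamics profile per (participant, item) from long-format records.

    Metrics are computed on *observed* (non-imputed) ratings in occasion
    order; undefined metrics are carried as NaN.
    """
    items = list(pd.unique(records["item"]))
    wide = records.pivot(
        index=["participant_id", "item"],
        columns="assessment_index",
        values="rating",
    ).sort_index(axis=1)
    stats = dynamics_wide(wide.to_numpy(dtype=float), pair_policy=pair_policy)
    out = wide.index.to_frame(index=False)
    for key in ("n_obs", "mean_level", "sd", "mssd", "acf1"):
        out[key] = stats[key]
    out["item"] = pd.Categorical(out["item"], categories=items, ordered=True)
    out = out.sort_values(["participant_id", "item"]).reset_index(drop=True)
    out["item"] = out["item"].astype(str)
    return out


@dataclass
class OutlierRule:
    """Record of the sample-level |z| > threshold removal."""

    threshold_sd: float = 4.0
    removed: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be > 0")


def remove_outliers(values, threshold: float = 4.0):
    """Set values beyond ``threshold``·SD from the column mean to NaN.

    Mean and SD are computed once over the defined values (non-iterative).
    Returns ``(filtered array, list of (index, value, z))``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    v = np.asarray(values, dtype=float).copy()
    obs = ~np.isnan(v)
    if obs.sum() < 2:
        warnings.warn("outlier rule skipped: fewer than 2 defined values")
        return v, []
    m = v[obs].mean()
    s = v[obs].std(ddof=1)
    if s == 0.0:
        return v, []
    z = (v - m) / s
    flag = obs & (np.abs(z) > threshold)
    removed = [(int(i), float(v[i]), float(z[i])) for i in np.flatnonzero(flag)]
    v[flag] = np.nan
    return v, removed


def apply_outlier_rule(
    profiles: pd.DataFrame,
    metrics: tuple[str, ...] = METRIC_NAMES,
    threshold: float = 4.0,
) -> tuple[pd.DataFrame, OutlierRule]:
    """Apply the sample-level rule per (metric, item) column of a profile table."""
    out = profiles.copy()
    rule = OutlierRule(threshold_sd=threshold)
    for item in pd.unique(out["item"]):
        sel = out["item"] == item
        for metric in metrics:
            filtered, removed = remove_outliers(
                out.loc[sel, metric].to_numpy(), threshold=threshold
            )
            out.loc[sel, metric] = filtered
            idx = out.index[sel]
            for local_i, value, z in removed:
                pid = out.loc[idx[local_i], "participant_id"]
                rule.removed.append((pid, item, metric, value, z))
    return out, rule
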