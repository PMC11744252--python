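"""Time-weighted k-nearest-neighbour imputation of missing ratings.

Missing ordinal ratings are filled from the ``k`` most similar complete
observations of the *same item* across all participants.  Similarity is a
weighted Gower distance over a small feature set — time-of-day, assessment
index, ISI, and the co-rated values of the other items at the same moment —
with every numeric feature range-scaled to [0, 1] and the time-of-day
feature multiplied by ``time_weight`` so temporally close observations
dominate the neighbourhood.  Features missing on either side of a pair are
dropped from the distance (classic Gower handling).  The imputed value is
the inverse-distance-weighted mean (or median) of the donors' ratings,
optionally rounded back to the 0-8 grid.

The procedure is deterministic: distance ties are broken by row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import RATING_MAX, RATING_MIN

EPSILON = 1e-9  # guards inverse-distance weights at exact-zero distance


@dataclass(frozen=True)
class ImputationConfig:
    k: int = 4
    time_weight: float = 4.0
    feature_set: tuple[str, ...] = (
        "time_of_day",
        "assessment_index",
        "isi",
        "co_ratings",
    )
    aggregation: str = "weighted_mean"
    round_to_scale: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.time_weight < 0:
            raise ValueError("time_weight must be >= 0")
        if self.aggregation not in ("weighted_mean", "weighted_median"):
            raise ValueError("aggregation must be weighted_mean or weighted_median")


def missingness_summary(records: pd.DataFrame) -> tuple[int, int, float]:
    """(n_missing, n_total, rate) over item-rating cells."""
    r = records["rating"]
    n_total = int(len(r))
    n_missing = int(r.isna().sum())
    rate = n_missing / n_total if n_total else 0.0
    return n_missing, n_total, rate


def _gower_distances(
    targets: np.ndarray, donors: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Weighted Gower distance between every target row and every donor row.

    Inputs are already range-scaled; NaN features are excluded pairwise and
    the weight mass renormalised over the available features.
    """
    t_nan = np.isnan(targets)
    d_nan = np.isnan(donors)
    t = np.where(t_nan, 0.0, targets)
    d = np.where(d_nan, 0.0, donors)
    # |a - b| with missing features zeroed out
    diff = np.abs(t[:, None, :] - d[None, :, :])
    avail = (~t_nan)[:, None, :] & (~d_nan)[None, :, :]
    w = weights[None, None, :] * avail
    wsum = w.sum(axis=2)
    dist = (diff * w).sum(axis=2) / np.where(wsum > 0, wsum, 1.0)
    dist[wsum == 0] = np.inf
    return dist


def knn_impute(
    records: pd.DataFrame, config: ImputationConfig = ImputationConfig()
) -> tuple[pd.DataFrame, list[dict]]:
    """Fill every missing rating from its k nearest complete donors.

    Returns the completed records (observed ratings untouched) and a log
    with one entry per imputed cell naming the donor rows, distances and
    the imputed value.  Raises if any item has fewer than ``k`` complete
    donor rows.
    """
    items = list(pd.unique(records["item"]))
    wide = records.pivot(
        index=["participant_id", "assessment_index"], columns="item", values="rating"
    )
    meta = (
        records.drop_duplicates(["participant_id", "assessment_index"])
        .set_index(["participant_id", "assessment_index"])
        .loc[wide.index, ["time_of_day", "isi"]]
    )
    n_rows = len(wide)

    # assemble the raw feature matrix: time, index, isi, then all item columns
    assessment_index = wide.index.get_level_values("assessment_index").to_numpy(float)
    base_feats = {
        "time_of_day": meta["time_of_day"].to_numpy(float),
        "assessment_index": assessment_index,
        "isi": meta["isi"].to_numpy(float),
    }
    use_co = "co_ratings" in config.feature_set

    def scaled(col: np.ndarray) -> np.ndarray:
        lo, hi = np.nanmin(col), np.nanmax(col)
        rng = hi - lo
        return (col - lo) / rng if rng > 0 else np.zeros_like(col)

    out = wide.copy()
    log: list[dict] = []
    row_labels = list(wide.index)

    for item in items:
        y = wide[item].to_numpy(float)
        missing_idx = np.flatnonzero(np.isnan(y))
        donor_idx = np.flatnonzero(~np.isnan(y))
        if missing_idx.size == 0:
            continue
        if donor_idx.size < config.k:
            raise ValueError(
                f"item {item!r}: only {donor_idx.size} complete donors "
                f"(need k={config.k})"
            )
        feat_cols, weights = [], []
        for name in ("time_of_day", "assessment_index", "isi"):
            if name in config.feature_set:
                feat_cols.append(scaled(base_feats[name]))
                weights.append(config.time_weight if name == "time_of_day" else 1.0)
        if use_co:
            for other in items:
                if other == item:
                    continue
                feat_cols.append(scaled(wide[other].to_numpy(float)))
                weights.append(1.0)
        if not feat_cols:
            raise ValueError("feature_set selects no features")
        feats = np.column_stack(feat_cols)
        weights = np.asarray(weights, float)
        if np.isnan(feats[missing_idx]).all(axis=1).any():
            raise ValueError(f"item {item!r}: a row has all features missing")

        dist = _gower_distances(feats[missing_idx], feats[donor_idx], weights)
        # k nearest per target; stable sort keeps row order on ties
        nearest = np.argsort(dist, axis=1, kind="stable")[:, : config.k]
        for t_local, t_row in enumerate(missing_idx):
            sel = nearest[t_local]
            d = dist[t_local, sel]
            donors = donor_idx[sel]
            w = 1.0 / (d + EPSILON)
            vals = y[donors]
            if config.aggregation == "weighted_mean":
                value = float(np.sum(w * vals) / np.sum(w))
            else:
                order = np.argsort(vals, kind="stable")
                cw = np.cumsum(w[order]) / np.sum(w)
                value = float(vals[order][np.searchsorted(cw, 0.5)])
            if config.round_to_scale:
                value = float(np.clip(np.rint(value), RATING_MIN, RATING_MAX))
            out.iloc[t_row, out.columns.get_loc(item)] = value
            pid, aidx = row_labels[t_row]
            log.append(
                {
                    "participant_id": pid,
                    "assessment_index": int(aidx),
                    "item": item,
                    "imputed": value,
                    "donors": [
                        {
                            "participant_id": row_labels[dr][0],
                            "assessment_index": int(row_labels[dr][1]),
                            "distance": float(dd),
                        }
                        for dr, dd in zip(donors, d)
                    ],
                }
            )

    completed = records.copy()
    stacked = out.stack(future_stack=True).rename("rating_imp")
    key = pd.MultiIndex.from_frame(
        completed[["participant_id", "assessment_index", "item"]]
    )
    completed["rating"] = stacked.reindex(key).to_numpy()
    return completed, log
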