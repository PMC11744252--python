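"""Fixed-effect regressions of dynamics outcomes on insomnia severity.

Each per-person dynamics statistic (mean level, SD, MSSD, lag-1
autocorrelation; one column per item) is regressed on the participant's ISI
total with ordinary least squares.  The slope *b* is the change in the
outcome per one ISI scale step; inference uses the t distribution with
n − 2 residual degrees of freedom (two-sided p, 95% CI).  ISI is treated as
continuous; the severity bands (0-7 / 8-14 / 15+) exist only as a grouping
utility for descriptive plots.

No multiple-testing correction is applied across the 16 metric × item rows
by default (raw p-values are reported); an optional Benjamini-Hochberg
adjustment can be requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import METRIC_NAMES


@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    b: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    df_resid: int
    intercept: float  # reported but tied to the (uncentered) ISI origin


def ols_fit(y, x, outcome: str = "") -> RegressionResult:
    """Closed-form OLS of ``y`` on ``x`` with intercept.

    Pairs with a missing outcome or predictor are dropped listwise; needs
    >= 3 complete pairs and a non-constant predictor.  A perfect fit yields
    se = 0 and p = 0 (p = 1 if the slope is also 0).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    n = y.size
    if n < 3:
        raise ValueError(f"insufficient data: {n} complete pairs (< 3)")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("constant predictor: design is rank deficient")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    b = sxy / sxx
    a = float(y.mean() - b * x.mean())
    resid = y - (a + b * x)
    df = n - 2
    s2 = float(np.sum(resid**2)) / df
    se = float(np.sqrt(s2 / sxx))
    tq = float(stats.t.ppf(0.975, df))
    if se > 0:
        tval = b / se
        p = float(2.0 * stats.t.sf(abs(tval), df))
    else:
        p = 0.0 if b != 0 else 1.0
    return RegressionResult(
        outcome=outcome,
        b=b,
        se=se,
        ci_low=b - tq * se,
        ci_high=b + tq * se,
        p_value=p,
        n=n,
        df_resid=df,
        intercept=a,
    )


def run_table(
    profiles: pd.DataFrame,
    isi: pd.Series | dict,
    metrics: tuple[str, ...] = METRIC_NAMES,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Regress every metric × item column on ISI; one result row each.

    ``isi`` maps participant_id to the ISI total.  Participants with a
    missing metric are dropped per row (listwise per outcome).  With four
    metrics and four items this reproduces the 16-row layout of the
    headline regression table.  ``adjust='bh'`` appends
    Benjamini-Hochberg-adjusted p-values.
    """
    if isinstance(isi, dict):
        isi = pd.Series(isi)
    merged = profiles.copy()
    merged["_isi"] = merged["participant_id"].map(isi)
    if merged["_isi"].isna().all():
        raise ValueError("empty join: no participant has an ISI value")
    rows = []
    for metric in metrics:
        for item in pd.unique(merged["item"]):
            sub = merged[merged["item"] == item]
            res = ols_fit(
                sub[metric].to_numpy(),
                sub["_isi"].to_numpy(),
                outcome=f"{metric} {item}",
            )
            rows.append(
                {
                    "metric": metric,
                    "item": item,
                    "b": res.b,
                    "se": res.se,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p_value": res.p_value,
                    "n": res.n,
                    "df_resid": res.df_resid,
                }
            )
    table = pd.DataFrame(rows)
    if adjust == "bh":
        table["p_adj"] = _benjamini_hochberg(table["p_value"].to_numpy())
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def isi_band(isi) -> np.ndarray:
    """Severity band labels used for descriptive grouping.

    0-7 none, 8-14 subthreshold, 15+ moderate-to-severe.
    """
    isi = np.asarray(isi)
    bands = np.where(isi <= 7, "0-7", np.where(isi <= 14, "8-14", "15+"))
    return bands
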