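"""Independent brute-force oracles for the dynamics statistics.

These deliberately re-derive each formula from first principles with plain
Python loops, independent of the package's vectorised implementations.
"""

import math


def brute_mean(xs):
    obs = [v for v in xs if not math.isnan(v)]
    return sum(obs) / len(obs) if obs else float("nan")


def brute_sd(xs):
    obs = [v for v in xs if not math.isnan(v)]
    if len(obs) < 2:
        return float("nan")
    m = sum(obs) / len(obs)
    return math.sqrt(sum((v - m) ** 2 for v in obs) / (len(obs) - 1))


def brute_mssd(xs):
    obs = [v for v in xs if not math.isnan(v)]
    if len(obs) < 2:
        return float("nan")
    diffs = [(obs[i + 1] - obs[i]) ** 2 for i in range(len(obs) - 1)]
    return sum(diffs) / len(diffs)


def brute_acf1(xs):
    obs = [v for v in xs if not math.isnan(v)]
    if len(obs) < 3:
        return float("nan")
    m = sum(obs) / len(obs)
    den = sum((v - m) ** 2 for v in obs)
    if den == 0:
        return float("nan")
    num = sum((obs[i] - m) * (obs[i + 1] - m) for i in range(len(obs) - 1))
    return num / den


def brute_ols(ys, xs):
    """Normal-equations OLS (slope, intercept) with explicit sums."""
    n = len(ys)
    sx = sum(xs)
    sy = sum(ys)
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    det = n * sxx - sx * sx
    b = (n * sxy - sx * sy) / det
    a = (sy - b * sx) / n
    return b, a
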