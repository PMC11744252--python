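"""Penalized-spline additive modelling of symptom intensity over ISI × time.

The model for one item's (complete, imputed) ratings is a generalized
additive mixed model estimated as one penalized regression:

    g(E[y_ij]) = beta0 + b_i + f_isi(ISI_i) + f_time(t_ij)
                 [+ f_int(ISI_i, t_ij)]

* ``b_i`` — per-participant intercepts entered as an indicator block with a
  single shared ridge penalty (a random intercept in penalized form);
* ``f_isi``, ``f_time`` — P-splines: cubic B-spline bases (default 10
  columns per margin, equally spaced interior knots over the observed
  range, sum-to-zero centered) with second-order difference penalties;
* *double-penalty shrinkage* — each marginal smooth carries a second
  penalty on the null space of its difference penalty, so a predictor that
  contributes nothing can be shrunk out entirely (its effective degrees of
  freedom approach zero);
* ``f_int`` — tensor-product interaction: row-wise Kronecker product of the
  centered marginal bases with one penalty per margin
  (``I ⊗ S_time`` and ``S_isi ⊗ I``);
* family — Gaussian (identity link) solved by penalized normal equations,
  or Poisson with log link solved by penalized IRLS, treating the 0-8
  ratings as counts.

Smoothing parameters (one per penalty) minimise generalized cross-validation
on the (working) deviance, searched by cyclic coordinate descent on a log
grid with a local refinement pass.  Model complexity is measured by
effective degrees of freedom (trace of the influence matrix), and models are
compared by conditional AIC.  Fitting is fully deterministic.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special
from scipy.interpolate import BSpline

#: absolute ridge floor on every penalized block; keeps the penalized normal
#: equations positive definite even when a smoothing parameter is zero or the
#: centered basis carries an exact null direction
PENALTY_FLOOR = 1e-8

LAMBDA_MIN, LAMBDA_MAX = 1e-6, 1e7


def _chol_ridge(A: np.ndarray, ref_scale: float):
    """Cholesky with an escalating diagonal ridge.

    Sum-to-zero centering leaves exact zero-function coefficient directions
    (e.g. the all-ones vector of a centered margin) that neither the data
    nor the difference penalties touch; a ridge tied to the scale of the
    information matrix keeps the factorization stable without perturbing
    well-identified directions (relative ridge <= 1e-9 in the usual case).
    """
    for eps in (0.0, 1e-9, 1e-7, 1e-5):
        try:
            if eps == 0.0:
                return linalg.cho_factor(A)
            return linalg.cho_factor(A + (eps * ref_scale) * np.eye(A.shape[0]))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("penalized information matrix not factorizable")


class NotConvergedError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# basis and penalty construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BSplineSpec:
    """Frozen description of one marginal B-spline basis.

    Stores the knot vector and the column means used for the sum-to-zero
    constraint so the identical (centered) basis can be rebuilt at
    prediction points.
    """

    knots: np.ndarray
    degree: int
    col_means: np.ndarray
    x_min: float
    x_max: float

    @property
    def n_cols(self) -> int:
        return len(self.knots) - self.degree - 1

    def design(self, x, center: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        B = BSpline.design_matrix(
            x, self.knots, self.degree, extrapolate=True
        ).toarray()
        if center:
            B = B - self.col_means
        return B


def build_bspline_basis(
    x, basis_dim: int, degree: int = 3
) -> tuple[np.ndarray, BSplineSpec]:
    """Centered B-spline design matrix with equally spaced knots.

    Uniform (unclamped) knots in the P-spline convention: ``basis_dim``
    columns need ``basis_dim + degree + 1`` equally spaced knots running
    ``degree`` spacings beyond each end of ``[min(x), max(x)]``, which gives
    ``basis_dim - degree - 1`` interior knots.  On uniform knots the basis
    sums to 1 over the data range (partition of unity) and coefficient
    vectors linear in the index represent exactly the linear functions of
    ``x`` — the null space of the second-order difference penalty.  Columns
    are centered to sum to zero over the observed ``x``.
    """
    x = np.asarray(x, dtype=float)
    if basis_dim < degree + 2:
        raise ValueError(f"basis_dim must be >= degree + 2 (= {degree + 2})")
    x_min, x_max = float(x.min()), float(x.max())
    if x_max <= x_min:
        raise ValueError("degenerate covariate: all values identical")
    h = (x_max - x_min) / (basis_dim - degree)
    knots = x_min + h * np.arange(-degree, basis_dim + 1)
    B = BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()
    col_means = B.mean(axis=0)
    spec = BSplineSpec(
        knots=knots, degree=degree, col_means=col_means, x_min=x_min, x_max=x_max
    )
    return B - col_means, spec


def difference_penalty_parts(
    basis_dim: int, order: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """(S, N): difference penalty ``D'D`` and its null-space projector.

    ``N`` projects onto the span of coefficient vectors annihilated by the
    order-``order`` difference operator (polynomials of degree < order in
    the coefficient index); the double-penalty shrinkage term is a separate
    smoothing parameter on ``N``.
    """
    if order >= basis_dim:
        raise ValueError("difference order must be < basis_dim")
    D = np.diff(np.eye(basis_dim), n=order, axis=0)
    S = D.T @ D
    vals, vecs = np.linalg.eigh(S)
    null = vecs[:, vals < 1e-10 * max(vals.max(), 1.0)]
    N = null @ null.T
    return S, N


def build_difference_penalty(
    basis_dim: int, order: int = 2, shrink: float = 0.0
) -> np.ndarray:
    """Difference penalty plus ``shrink`` times its null-space projector."""
    if shrink < 0:
        raise ValueError("shrink must be >= 0")
    S, N = difference_penalty_parts(basis_dim, order)
    return S + shrink * N


def build_tensor_basis(
    B_isi: np.ndarray,
    B_time: np.ndarray,
    S_isi: np.ndarray,
    S_time: np.ndarray,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Row-wise Kronecker interaction block and its two marginal penalties.

    Column ``(i, j)`` of the block is ``B_isi[:, i] * B_time[:, j]`` with
    index ``i * p_time + j``; the penalties are ``S_isi ⊗ I`` and
    ``I ⊗ S_time`` in that column ordering.  Centered margins make the block
    approximately orthogonal to the marginal main-effect smooths.
    """
    if B_isi.shape[0] != B_time.shape[0]:
        raise ValueError("marginal bases have mismatched row counts")
    n = B_isi.shape[0]
    p1, p2 = B_isi.shape[1], B_time.shape[1]
    T = (B_isi[:, :, None] * B_time[:, None, :]).reshape(n, p1 * p2)
    P_isi = np.kron(S_isi, np.eye(p2))
    P_time = np.kron(np.eye(p1), S_time)
    return T, (P_isi, P_time)


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Block:
    """One coefficient block of the penalized design."""

    name: str
    start: int
    stop: int
    penalties: tuple[tuple[str, np.ndarray], ...]  # (lambda key, matrix)

    @property
    def size(self) -> int:
        return self.stop - self.start


def _design_for_item(
    df: pd.DataFrame,
    basis_dim: int,
    degree: int,
    penalty_order: int,
    include_interaction: bool,
):
    y = df["rating"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("ratings contain missing values; impute first")
    isi = df["isi"].to_numpy(dtype=float)
    t = df["time_of_day"].to_numpy(dtype=float)
    pids, codes = np.unique(df["participant_id"].to_numpy(), return_inverse=True)
    n, n_p = y.size, pids.size

    Z = np.zeros((n, n_p))
    Z[np.arange(n), codes] = 1.0

    B_isi, spec_isi = build_bspline_basis(isi, basis_dim, degree)
    B_time, spec_time = build_bspline_basis(t, basis_dim, degree)
    S_isi, N_isi = difference_penalty_parts(B_isi.shape[1], penalty_order)
    S_time, N_time = difference_penalty_parts(B_time.shape[1], penalty_order)

    cols = [np.ones((n, 1)), Z, B_isi, B_time]
    blocks = []
    pos = 0
    blocks.append(Block("intercept", 0, 1, ()))
    pos = 1
    blocks.append(
        Block("participant", pos, pos + n_p, (("ridge", np.eye(n_p)),))
    )
    pos += n_p
    blocks.append(
        Block(
            "s(isi)",
            pos,
            pos + B_isi.shape[1],
            (("isi", S_isi), ("isi_null", N_isi)),
        )
    )
    pos += B_isi.shape[1]
    blocks.append(
        Block(
            "s(time)",
            pos,
            pos + B_time.shape[1],
            (("time", S_time), ("time_null", N_time)),
        )
    )
    pos += B_time.shape[1]
    if include_interaction:
        T, (P_isi, P_time) = build_tensor_basis(B_isi, B_time, S_isi, S_time)
        cols.append(T)
        # double-penalty shrinkage for the tensor: its two marginal penalties
        # share a joint null space (e.g. the bilinear isi*time direction) that
        # no lambda can reach; a third penalty on that projector lets the
        # whole interaction shrink to zero like any other predictor
        N_joint = np.kron(N_isi, N_time)
        blocks.append(
            Block(
                "ti(isi,time)",
                pos,
                pos + T.shape[1],
                (
                    ("tensor_isi", P_isi),
                    ("tensor_time", P_time),
                    ("tensor_null", N_joint),
                ),
            )
        )
        pos += T.shape[1]

    X = np.hstack(cols)
    # pin the functional null space of every penalized block: directions with
    # zero data energy (e.g. the all-ones vector of a centered margin) never
    # affect fitted values, so a fixed unit penalty on them keeps the system
    # positive definite at any smoothing parameter without biasing the fit
    for i, block in enumerate(blocks):
        if not block.penalties:
            continue
        Xb = X[:, block.start : block.stop]
        G_b = Xb.T @ Xb
        vals, vecs = np.linalg.eigh(G_b)
        tol = 1e-10 * max(vals.max(), 1.0)
        null = vecs[:, vals < tol]
        if null.shape[1]:
            pin = null @ null.T
            blocks[i] = Block(
                block.name,
                block.start,
                block.stop,
                block.penalties + (("_pin", pin),),
            )
    return {
        "X": X,
        "y": y,
        "blocks": blocks,
        "participants": pids,
        "spec_isi": spec_isi,
        "spec_time": spec_time,
        "isi_range": (float(isi.min()), float(isi.max())),
        "time_range": (float(t.min()), float(t.max())),
        # default prediction-grid span: inner 98% of each covariate, so the
        # surface is evaluated where the model is actually informed by data
        "isi_grid_range": tuple(np.quantile(isi, [0.01, 0.99])),
        "time_grid_range": tuple(np.quantile(t, [0.01, 0.99])),
    }


def _assemble_penalty(p: int, blocks, lam: dict) -> np.ndarray:
    S = np.zeros((p, p))
    for block in blocks:
        sl = slice(block.start, block.stop)
        if block.penalties:
            S[sl, sl] += PENALTY_FLOOR * np.eye(block.size)
        for key, mat in block.penalties:
            weight = 1.0 if key == "_pin" else lam[key]
            S[sl, sl] += weight * mat
    return S


def _edf_by_block(A_cho, XtWX: np.ndarray, blocks) -> tuple[dict, float]:
    M = linalg.cho_solve(A_cho, XtWX)
    diag = np.diag(M)
    per = {b.name: float(diag[b.start : b.stop].sum()) for b in blocks}
    return per, float(diag.sum())


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class GamFit:
    """A fitted penalized additive model for one item."""

    family: str
    item: str
    include_interaction: bool
    coef: np.ndarray
    lambdas: dict
    edf_by_block: dict
    edf_total: float
    deviance: float
    loglik: float
    aic: float
    gcv: float
    scale: float | None
    converged: bool
    iterations: int
    blocks: list
    spec_isi: BSplineSpec
    spec_time: BSplineSpec
    participants: np.ndarray
    n: int
    y_fingerprint: str
    cov: np.ndarray = field(repr=False, default=None)
    isi_range: tuple = (0.0, 0.0)
    time_range: tuple = (0.0, 0.0)
    isi_grid_range: tuple = (0.0, 0.0)
    time_grid_range: tuple = (0.0, 0.0)

    def summary(self) -> dict:
        return {
            "family": self.family,
            "item": self.item,
            "include_interaction": self.include_interaction,
            "n": self.n,
            "edf_by_block": self.edf_by_block,
            "edf_total": self.edf_total,
            "deviance": self.deviance,
            "aic": self.aic,
            "gcv": self.gcv,
            "scale": self.scale,
            "lambdas": {k: float(v) for k, v in self.lambdas.items()},
            "converged": self.converged,
            "iterations": self.iterations,
        }


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _pirls(X, y, S, max_iter=200, tol=1e-8):
    """Penalized IRLS for the Poisson log link; returns fit internals."""
    eta = np.log(y + 0.5)
    dev = np.inf
    for it in range(1, max_iter + 1):
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        w = mu
        z = eta + (y - mu) / mu
        XtWX = (X * w[:, None]).T @ X
        XtWz = X.T @ (w * z)
        A = XtWX + S
        cho = _chol_ridge(A, float(np.max(np.diag(XtWX))))
        beta = linalg.cho_solve(cho, XtWz)
        eta = X @ beta
        new_dev = _poisson_deviance(y, np.exp(np.clip(eta, -30.0, 30.0)))
        if np.isfinite(dev) and abs(dev - new_dev) <= tol * (abs(new_dev) + 1e-10):
            return beta, eta, new_dev, XtWX, cho, it, True
        dev = new_dev
    return beta, eta, dev, XtWX, cho, max_iter, False


def _fit_fixed_lambda(design, family, lam, max_iter, tol, gcv_gamma=1.4):
    X, y, blocks = design["X"], design["y"], design["blocks"]
    n, p = X.shape
    S = _assemble_penalty(p, blocks, lam)
    if family == "gaussian":
        G = design.setdefault("_G", X.T @ X)
        Xty = design.setdefault("_Xty", X.T @ y)
        yty = design.setdefault("_yty", float(y @ y))
        A = G + S
        cho = _chol_ridge(A, float(np.max(np.diag(G))))
        beta = linalg.cho_solve(cho, Xty)
        rss = float(yty - beta @ (2.0 * Xty - G @ beta))
        edf_by_block, edf = _edf_by_block(cho, G, blocks)
        gcv = n * rss / (n - gcv_gamma * edf) ** 2
        return {
            "beta": beta,
            "deviance": rss,
            "edf": edf,
            "edf_by_block": edf_by_block,
            "gcv": gcv,
            "cho": cho,
            "XtWX": G,
            "converged": True,
            "iterations": 1,
        }
    elif family == "poisson_log":
        beta, eta, dev, XtWX, cho, its, conv = _pirls(X, y, S, max_iter, tol)
        edf_by_block, edf = _edf_by_block(cho, XtWX, blocks)
        gcv = n * dev / (n - gcv_gamma * edf) ** 2
        return {
            "beta": beta,
            "deviance": dev,
            "edf": edf,
            "edf_by_block": edf_by_block,
            "gcv": gcv,
            "cho": cho,
            "XtWX": XtWX,
            "converged": conv,
            "iterations": its,
        }
    raise ValueError(f"unknown family {family!r}")


def _lambda_keys(blocks) -> list[str]:
    keys = []
    for b in blocks:
        for key, _ in b.penalties:
            if key not in keys and not key.startswith("_"):
                keys.append(key)
    return keys


def _select_lambdas(design, family, max_iter, tol, gcv_gamma=1.4):
    """Cyclic coordinate descent on GCV over log-spaced lambda grids."""
    keys = _lambda_keys(design["blocks"])
    lam = {k: 1.0 for k in keys}
    cache: dict[tuple, float] = {}

    def score(l: dict) -> float:
        key = tuple(round(np.log10(l[k]), 6) for k in keys)
        if key not in cache:
            cache[key] = _fit_fixed_lambda(design, family, l, max_iter, tol, gcv_gamma)["gcv"]
        return cache[key]

    coarse = 10.0 ** np.array([-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0])
    fine = 10.0 ** np.array([-0.5, -0.25, 0.0, 0.25, 0.5])
    # near-flat GCV profiles are resolved toward the smoother fit (largest
    # lambda within a small relative tolerance of the optimum), in the spirit
    # of the one-standard-error rule
    rel_tol = 1e-3
    for multipliers in (coarse, coarse, coarse, fine):
        for k in keys:
            cands = [lam[k]] + [
                float(np.clip(lam[k] * mult, LAMBDA_MIN, LAMBDA_MAX))
                for mult in multipliers
            ]
            cands = sorted(set(cands))
            scores = []
            for cand in cands:
                trial = dict(lam)
                trial[k] = cand
                scores.append(score(trial))
            best = min(scores)
            cutoff = best + rel_tol * abs(best) + 1e-300
            lam[k] = max(c for c, s in zip(cands, scores) if s <= cutoff)
    return lam


def _gaussian_loglik(rss: float, n: int) -> tuple[float, float]:
    scale = rss / n
    ll = -0.5 * n * (np.log(2.0 * np.pi * scale) + 1.0)
    return ll, scale


def fit_gam(
    records: pd.DataFrame,
    item: str,
    family: str = "gaussian",
    include_interaction: bool = False,
    lambdas="select",
    basis_dim: int = 10,
    degree: int = 3,
    penalty_order: int = 2,
    max_iter: int = 200,
    tol: float = 1e-8,
    gcv_gamma: float = 1.4,
) -> GamFit:
    """Fit the penalized additive model for one item on complete records.

    ``lambdas`` is either ``"select"`` (GCV coordinate descent) or a dict of
    fixed smoothing parameters keyed by ``ridge, isi, isi_null, time,
    time_null`` (plus ``tensor_isi, tensor_time`` with an interaction).
    """
    if family not in ("gaussian", "poisson_log"):
        raise ValueError("family must be 'gaussian' or 'poisson_log'")
    df = records[records["item"] == item]
    if df.empty:
        raise ValueError(f"no records for item {item!r}")
    if family == "poisson_log" and (df["rating"] < 0).any():
        raise ValueError("negative ratings are not valid Poisson counts")
    design = _design_for_item(
        df, basis_dim, degree, penalty_order, include_interaction
    )
    keys = _lambda_keys(design["blocks"])
    if lambdas == "select":
        lam = _select_lambdas(design, family, max_iter, tol, gcv_gamma)
    else:
        lam = {k: float(lambdas.get(k, 1.0)) for k in keys}

    res = _fit_fixed_lambda(design, family, lam, max_iter, tol, gcv_gamma)
    n = design["y"].size
    if family == "gaussian":
        ll, scale = _gaussian_loglik(res["deviance"], n)
        aic = -2.0 * ll + 2.0 * (res["edf"] + 1.0)
        cov = linalg.cho_solve(res["cho"], np.eye(len(res["beta"]))) * scale * n / max(
            n - res["edf"], 1.0
        )
    else:
        y = design["y"]
        mu = np.exp(np.clip(design["X"] @ res["beta"], -30.0, 30.0))
        ll = float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1.0)))
        scale = None
        aic = -2.0 * ll + 2.0 * res["edf"]
        cov = linalg.cho_solve(res["cho"], np.eye(len(res["beta"])))

    y_bytes = np.ascontiguousarray(design["y"]).tobytes()
    return GamFit(
        family=family,
        item=item,
        include_interaction=include_interaction,
        coef=res["beta"],
        lambdas=lam,
        edf_by_block=res["edf_by_block"],
        edf_total=res["edf"],
        deviance=res["deviance"],
        loglik=ll,
        aic=aic,
        gcv=res["gcv"],
        scale=scale,
        converged=res["converged"],
        iterations=res["iterations"],
        blocks=design["blocks"],
        spec_isi=design["spec_isi"],
        spec_time=design["spec_time"],
        participants=design["participants"],
        n=n,
        y_fingerprint=hashlib.sha256(y_bytes).hexdigest(),
        cov=cov,
        isi_range=design["isi_range"],
        time_range=design["time_range"],
        isi_grid_range=design["isi_grid_range"],
        time_grid_range=design["time_grid_range"],
    )


#: AIC differences smaller than this are numerical noise (the deviance is
#: accumulated over thousands of terms); they are treated as exact ties
AIC_TIE_TOL = 1e-3


def compare_models(fit_a: GamFit, fit_b: GamFit):
    """Pick the lower-AIC fit; ties (within numerical tolerance) keep the first.

    Both fits must be on the same response vector.  Cross-family comparisons
    (Gaussian density vs Poisson mass on the same discrete ratings) are
    allowed, mirroring distribution selection by AIC, but are approximate
    because the likelihoods live on different dominating measures.
    """
    if fit_a.n != fit_b.n or fit_a.y_fingerprint != fit_b.y_fingerprint:
        raise ValueError("fits are not on identical data")
    table = pd.DataFrame(
        {
            "model": [
                f"{f.family}{'+interaction' if f.include_interaction else ''}"
                for f in (fit_a, fit_b)
            ],
            "aic": [fit_a.aic, fit_b.aic],
            "edf": [fit_a.edf_total, fit_b.edf_total],
            "deviance": [fit_a.deviance, fit_b.deviance],
        }
    )
    best = fit_a if fit_a.aic <= fit_b.aic + AIC_TIE_TOL else fit_b
    return best, table


@dataclass
class PredictionGrid:
    isi_values: np.ndarray
    time_values: np.ndarray
    predicted: np.ndarray  # (n_isi, n_time), response scale
    se: np.ndarray  # (n_isi, n_time), linear-predictor scale

    def to_frame(self) -> pd.DataFrame:
        ii, tt = np.meshgrid(self.isi_values, self.time_values, indexing="ij")
        return pd.DataFrame(
            {
                "isi": ii.ravel(),
                "time_of_day": tt.ravel(),
                "predicted": self.predicted.ravel(),
                "se": self.se.ravel(),
            }
        )


def _population_design(fit: GamFit, isi: np.ndarray, t: np.ndarray) -> np.ndarray:
    n = isi.size
    n_p = fit.participants.size
    cols = [
        np.ones((n, 1)),
        np.zeros((n, n_p)),  # random intercepts at population (zero) level
        fit.spec_isi.design(isi),
        fit.spec_time.design(t),
    ]
    if fit.include_interaction:
        Bi = fit.spec_isi.design(isi)
        Bt = fit.spec_time.design(t)
        cols.append(
            (Bi[:, :, None] * Bt[:, None, :]).reshape(n, Bi.shape[1] * Bt.shape[1])
        )
    return np.hstack(cols)


def predict_surface(
    fit: GamFit,
    isi_values=None,
    time_values=None,
    n_grid: int = 12,
) -> PredictionGrid:
    """Population-level predictions on an ISI × time grid.

    Defaults to an ``n_grid × n_grid`` grid spanning the training ranges.
    Predictions are on the response scale (Poisson predictions are positive
    by the log link); standard errors are on the linear-predictor scale from
    the penalized coefficient covariance.  Points outside the training range
    trigger an extrapolation warning, not an error.
    """
    if not fit.converged:
        raise NotConvergedError("cannot predict from a non-converged fit")
    if isi_values is None:
        isi_values = np.linspace(fit.isi_grid_range[0], fit.isi_grid_range[1], n_grid)
    if time_values is None:
        time_values = np.linspace(fit.time_grid_range[0], fit.time_grid_range[1], n_grid)
    isi_values = np.asarray(isi_values, dtype=float)
    time_values = np.asarray(time_values, dtype=float)
    if (
        isi_values.min() < fit.isi_range[0] - 1e-9
        or isi_values.max() > fit.isi_range[1] + 1e-9
        or time_values.min() < fit.time_range[0] - 1e-9
        or time_values.max() > fit.time_range[1] + 1e-9
    ):
        warnings.warn("prediction grid extends beyond the training range")
    ii, tt = np.meshgrid(isi_values, time_values, indexing="ij")
    Xg = _population_design(fit, ii.ravel(), tt.ravel())
    eta = Xg @ fit.coef
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, fit.cov, Xg), 0.0))
    if fit.family == "poisson_log":
        pred = np.exp(eta)
    else:
        pred = eta
    shape = (isi_values.size, time_values.size)
    return PredictionGrid(
        isi_values=isi_values,
        time_values=time_values,
        predicted=pred.reshape(shape),
        se=se.reshape(shape),
    )


def fit_diurnal(
    records: pd.DataFrame,
    item: str,
    family: str = "gaussian",
    interaction: str = "both",
    **kwargs,
):
    """Convenience wrapper: fit candidate models for one item and choose.

    ``family`` may be ``'gaussian'``, ``'poisson_log'`` or ``'auto'`` (both
    families fitted, AIC decides); ``interaction`` may be ``'with'``,
    ``'without'`` or ``'both'``.  Returns ``(best_fit, table)`` where the
    table lists every candidate's AIC.
    """
    families = (
        ["gaussian", "poisson_log"] if family == "auto" else [family]
    )
    inter_opts = {"with": [True], "without": [False], "both": [False, True]}[
        interaction
    ]
    fits = [
        fit_gam(records, item, family=fam, include_interaction=inc, **kwargs)
        for fam in families
        for inc in inter_opts
    ]
    best = fits[0]
    for f in fits[1:]:
        best, _ = compare_models(best, f)
    table = pd.DataFrame(
        {
            "family": [f.family for f in fits],
            "interaction": [f.include_interaction for f in fits],
            "aic": [f.aic for f in fits],
            "edf": [f.edf_total for f in fits],
        }
    )
    return best, table
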