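"""Causal-effect estimators operating on a harmonized instrument set.

Implemented here: fixed-effect inverse-variance-weighted (IVW) combination of
Wald ratios, the weighted median, the weighted mode, and Egger regression with
intercept.  The LD-aware GLS estimator lives in :mod:`tsmr.gsmr`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .exceptions import DegenerateWeightsError, InsufficientInstrumentsError
from .instruments import HarmonizedSet

Z95 = 1.96  # conventional two-sided 95% multiplier used for all intervals


@dataclass
class MREstimate:
    """A causal-effect estimate from one method."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    or_value: float | None = None
    or_ci: tuple[float, float] | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    reported: bool = True

    def with_or(self) -> "MREstimate":
        """Attach the natural-scale transform (for binary outcomes)."""
        orv, orci = logodds_to_or(self.beta, self.ci_low, self.ci_high)
        return replace(self, or_value=orv, or_ci=orci)


def _two_sided_p(beta: float, se: float, df: int | None = None) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    if not math.isfinite(se):
        return float("nan")
    z = abs(beta / se)
    if df is None:
        return float(2.0 * stats.norm.sf(z))
    return float(2.0 * stats.t.sf(z, df))


def _estimate(method: str, beta: float, se: float, n: int,
              df: int | None = None, **kw) -> MREstimate:
    return MREstimate(
        method=method, beta=float(beta), se=float(se),
        ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
        pval=_two_sided_p(beta, se, df), n_snps=n, **kw)


def _require(set_: HarmonizedSet, minimum: int, method: str) -> None:
    if set_.n_kept < minimum:
        raise InsufficientInstrumentsError(
            f"{method} needs at least {minimum} instruments, got {set_.n_kept}")


def ivw(set_: HarmonizedSet, random_effects: bool = False) -> MREstimate:
    """Fixed-effect inverse-variance-weighted combination of Wald ratios.

    ``beta = sum(w_i r_i) / sum(w_i)`` with ``w_i = 1 / ratio_se_i**2`` and
    ``se = sum(w_i) ** -0.5`` — algebraically the weighted least-squares slope
    of ``beta_out`` on ``beta_exp`` through the origin with weights
    ``1/se_out**2``.  ``random_effects=True`` applies a multiplicative
    heterogeneity inflation (floored at 1); the default policy never uses it.
    """
    _require(set_, 1, "ivw")
    r, s = set_.ratios()
    w = 1.0 / s ** 2
    if not np.all(np.isfinite(w)):
        raise DegenerateWeightsError("non-finite IVW weights (ratio SE of 0?)")
    sw = w.sum()
    beta = float((w * r).sum() / sw)
    se = float(sw ** -0.5)
    if random_effects and set_.n_kept > 1:
        q = float((w * (r - beta) ** 2).sum())
        se *= max(1.0, math.sqrt(q / (set_.n_kept - 1)))
    return _estimate("ivw", beta, se, set_.n_kept)


def _weighted_median_1d(values: np.ndarray, weights: np.ndarray) -> float:
    # merge tied values so that splitting one instrument's weight across
    # duplicates cannot move the interpolated quantile
    v, inverse = np.unique(values, return_inverse=True)
    w = np.bincount(inverse, weights=weights)
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w  # mid-point running weight
    if s[0] >= 0.5:
        return float(v[0])
    k = int(np.searchsorted(s, 0.5))
    if k >= len(v):
        return float(v[-1])
    if s[k] == s[k - 1]:
        return float(v[k])
    return float(v[k - 1] + (v[k] - v[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1]))


def _weighted_median_rows(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median for (B, L) matrices (bootstrap fast path)."""
    order = np.argsort(values, axis=1, kind="stable")
    v = np.take_along_axis(values, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    s = np.cumsum(w, axis=1) - 0.5 * w
    out = np.empty(values.shape[0])
    for i in range(values.shape[0]):  # cheap: searchsorted per row
        si, vi = s[i], v[i]
        if si[0] >= 0.5:
            out[i] = vi[0]
            continue
        k = int(np.searchsorted(si, 0.5))
        if k >= len(vi):
            out[i] = vi[-1]
        elif si[k] == si[k - 1]:
            out[i] = vi[k]
        else:
            out[i] = vi[k - 1] + (vi[k] - vi[k - 1]) * (0.5 - si[k - 1]) / (si[k] - si[k - 1])
    return out


def _parametric_bootstrap(set_: HarmonizedSet, n_boot: int, seed,
                          statistic) -> float:
    """SE of ``statistic(ratios, weights)`` under resampled summary stats."""
    bx, sx, by, sy = set_.arrays()
    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, bx.size))
    bys = rng.normal(by, sy, size=(n_boot, by.size))
    ratios = bys / bxs
    weights = (bxs / sy) ** 2  # 1 / (sy/|bx|)^2
    est = statistic(ratios, weights)
    return float(np.std(est, ddof=1))


def weighted_median(set_: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None) -> MREstimate:
    """Weighted median of the Wald ratios (breakdown at 50% invalid weight).

    The point estimate interpolates the weighted 50% quantile of the sorted
    ratios; the SE comes from a parametric bootstrap that redraws each
    exposure and outcome beta from a normal with its reported SE
    (``n_boot`` draws, seeded).  ``n_boot=0`` skips the bootstrap (SE=nan).
    """
    _require(set_, 3, "weighted_median")
    r, s = set_.ratios()
    beta = _weighted_median_1d(r, 1.0 / s ** 2)
    se = (_parametric_bootstrap(set_, n_boot, seed, _weighted_median_rows)
          if n_boot > 0 else float("nan"))
    return _estimate("weighted_median", beta, se, set_.n_kept)


def _mode_bandwidth(r: np.ndarray, w: np.ndarray, phi: float) -> float:
    wn = w / w.sum()
    mean = float((wn * r).sum())
    sd = math.sqrt(float((wn * (r - mean) ** 2).sum()))
    med = _weighted_median_1d(r, w)
    mad = _weighted_median_1d(np.abs(r - med), w) / 0.6745
    spread = min(sd, mad) if mad > 0 else sd
    return phi * 0.9 * spread * r.size ** (-1.0 / 5)


def _mode_point(r: np.ndarray, w: np.ndarray, phi: float) -> float:
    h = _mode_bandwidth(r, w, phi)
    if h == 0 or not math.isfinite(h):
        # degenerate spread: all mass at one value
        vals, idx = np.unique(r, return_inverse=True)
        mass = np.bincount(idx, weights=w)
        return float(vals[int(np.argmax(mass))])
    lo, hi = r.min() - 3 * h, r.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2) @ w
    k = int(np.argmax(dens))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(lambda x: -float(np.dot(w, np.exp(-0.5 * ((x - r) / h) ** 2))),
                                   bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


def _mode_rows(ratios: np.ndarray, weights: np.ndarray, phi: float) -> np.ndarray:
    out = np.empty(ratios.shape[0])
    for i in range(ratios.shape[0]):
        out[i] = _mode_point(ratios[i], weights[i], phi)
    return out


def weighted_mode(set_: HarmonizedSet, phi: float = 1.0, n_boot: int = 1000,
                  seed: int | None = None) -> MREstimate:
    """Mode of an inverse-variance-weighted normal-kernel density of the ratios.

    Bandwidth: ``phi * 0.9 * min(weighted SD, weighted MAD/0.6745) * n**(-1/5)``.
    SE by the same parametric bootstrap as :func:`weighted_median`.
    """
    _require(set_, 3, "weighted_mode")
    r, s = set_.ratios()
    if np.all(s == 0):
        raise DegenerateWeightsError("all ratio SEs are zero")
    w = 1.0 / s ** 2
    beta = _mode_point(r, w, phi)
    se = (_parametric_bootstrap(set_, n_boot, seed,
                                lambda rr, ww: _mode_rows(rr, ww, phi))
          if n_boot > 0 else float("nan"))
    return _estimate("weighted_mode", beta, se, set_.n_kept)


def _egger_wls(bx: np.ndarray, by: np.ndarray, w: np.ndarray):
    """Weighted LS of oriented beta_out on |beta_exp| with intercept.

    Supports (L,) vectors or (B, L) matrices (vectorized over rows).
    Returns (slope, intercept).
    """
    x = np.abs(bx)
    y = np.where(bx < 0, -by, by)
    sw = np.sum(w, axis=-1)
    xbar = np.sum(w * x, axis=-1) / sw
    ybar = np.sum(w * y, axis=-1) / sw
    xc = x - np.expand_dims(xbar, -1) if x.ndim > 1 else x - xbar
    yc = y - np.expand_dims(ybar, -1) if y.ndim > 1 else y - ybar
    sxx = np.sum(w * xc * xc, axis=-1)
    sxy = np.sum(w * xc * yc, axis=-1)
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    return slope, intercept


def egger(set_: HarmonizedSet) -> MREstimate:
    """Egger regression: weighted LS of outcome on exposure betas with intercept.

    Instruments are first oriented so every exposure beta is positive (both
    betas negated where needed) — the intercept, which estimates directional
    pleiotropy, is only meaningful under that orientation.  Weights are
    ``1/se_out**2``; coefficient SEs use the residual-scaled WLS covariance and
    p-values the t distribution with ``n_snps - 2`` degrees of freedom.
    """
    _require(set_, 3, "egger")
    bx, sx, by, sy = set_.arrays()
    w = 1.0 / sy ** 2
    slope, intercept = _egger_wls(bx, by, w)
    x = np.abs(bx)
    y = np.where(bx < 0, -by, by)
    resid = y - intercept - slope * x
    n = bx.size
    s2 = float((w * resid ** 2).sum() / (n - 2))
    sw = w.sum()
    sxx = float((w * (x - (w * x).sum() / sw) ** 2).sum())
    se_slope = math.sqrt(s2 / sxx)
    se_int = math.sqrt(s2 * (1.0 / sw + ((w * x).sum() / sw) ** 2 / sxx))
    return _estimate(
        "egger", float(slope), se_slope, n, df=n - 2,
        intercept=float(intercept), intercept_se=se_int,
        intercept_pval=_two_sided_p(float(intercept), se_int, n - 2))


def logodds_to_or(beta: float, ci_low: float, ci_high: float):
    """Elementwise exponential onto the odds-ratio scale.

    Rounding happens only at the presentation layer (2 decimals in reports).
    """
    return math.exp(beta), (math.exp(ci_low), math.exp(ci_high))
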