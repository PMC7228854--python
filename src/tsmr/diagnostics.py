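"""Heterogeneity, instrument-strength, measurement-error and directionality
diagnostics for a harmonized instrument set."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .estimators import MREstimate, _egger_wls, _estimate, _two_sided_p, egger, ivw
from .exceptions import (ConfigurationError, InsufficientInstrumentsError,
                         MissingDataError)
from .instruments import HarmonizedSet
from .sumstats import SummaryStatRecord, SummaryStatTable


@dataclass
class HeterogeneityStats:
    """Cochran's Q for dispersion of the per-SNP Wald ratios."""

    q: float
    df: int
    pval: float


@dataclass
class InstrumentStrength:
    i2_gx: float
    f_per_snp: list[float]
    f_mean: float
    r2_exposure_total: float


@dataclass
class SteigerRecord:
    snp_id: str
    r2_exp: float
    r2_out: float
    correct_direction: bool
    tie: bool = False


def cochran_q(set_: HarmonizedSet) -> HeterogeneityStats:
    """Q = sum of w_i (ratio_i - beta_IVW)^2 with IVW weights; df = n-1."""
    if set_.n_kept < 2:
        raise InsufficientInstrumentsError("cochran_q needs >= 2 instruments")
    r, s = set_.ratios()
    w = 1.0 / s ** 2
    beta = float((w * r).sum() / w.sum())
    q = float((w * (r - beta) ** 2).sum())
    df = set_.n_kept - 1
    return HeterogeneityStats(q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def i2_gx(set_: HarmonizedSet) -> float:
    """I^2 of the exposure associations — the NOME-violation gauge for Egger.

    Computed on Egger-oriented (positive) exposure betas:
    ``Q_GX = sum(((|bx_i| - bbar_w) / sx_i)^2)`` with ``bbar_w`` their
    inverse-variance-weighted mean, then ``I2 = max(0, (Q_GX - (n-1)) / Q_GX)``.
    """
    if set_.n_kept < 2:
        raise InsufficientInstrumentsError("i2_gx needs >= 2 instruments")
    bx, sx, _, _ = set_.arrays()
    x = np.abs(bx)
    w = 1.0 / sx ** 2
    xbar = float((w * x).sum() / w.sum())
    q_gx = float((((x - xbar) / sx) ** 2).sum())
    if q_gx == 0:
        return 0.0
    return max(0.0, (q_gx - (set_.n_kept - 1)) / q_gx)


def simex_egger(set_: HarmonizedSet,
                lambda_grid=(0.0, 0.5, 1.0, 1.5, 2.0),
                B: int = 1000,
                seed: int | None = None) -> MREstimate:
    """Simulation-extrapolation correction of Egger for exposure measurement error.

    For each grid value lambda > 0, noise with variance ``lambda * se_exp^2``
    is added to every exposure beta ``B`` times and the Egger fit is averaged.
    A quadratic in ``(1 + lambda)`` through the averaged coefficients (the
    lambda=0 point is the naive fit) is extrapolated to lambda = -1.  SEs are
    delete-one jackknife over the ``B`` simulation replicates.
    """
    if set_.n_kept < 3:
        raise InsufficientInstrumentsError("simex_egger needs >= 3 instruments")
    grid = [float(l) for l in lambda_grid]
    if 0.0 not in grid or len(grid) < 3:
        raise ConfigurationError("lambda_grid must contain 0 and at least 3 values")
    if any(l < 0 for l in grid):
        raise ConfigurationError("lambda_grid values must be non-negative")
    grid = sorted(set(grid))
    naive = egger(set_)
    bx, sx, by, sy = set_.arrays()
    if np.all(sx == 0):
        return replace(naive, method="egger_simex")
    w = 1.0 / sy ** 2
    pos = [l for l in grid if l > 0]
    rng = np.random.default_rng(seed)
    slopes = np.empty((len(pos), B))
    intercepts = np.empty((len(pos), B))
    for j, lam in enumerate(pos):
        eps = rng.standard_normal((B, bx.size))
        bx_sim = bx + math.sqrt(lam) * sx * eps
        sl, ic = _egger_wls(bx_sim, np.broadcast_to(by, bx_sim.shape), w)
        slopes[j], intercepts[j] = sl, ic

    u = np.array([1.0 + l for l in grid])  # includes u=1 for lambda=0
    design = np.column_stack([np.ones_like(u), u, u * u])
    # extrapolated value at u=0 is the constant coefficient -> a linear
    # functional c^T y of the per-lambda means y
    proj = np.linalg.solve(design.T @ design, design.T)
    c = proj[0]

    def extrapolate(mean_pos_slope, mean_pos_int):
        y_s = np.concatenate([[naive.beta], mean_pos_slope])
        y_i = np.concatenate([[naive.intercept], mean_pos_int])
        # grid is sorted with 0 first, matching u's order
        return float(c @ y_s), float(c @ y_i)

    mean_s = slopes.mean(axis=1)
    mean_i = intercepts.mean(axis=1)
    beta_corr, int_corr = extrapolate(mean_s, mean_i)

    # jackknife over replicates: leave-one-out means per lambda
    loo_s = (mean_s[:, None] * B - slopes) / (B - 1)
    loo_i = (mean_i[:, None] * B - intercepts) / (B - 1)
    theta_s = c[0] * naive.beta + c[1:] @ loo_s
    theta_i = c[0] * naive.intercept + c[1:] @ loo_i
    se_s = math.sqrt((B - 1) / B * float(((theta_s - theta_s.mean()) ** 2).sum()))
    se_i = math.sqrt((B - 1) / B * float(((theta_i - theta_i.mean()) ** 2).sum()))
    n = set_.n_kept
    return _estimate(
        "egger_simex", beta_corr, se_s, n, df=n - 2,
        intercept=int_corr, intercept_se=se_i,
        intercept_pval=_two_sided_p(int_corr, se_i, n - 2))


def steiger_r2(record: SummaryStatRecord) -> float:
    """Variance in the trait explained by one SNP: t^2 / (t^2 + n_eff - 2)."""
    n_eff = record.effective_n()
    t = record.beta / record.se
    return float(t * t / (t * t + n_eff - 2.0))


def steiger_filter(
    set_: HarmonizedSet,
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
) -> tuple[HarmonizedSet, list[SteigerRecord]]:
    """Drop instruments explaining more outcome than exposure variance.

    Exact ties are kept (conservative) and flagged in the report.
    """
    records: list[SteigerRecord] = []
    keep: list[str] = []
    for inst in set_.kept:
        xrec = exposure.get(inst.snp_id)
        yrec = outcome.get(inst.snp_id)
        if xrec is None or yrec is None:
            raise MissingDataError(f"SNP {inst.snp_id!r} missing from a source table")
        r2x, r2y = steiger_r2(xrec), steiger_r2(yrec)
        tie = r2x == r2y
        ok = r2x > r2y or tie
        records.append(SteigerRecord(inst.snp_id, r2x, r2y,
                                     correct_direction=r2x > r2y, tie=tie))
        if ok:
            keep.append(inst.snp_id)
    return set_.subset(keep), records


def f_statistic(set_: HarmonizedSet,
                exposure: SummaryStatTable | None = None) -> InstrumentStrength:
    """Per-SNP F = (beta_exp/se_exp)^2, plus I^2_GX and total exposure r^2.

    ``r2_exposure_total`` needs per-SNP sample sizes, so it is only computed
    when the exposure table is supplied (nan otherwise).
    """
    if set_.n_kept < 1:
        raise InsufficientInstrumentsError("f_statistic needs >= 1 instrument")
    bx, sx, _, _ = set_.arrays()
    f = (bx / sx) ** 2
    r2_total = float("nan")
    if exposure is not None:
        r2 = []
        for inst in set_.kept:
            rec = exposure.get(inst.snp_id)
            if rec is not None and (rec.n is not None or rec.n_case is not None):
                r2.append(steiger_r2(rec))
        if r2 and len(r2) == set_.n_kept:
            r2_total = float(sum(r2))
    i2 = i2_gx(set_) if set_.n_kept >= 2 else float("nan")
    return InstrumentStrength(i2_gx=i2, f_per_snp=[float(v) for v in f],
                              f_mean=float(f.mean()), r2_exposure_total=r2_total)


def leave_one_out(set_: HarmonizedSet) -> list[tuple[str, MREstimate]]:
    """IVW re-estimated with each kept instrument omitted in turn."""
    if set_.n_kept < 2:
        raise InsufficientInstrumentsError("leave_one_out needs >= 2 instruments")
    ids = set_.snp_ids()
    results = []
    for omit in ids:
        sub = set_.subset([s for s in ids if s != omit])
        results.append((omit, ivw(sub)))
    return results
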