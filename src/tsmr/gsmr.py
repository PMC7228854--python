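"""LD-aware generalized least-squares causal estimate with HEIDI outlier
removal beforehand."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import MREstimate, _estimate
from .exceptions import (ConditioningError, CoverageError,
                         InsufficientInstrumentsError)
from .instruments import HarmonizedSet
from .sumstats import LDMatrix

logger = logging.getLogger(__name__)


@dataclass
class HeidiReport:
    """Outcome of HEIDI outlier filtering."""

    reference_snp: str
    removed: list[tuple[str, float]]  # (snp_id, heidi p-value)
    threshold: float


def _identity_ld(set_: HarmonizedSet) -> LDMatrix:
    ids = set_.snp_ids()
    return LDMatrix(ids, np.eye(len(ids)))


def heidi_filter(
    set_: HarmonizedSet,
    ld: LDMatrix | None = None,
    p_threshold: float = 0.01,
) -> tuple[HarmonizedSet, HeidiReport]:
    """Remove instruments whose Wald ratio differs from the reference SNP's.

    The reference is the instrument with the largest |beta_exp/se_exp| (ties:
    lexicographically smallest snp_id).  For every other SNP the difference of
    ratios is tested against chi-square(1) using
    ``var(d) = se_i^2 + se_ref^2 - 2 r se_i se_ref``; SNPs with p below the
    threshold are removed in a single pass.
    """
    kept = set_.kept
    if not kept:
        raise InsufficientInstrumentsError("heidi_filter needs >= 1 instrument")
    if ld is None:
        ld = _identity_ld(set_)
    for inst in kept:
        if inst.snp_id not in ld:
            raise CoverageError(f"SNP {inst.snp_id!r} missing from LD matrix")
    ref = min(kept, key=lambda i: (-abs(i.beta_exp / i.se_exp), i.snp_id))
    removed: list[tuple[str, float]] = []
    survivors = []
    for inst in kept:
        if inst.snp_id == ref.snp_id:
            survivors.append(inst.snp_id)
            continue
        d = inst.ratio - ref.ratio
        var = (inst.ratio_se ** 2 + ref.ratio_se ** 2
               - 2.0 * ld.corr(inst.snp_id, ref.snp_id) * inst.ratio_se * ref.ratio_se)
        if var <= 0:
            p = 0.0 if d != 0 else 1.0
        else:
            p = float(stats.chi2.sf(d * d / var, 1))
        if p < p_threshold:
            removed.append((inst.snp_id, p))
            logger.info("HEIDI removed %s (p=%.3g)", inst.snp_id, p)
        else:
            survivors.append(inst.snp_id)
    return (set_.subset(survivors),
            HeidiReport(reference_snp=ref.snp_id, removed=removed,
                        threshold=p_threshold))


def gsmr_estimate(set_: HarmonizedSet, ld: LDMatrix | None = None,
                  cond_threshold: float = 1e12) -> MREstimate:
    """GLS combination of Wald ratios under the LD-induced covariance.

    With ratio vector ``r`` and ``V_ij = r_ij * se_i * se_j``:
    ``beta = (1' V^-1 r) / (1' V^-1 1)`` and ``se = (1' V^-1 1)^-0.5``.
    With identity LD this reduces exactly to fixed-effect IVW.
    """
    if set_.n_kept < 2:
        raise InsufficientInstrumentsError("gsmr_estimate needs >= 2 instruments")
    if ld is None:
        ld = _identity_ld(set_)
    ids = set_.snp_ids()
    sub = ld.subset(ids)
    r, s = set_.ratios()
    v = sub.r * np.outer(s, s)
    cond = np.linalg.cond(v)
    if not np.isfinite(cond) or cond > cond_threshold:
        logger.warning("GSMR covariance ill-conditioned (cond=%.3g); "
                       "regularizing diagonal by 1e-10", cond)
        v = v + 1e-10 * np.eye(len(ids))
    try:
        chol = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        raise ConditioningError(
            "GSMR covariance is not positive definite; prune correlated "
            "instruments or supply a better-conditioned LD matrix") from None
    ones = np.ones(len(ids))
    vi_r = np.linalg.solve(v, r)
    vi_1 = np.linalg.solve(v, ones)
    denom = float(ones @ vi_1)
    beta = float(ones @ vi_r) / denom
    se = denom ** -0.5
    del chol
    return _estimate("gsmr", beta, se, set_.n_kept)
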