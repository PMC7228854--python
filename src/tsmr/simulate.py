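"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator draws, per SNP, an allele frequency and a true SNP-exposure
effect (resampled until it is detectable at genome-wide significance for the
configured exposure sample size, mimicking a published index-SNP list), adds
optional pleiotropic and reverse-causation paths, and emits two independent
noisy summary-statistics tables on the standardized (unit-variance) scale,
where ``se = (2 p (1-p) N)**-0.5``.

True SNP-exposure effects are oriented positive, i.e. the effect allele is
always the exposure-increasing allele — the convention of published index-SNP
lists, and the orientation under which "directional" pleiotropy is directional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ScenarioInfeasibleError
from .sumstats import SummaryStatRecord, SummaryStatTable

_GWAS_P = 5e-8
_Z_SIG = float(stats.norm.isf(_GWAS_P / 2.0))  # two-sided threshold, ~5.45
_MIN_PVAL = float(np.nextafter(0.0, 1.0))
_MAX_RESAMPLE = 1000

_NONPALINDROMIC_PAIRS = (("A", "G"), ("C", "T"), ("G", "T"), ("A", "C"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))


@dataclass(frozen=True)
class SimulationScenario:
    """Generative parameters for one synthetic two-sample dataset."""

    L: int
    theta: float = 0.0              # causal effect exposure -> outcome
    theta_rev: float = 0.0          # reverse causal effect outcome -> exposure
    sigma_gamma: float = 0.05       # SD of true SNP-exposure effects
    pi_inv: float = 0.0             # fraction of pleiotropic instruments
    mu_alpha: float = 0.0           # mean direct (pleiotropic) effect
    sigma_alpha: float = 0.0        # SD of direct effects
    q_inside: float = 0.0           # regression of alpha on gamma (0 = InSIDE)
    n_exp: int = 100_000
    n_out: int = 100_000
    binary_exposure: bool = False
    binary_outcome: bool = False
    case_frac_exp: float = 0.5
    case_frac_out: float = 0.5
    maf_range: tuple[float, float] = (0.1, 0.9)
    palindromic_frac: float = 0.0
    swapped_frac: float = 0.0
    select_on_observed: bool = False  # winner's-curse selection (off by default)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ConfigurationError("L must be >= 1")
        if not (0.0 <= self.pi_inv <= 1.0):
            raise ConfigurationError("pi_inv must lie in [0, 1]")
        if self.n_exp < 2 or self.n_out < 2:
            raise ConfigurationError("sample sizes must be >= 2")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError("maf_range must satisfy 0 < lo < hi < 1")
        if self.sigma_gamma <= 0:
            raise ConfigurationError("sigma_gamma must be positive")
        for frac in (self.palindromic_frac, self.swapped_frac):
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError("allele fractions must lie in [0, 1]")


def _effective_n(n: int, binary: bool, case_frac: float) -> float:
    if not binary:
        return float(n)
    n_case = case_frac * n
    n_control = (1.0 - case_frac) * n
    return 4.0 / (1.0 / n_case + 1.0 / n_control)


def _draw_gammas(rng: np.random.Generator, se_exp: np.ndarray,
                 sigma_gamma: float) -> np.ndarray:
    """|Normal(0, sigma^2)| per SNP, resampled until genome-wide detectable."""
    L = se_exp.size
    gamma = np.abs(rng.normal(0.0, sigma_gamma, L))
    for _ in range(_MAX_RESAMPLE):
        weak = gamma / se_exp < _Z_SIG
        if not weak.any():
            return gamma
        gamma[weak] = np.abs(rng.normal(0.0, sigma_gamma, int(weak.sum())))
    raise ScenarioInfeasibleError(
        f"sigma_gamma={sigma_gamma:g} cannot reach p < {_GWAS_P:g} at the "
        f"configured exposure sample size within {_MAX_RESAMPLE} resampling rounds")


def _alleles(scenario: SimulationScenario) -> list[tuple[str, str, bool]]:
    """Deterministic (effect, other, swapped_in_outcome) per SNP."""
    L = scenario.L
    n_pal = round(scenario.palindromic_frac * L)
    n_swap = round(scenario.swapped_frac * L)
    out = []
    for i in range(L):
        if i < n_pal:
            pair = _PALINDROMIC_PAIRS[i % len(_PALINDROMIC_PAIRS)]
        else:
            pair = _NONPALINDROMIC_PAIRS[i % len(_NONPALINDROMIC_PAIRS)]
        out.append((pair[0], pair[1], i >= L - n_swap))
    return out


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.maximum(p, _MIN_PVAL)


def simulate_sumstats(
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
) -> tuple[SummaryStatTable, SummaryStatTable]:
    """Generate (exposure, outcome) summary-statistics tables.

    With the default ``rng=None`` the scenario's own seed is used, so a fixed
    scenario reproduces byte-identical tables.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    L = scenario.L
    lo, hi = scenario.maf_range
    p = rng.uniform(lo, hi, L)
    n_eff_exp = _effective_n(scenario.n_exp, scenario.binary_exposure,
                             scenario.case_frac_exp)
    n_eff_out = _effective_n(scenario.n_out, scenario.binary_outcome,
                             scenario.case_frac_out)
    se_exp = 1.0 / np.sqrt(2.0 * p * (1.0 - p) * n_eff_exp)
    se_out = 1.0 / np.sqrt(2.0 * p * (1.0 - p) * n_eff_out)

    if scenario.select_on_observed:
        gamma = np.abs(rng.normal(0.0, scenario.sigma_gamma, L))
    else:
        gamma = _draw_gammas(rng, se_exp, scenario.sigma_gamma)
    invalid = rng.uniform(size=L) < scenario.pi_inv
    alpha_noise = rng.normal(0.0, scenario.sigma_alpha, L) if scenario.sigma_alpha > 0 else np.zeros(L)
    alpha = np.where(invalid,
                     scenario.mu_alpha + scenario.q_inside * gamma + alpha_noise,
                     0.0)

    effect_on_outcome = scenario.theta * gamma + alpha
    true_exp = gamma + scenario.theta_rev * effect_on_outcome
    beta_exp = rng.normal(true_exp, se_exp)
    if scenario.select_on_observed:
        # winner's curse: redraw SNPs until the *observed* association is
        # genome-wide significant, inflating selected effect estimates
        for _ in range(_MAX_RESAMPLE):
            weak = np.abs(beta_exp) / se_exp < _Z_SIG
            if not weak.any():
                break
            k = int(weak.sum())
            gamma[weak] = np.abs(rng.normal(0.0, scenario.sigma_gamma, k))
            effect_on_outcome[weak] = scenario.theta * gamma[weak] + alpha[weak]
            true_exp[weak] = (gamma[weak]
                              + scenario.theta_rev * effect_on_outcome[weak])
            beta_exp[weak] = rng.normal(true_exp[weak], se_exp[weak])
        else:
            raise ScenarioInfeasibleError(
                "observed-significance selection did not converge")
    beta_out = rng.normal(effect_on_outcome, se_out)  # independent sample

    pe = _pvals(beta_exp, se_exp)
    po = _pvals(beta_out, se_out)
    alleles = _alleles(scenario)

    def binary_counts(n, binary, case_frac):
        if not binary:
            return None, None
        return case_frac * n, (1.0 - case_frac) * n

    nce, nco = binary_counts(scenario.n_exp, scenario.binary_exposure,
                             scenario.case_frac_exp)
    oce, oco = binary_counts(scenario.n_out, scenario.binary_outcome,
                             scenario.case_frac_out)
    exp_type = "binary" if scenario.binary_exposure else "continuous"
    out_type = "binary" if scenario.binary_outcome else "continuous"

    exp_records, out_records = [], []
    for i in range(L):
        ea, oa, swapped = alleles[i]
        snp = f"rs{i + 1}"
        exp_records.append(SummaryStatRecord(
            snp_id=snp, effect_allele=ea, other_allele=oa,
            beta=float(beta_exp[i]), se=float(se_exp[i]), pval=float(pe[i]),
            eaf=float(p[i]), n=float(scenario.n_exp), n_case=nce, n_control=nco,
            trait_type=exp_type))
        if swapped:
            out_records.append(SummaryStatRecord(
                snp_id=snp, effect_allele=oa, other_allele=ea,
                beta=float(-beta_out[i]), se=float(se_out[i]), pval=float(po[i]),
                eaf=float(1.0 - p[i]), n=float(scenario.n_out),
                n_case=oce, n_control=oco, trait_type=out_type))
        else:
            out_records.append(SummaryStatRecord(
                snp_id=snp, effect_allele=ea, other_allele=oa,
                beta=float(beta_out[i]), se=float(se_out[i]), pval=float(po[i]),
                eaf=float(p[i]), n=float(scenario.n_out),
                n_case=oce, n_control=oco, trait_type=out_type))
    return (SummaryStatTable("sim_exposure", exp_type, exp_records),
            SummaryStatTable("sim_outcome", out_type, out_records))


def recovery_suite(
    scenarios: Sequence[SimulationScenario],
    n_reps: int,
    seed: int = 0,
    estimators: Sequence[str] = ("ivw", "weighted_median", "weighted_mode", "egger"),
) -> pd.DataFrame:
    """Monte-Carlo evaluation of the estimators over replicated scenarios.

    Per scenario x estimator: mean estimate, mean bias, RMSE, empirical SE,
    Monte-Carlo SE of the mean, 95% CI coverage and rejection rate at
    alpha=0.05 (coverage/rejection use each method's analytic SE where one
    exists; the median and mode are evaluated as point estimates only).
    """
    from . import estimators as est_mod
    from .instruments import harmonize, select_instruments

    fns = {
        "ivw": lambda s: est_mod.ivw(s),
        "weighted_median": lambda s: est_mod.weighted_median(s, n_boot=0),
        "weighted_mode": lambda s: est_mod.weighted_mode(s, n_boot=0),
        "egger": lambda s: est_mod.egger(s),
    }
    for name in estimators:
        if name not in fns:
            raise ConfigurationError(f"unknown estimator {name!r}")
    rows = []
    for s_idx, scenario in enumerate(scenarios):
        draws: dict[str, list] = {name: [] for name in estimators}
        child = np.random.SeedSequence(entropy=seed, spawn_key=(s_idx,))
        rngs = [np.random.default_rng(s) for s in child.spawn(n_reps)]
        for rng in rngs:
            exposure, outcome = simulate_sumstats(scenario, rng=rng)
            inst = select_instruments(exposure)
            hset = harmonize(inst, outcome)
            for name in estimators:
                try:
                    draws[name].append(fns[name](hset))
                except Exception:
                    draws[name].append(None)
        for name in estimators:
            ests = [e for e in draws[name] if e is not None]
            betas = np.array([e.beta for e in ests])
            ses = np.array([e.se for e in ests])
            theta = scenario.theta
            cover = rej = float("nan")
            if np.all(np.isfinite(ses)):
                cover = float(np.mean((betas - 1.96 * ses <= theta)
                                      & (theta <= betas + 1.96 * ses)))
                rej = float(np.mean(np.array([e.pval for e in ests]) < 0.05))
            rows.append({
                "scenario": s_idx, "estimator": name, "n_reps": len(ests),
                "theta": theta,
                "mean_estimate": float(betas.mean()),
                "mean_bias": float(betas.mean() - theta),
                "rmse": float(np.sqrt(np.mean((betas - theta) ** 2))),
                "empirical_se": float(betas.std(ddof=1)),
                "mc_se_of_mean": float(betas.std(ddof=1) / math.sqrt(len(ests))),
                "coverage_95": cover,
                "rejection_rate_05": rej,
            })
    return pd.DataFrame(rows)
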