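"""Orchestration of the full bidirectional analysis with the reporting policy.

Policy in force (all thresholds configurable through :class:`DecisionPolicy`):

* instruments selected at p < 5e-8;
* IVW, weighted median and weighted mode always run (>= 3 instruments);
* Egger and GSMR require >= 10 instruments;
* Egger reporting follows the I^2_GX bands — full Egger when I^2 > 0.9, the
  SIMEX-corrected fit when 0.6 <= I^2 <= 0.9, suppressed when I^2 < 0.6;
* GSMR is preceded by HEIDI outlier filtering;
* all reported estimators are re-run on the Steiger-filtered subset;
* no multiple-testing correction (a Bonferroni column is emitted in the
  results table for reference only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field

from . import estimators as est
from .diagnostics import (HeterogeneityStats, InstrumentStrength, SteigerRecord,
                          cochran_q, f_statistic, i2_gx, leave_one_out,
                          simex_egger, steiger_filter)
from .estimators import MREstimate
from .exceptions import (ConfigurationError, EmptyInstrumentError,
                         InsufficientInstrumentsError, MRError)
from .gsmr import HeidiReport, gsmr_estimate, heidi_filter
from .instruments import HarmonizedSet, harmonize, select_instruments
from .sumstats import LDMatrix, SummaryStatTable

logger = logging.getLogger(__name__)

GRADE_CONSISTENT = "consistent-evidence"
GRADE_WEAK = "weak-evidence"
GRADE_NONE = "no-clear-evidence"
GRADE_INCONSISTENT = "inconsistent"


@dataclass(frozen=True)
class DecisionPolicy:
    """All thresholds and gates governing which methods run and are reported."""

    p_instrument: float = 5e-8
    r2_prune: float = 0.001
    min_snps_egger_gsmr: int = 10
    i2_full: float = 0.9
    i2_simex: float = 0.6
    heidi_p: float = 0.01
    alpha: float = 0.05
    eaf_window: tuple[float, float] = (0.42, 0.58)
    n_boot: int = 1000
    simex_b: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.i2_simex < self.i2_full <= 1.0):
            raise ConfigurationError("need 0 < i2_simex < i2_full <= 1")
        if self.min_snps_egger_gsmr < 3:
            raise ConfigurationError("min_snps_egger_gsmr must be >= 3")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionPolicy":
        d = dict(d)
        if "eaf_window" in d:
            d["eaf_window"] = tuple(d["eaf_window"])
        return cls(**d)


@dataclass
class EvidenceGrade:
    grade: str
    ivw_pval: float | None
    sign_agreement: dict[str, bool] = field(default_factory=dict)


@dataclass
class DirectionResult:
    """Everything computed for one exposure -> outcome direction."""

    exposure: str
    outcome: str
    estimable: bool
    n_selected: int = 0
    n_kept: int = 0
    reason: str | None = None
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    suppressed: dict[str, str] = field(default_factory=dict)
    i2_gx: float | None = None
    heterogeneity: HeterogeneityStats | None = None
    strength: InstrumentStrength | None = None
    steiger: list[SteigerRecord] = field(default_factory=list)
    steiger_refit: dict[str, MREstimate] = field(default_factory=dict)
    loo: list[tuple[str, MREstimate]] = field(default_factory=list)
    heidi: HeidiReport | None = None
    evidence: EvidenceGrade | None = None
    outcome_binary: bool = False
    harmonized: HarmonizedSet | None = None

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, float) and not math.isfinite(obj):
                return None
            return obj

        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)
             if f.name != "harmonized"}
        return enc(d)


def _maybe_or(estimate: MREstimate, binary_outcome: bool) -> MREstimate:
    return estimate.with_or() if binary_outcome else estimate


def run_direction(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    policy: DecisionPolicy | None = None,
    ld: LDMatrix | None = None,
) -> DirectionResult:
    """Run the full estimator battery and diagnostics for one direction."""
    policy = policy or DecisionPolicy()
    binary_out = outcome.trait_type == "binary"
    result = DirectionResult(exposure=exposure.trait_name,
                             outcome=outcome.trait_name,
                             estimable=False, outcome_binary=binary_out)
    try:
        instruments = select_instruments(exposure, policy.p_instrument, ld,
                                         policy.r2_prune)
    except EmptyInstrumentError as exc:
        result.reason = str(exc)
        return result
    result.n_selected = len(instruments)
    hset = harmonize(instruments, outcome, policy.eaf_window)
    result.harmonized = hset
    result.n_kept = hset.n_kept

    if hset.n_kept >= 1:
        result.strength = f_statistic(hset, exposure)
    if hset.n_kept >= 2:
        result.heterogeneity = cochran_q(hset)
        result.i2_gx = i2_gx(hset)
    if hset.n_kept < 3:
        result.reason = (f"only {hset.n_kept} instruments harmonized; "
                         "at least 3 required")
        logger.warning("%s -> %s: %s", result.exposure, result.outcome, result.reason)
        return result
    result.estimable = True

    estimates: dict[str, MREstimate] = {}
    estimates["ivw"] = est.ivw(hset)
    estimates["weighted_median"] = est.weighted_median(
        hset, n_boot=policy.n_boot, seed=policy.seed)
    estimates["weighted_mode"] = est.weighted_mode(
        hset, n_boot=policy.n_boot, seed=policy.seed + 1)

    # --- Egger: sample-size gate, then the I^2 three-band rule ---
    i2 = result.i2_gx
    if hset.n_kept < policy.min_snps_egger_gsmr:
        result.suppressed["egger"] = (
            f"n.a.: {hset.n_kept} < {policy.min_snps_egger_gsmr} instruments")
        result.suppressed["gsmr"] = result.suppressed["egger"]
    else:
        if i2 > policy.i2_full:
            estimates["egger"] = est.egger(hset)
        elif i2 >= policy.i2_simex:
            estimates["egger_simex"] = simex_egger(
                hset, B=policy.simex_b, seed=policy.seed + 2)
        else:
            result.suppressed["egger"] = (
                f"I2_GX = {i2:.3f} < {policy.i2_simex:g}: Egger unreliable")
        try:
            filtered, heidi_report = heidi_filter(hset, ld, policy.heidi_p)
            result.heidi = heidi_report
            estimates["gsmr"] = gsmr_estimate(filtered, ld)
        except (InsufficientInstrumentsError, MRError) as exc:
            result.suppressed["gsmr"] = f"GSMR failed: {exc}"
    for name in result.suppressed:
        logger.info("%s -> %s: %s suppressed (%s)", result.exposure,
                    result.outcome, name, result.suppressed[name])

    result.estimates = {k: _maybe_or(v, binary_out) for k, v in estimates.items()}

    # --- directionality: Steiger report + refit of all reported estimators ---
    try:
        filtered_set, result.steiger = steiger_filter(hset, exposure, outcome)
        refit: dict[str, MREstimate] = {}
        for name in result.estimates:
            try:
                if name == "ivw":
                    refit[name] = est.ivw(filtered_set)
                elif name == "weighted_median":
                    refit[name] = est.weighted_median(
                        filtered_set, n_boot=policy.n_boot, seed=policy.seed)
                elif name == "weighted_mode":
                    refit[name] = est.weighted_mode(
                        filtered_set, n_boot=policy.n_boot, seed=policy.seed + 1)
                elif name == "egger":
                    refit[name] = est.egger(filtered_set)
                elif name == "egger_simex":
                    refit[name] = simex_egger(
                        filtered_set, B=policy.simex_b, seed=policy.seed + 2)
                elif name == "gsmr":
                    f2, _ = heidi_filter(filtered_set, ld, policy.heidi_p)
                    refit[name] = gsmr_estimate(f2, ld)
            except MRError as exc:
                logger.info("Steiger refit of %s skipped: %s", name, exc)
        result.steiger_refit = {k: _maybe_or(v, binary_out)
                                for k, v in refit.items()}
    except MRError as exc:
        logger.info("Steiger filtering unavailable: %s", exc)

    result.loo = leave_one_out(hset)
    result.evidence = evidence_summary(result, policy)
    return result


def run_bidirectional(
    a: SummaryStatTable,
    b: SummaryStatTable,
    policy: DecisionPolicy | None = None,
    ld_a: LDMatrix | None = None,
    ld_b: LDMatrix | None = None,
) -> tuple[DirectionResult, DirectionResult]:
    """run_direction(a -> b) and run_direction(b -> a)."""
    return (run_direction(a, b, policy, ld_a),
            run_direction(b, a, policy, ld_b))


def evidence_summary(result: DirectionResult,
                     policy: DecisionPolicy | None = None) -> EvidenceGrade:
    """Grade cross-estimator consistency of a direction's estimates.

    no-clear-evidence if IVW p >= alpha; consistent-evidence if IVW p < alpha
    and every reported sensitivity estimate shares IVW's sign; weak-evidence
    if at least half share it; inconsistent otherwise.  This is an
    interpretation layer over a narrative grading practice, not a standard.
    """
    policy = policy or DecisionPolicy()
    ivw_est = result.estimates.get("ivw")
    if ivw_est is None:
        return EvidenceGrade(GRADE_NONE, None)
    agreement = {
        name: (e.beta >= 0) == (ivw_est.beta >= 0)
        for name, e in result.estimates.items() if name != "ivw" and e.reported
    }
    if ivw_est.pval >= policy.alpha:
        return EvidenceGrade(GRADE_NONE, ivw_est.pval, agreement)
    if all(agreement.values()):
        return EvidenceGrade(GRADE_CONSISTENT, ivw_est.pval, agreement)
    if agreement and sum(agreement.values()) >= len(agreement) / 2.0:
        return EvidenceGrade(GRADE_WEAK, ivw_est.pval, agreement)
    return EvidenceGrade(GRADE_INCONSISTENT, ivw_est.pval, agreement)


# ---------------------------------------------------------------------------
# reporting

_METHOD_ORDER = ("ivw", "weighted_median", "weighted_mode", "egger", "gsmr")


def _fmt_p(p: float | None) -> str:
    if p is None or not math.isfinite(p):
        return "n.a."
    return format(p, ".3g")


def _method_cells(result: DirectionResult, method: str) -> list[str]:
    """beta / OR / 95% CI / P cells for one method column group."""
    estimate = result.estimates.get(method)
    if method == "egger" and estimate is None:
        estimate = result.estimates.get("egger_simex")
    if estimate is None:
        return ["n.a."] * 4
    beta = format(estimate.beta, ".2f")
    if result.outcome_binary and estimate.or_value is not None:
        orv = format(estimate.or_value, ".2f")
        ci = (f"{estimate.or_ci[0]:.2f} to {estimate.or_ci[1]:.2f}")
    else:
        orv = ""
        ci = f"{estimate.ci_low:.2f} to {estimate.ci_high:.2f}"
    return [beta, orv, ci, _fmt_p(estimate.pval)]


def render_report(results, out_dir: str, n_tests: int | None = None) -> dict[str, str]:
    """Write the results table, diagnostic annex and leave-one-out series.

    ``results`` is one DirectionResult or a sequence of them.  Returns a
    mapping of artifact name -> path.  All files are tab-delimited text with
    deterministic formatting.
    """
    if isinstance(results, DirectionResult):
        results = [results]
    results = list(results)
    n_tests = n_tests if n_tests is not None else len(results)
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    main_path = os.path.join(out_dir, "results.tsv")
    header = ["exposure", "outcome", "n_snps"]
    for m in _METHOD_ORDER:
        if m == "gsmr":
            header.append("n_snps_heidi")
        header += [f"{m}_beta", f"{m}_or", f"{m}_ci", f"{m}_p"]
    header += ["ivw_p_bonferroni", "evidence"]
    with open(main_path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for res in results:
            row = [res.exposure, res.outcome, str(res.n_kept)]
            for m in _METHOD_ORDER:
                if m == "gsmr":
                    gsmr_est = res.estimates.get("gsmr")
                    n_heidi = (str(gsmr_est.n_snps) if gsmr_est is not None
                               else "n.a.")
                    row.append(n_heidi)
                if res.estimable:
                    row += _method_cells(res, m)
                else:
                    row += ["n.a."] * 4
            ivw_est = res.estimates.get("ivw")
            bonf = (_fmt_p(min(1.0, ivw_est.pval * n_tests))
                    if ivw_est is not None else "n.a.")
            grade = res.evidence.grade if res.evidence else "not-estimable"
            row += [bonf, grade]
            fh.write("\t".join(row) + "\n")
    paths["results"] = main_path

    annex_path = os.path.join(out_dir, "diagnostics.tsv")
    with open(annex_path, "w") as fh:
        fh.write("exposure\toutcome\tn_selected\tn_kept\tq\tq_df\tq_p\ti2_gx\t"
                 "f_mean\tr2_exposure_total\tegger_intercept\tegger_intercept_se\t"
                 "egger_intercept_p\tsteiger_n_correct\tsteiger_n_wrong\t"
                 "heidi_removed\tsuppressed\n")
        for res in results:
            het = res.heterogeneity
            strength = res.strength
            eg = res.estimates.get("egger") or res.estimates.get("egger_simex")
            n_ok = sum(1 for s in res.steiger if s.correct_direction or s.tie)
            n_bad = len(res.steiger) - n_ok
            supp = "; ".join(f"{k}: {v}" for k, v in sorted(res.suppressed.items())) or "-"
            cells = [
                res.exposure, res.outcome, str(res.n_selected), str(res.n_kept),
                format(het.q, ".4g") if het else "n.a.",
                str(het.df) if het else "n.a.",
                _fmt_p(het.pval) if het else "n.a.",
                format(res.i2_gx, ".3f") if res.i2_gx is not None else "n.a.",
                format(strength.f_mean, ".4g") if strength else "n.a.",
                (format(strength.r2_exposure_total, ".4g")
                 if strength and math.isfinite(strength.r2_exposure_total) else "n.a."),
                format(eg.intercept, ".4g") if eg and eg.intercept is not None else "n.a.",
                format(eg.intercept_se, ".4g") if eg and eg.intercept_se is not None else "n.a.",
                _fmt_p(eg.intercept_pval) if eg and eg.intercept_pval is not None else "n.a.",
                str(n_ok), str(n_bad),
                str(len(res.heidi.removed)) if res.heidi else "n.a.",
                supp,
            ]
            fh.write("\t".join(cells) + "\n")
    paths["diagnostics"] = annex_path

    loo_path = os.path.join(out_dir, "leave_one_out.tsv")
    with open(loo_path, "w") as fh:
        fh.write("exposure\toutcome\tomitted_snp\tbeta\tse\tci_low\tci_high\tp\n")
        for res in results:
            for snp, e in res.loo:
                fh.write("\t".join([
                    res.exposure, res.outcome, snp,
                    format(e.beta, ".10g"), format(e.se, ".10g"),
                    format(e.ci_low, ".10g"), format(e.ci_high, ".10g"),
                    _fmt_p(e.pval)]) + "\n")
    paths["leave_one_out"] = loo_path

    json_path = os.path.join(out_dir, "results.json")
    with open(json_path, "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["json"] = json_path
    return paths
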