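"""Instrument selection and exposure/outcome harmonization.

Selection keeps genome-wide-significant SNPs (optionally LD-pruned).
Harmonization aligns outcome effects to the exposure's effect allele and
attaches the per-SNP Wald ratio ``beta_out / beta_exp`` with first-order
delta-method standard error ``se_out / |beta_exp|``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import CoverageError, EmptyInstrumentError
from .sumstats import COMPLEMENT, LDMatrix, SummaryStatRecord, SummaryStatTable

logger = logging.getLogger(__name__)

KEPT = "kept"
DROPPED = "dropped"

#: drop_reason codes
ALLELE_MISMATCH = "allele_mismatch"
AMBIGUOUS_PALINDROME = "ambiguous_palindrome"
MISSING_IN_OUTCOME = "missing_in_outcome"
ZERO_EXPOSURE_EFFECT = "zero_exposure_effect"
NO_REASON = "none"


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects for one SNP on a common effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float | None
    se_out: float | None
    eaf_exp: float | None = None
    eaf_out: float | None = None
    ratio: float | None = None
    ratio_se: float | None = None
    status: str = KEPT
    drop_reason: str = NO_REASON


@dataclass
class HarmonizedSet:
    """All instruments for one exposure→outcome direction, kept and dropped."""

    exposure_name: str
    outcome_name: str
    instruments: list[HarmonizedInstrument] = field(default_factory=list)
    exposure_type: str = "continuous"
    outcome_type: str = "continuous"

    @property
    def kept(self) -> list[HarmonizedInstrument]:
        return [i for i in self.instruments if i.status == KEPT]

    @property
    def n_kept(self) -> int:
        return sum(1 for i in self.instruments if i.status == KEPT)

    def snp_ids(self) -> list[str]:
        return [i.snp_id for i in self.kept]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) over kept instruments."""
        k = self.kept
        return (np.array([i.beta_exp for i in k]),
                np.array([i.se_exp for i in k]),
                np.array([i.beta_out for i in k]),
                np.array([i.se_out for i in k]))

    def ratios(self) -> tuple[np.ndarray, np.ndarray]:
        """(wald ratios, ratio SEs) over kept instruments."""
        k = self.kept
        return (np.array([i.ratio for i in k]),
                np.array([i.ratio_se for i in k]))

    def subset(self, snp_ids: Sequence[str]) -> "HarmonizedSet":
        wanted = set(snp_ids)
        return HarmonizedSet(
            self.exposure_name, self.outcome_name,
            [i for i in self.instruments if i.status == KEPT and i.snp_id in wanted],
            self.exposure_type, self.outcome_type)


def select_instruments(
    exposure: SummaryStatTable,
    p_threshold: float = 5e-8,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.001,
) -> SummaryStatTable:
    """Keep genome-wide-significant SNPs, greedily LD-pruned when possible.

    With an LD matrix, candidates are visited in ascending p-value order and a
    SNP is discarded if its r^2 with any already-kept SNP reaches
    ``r2_threshold``.  Without one, the input is assumed pre-pruned (the usual
    situation when instruments come from a published index-SNP list) and is
    passed through with a prominent log message.
    """
    significant = [r for r in exposure.records if r.pval < p_threshold]
    if not significant:
        raise EmptyInstrumentError(
            f"no SNP in {exposure.trait_name!r} reaches p < {p_threshold:g}")
    if ld is None:
        logger.warning(
            "select_instruments(%s): no LD matrix supplied; assuming the %d "
            "significant SNPs are already LD-independent",
            exposure.trait_name, len(significant))
        chosen = significant
    else:
        for rec in significant:
            if rec.snp_id not in ld:
                raise CoverageError(f"SNP {rec.snp_id!r} missing from LD matrix")
        kept: list[SummaryStatRecord] = []
        for rec in sorted(significant, key=lambda r: (r.pval, r.snp_id)):
            if all(ld.corr(rec.snp_id, k.snp_id) ** 2 < r2_threshold for k in kept):
                kept.append(rec)
            else:
                logger.info("pruned %s (r2 >= %g with a kept SNP)", rec.snp_id, r2_threshold)
        order = {r.snp_id: i for i, r in enumerate(exposure.records)}
        chosen = sorted(kept, key=lambda r: order[r.snp_id])
    return SummaryStatTable(exposure.trait_name, exposure.trait_type, list(chosen))


def _wald(snp_id, bx, sx, by, sy, eaf_x, eaf_y,
          second_order_se: bool = False) -> HarmonizedInstrument:
    if bx == 0.0:
        logger.info("dropped %s: exposure beta is exactly 0, ratio undefined", snp_id)
        return HarmonizedInstrument(snp_id, bx, sx, by, sy, eaf_x, eaf_y,
                                    status=DROPPED, drop_reason=ZERO_EXPOSURE_EFFECT)
    se = sy / abs(bx)
    if second_order_se:
        # adds the exposure measurement-error term of the delta expansion
        se = float(np.sqrt(sy ** 2 / bx ** 2 + by ** 2 * sx ** 2 / bx ** 4))
    return HarmonizedInstrument(
        snp_id, bx, sx, by, sy, eaf_x, eaf_y,
        ratio=by / bx, ratio_se=se)


def harmonize(
    exposure_instruments: SummaryStatTable,
    outcome: SummaryStatTable,
    eaf_window: tuple[float, float] = (0.42, 0.58),
    second_order_se: bool = False,
) -> HarmonizedSet:
    """Align each instrument's outcome association to the exposure effect allele.

    Rules, per SNP:

    * absent from the outcome table → dropped ``missing_in_outcome``;
    * identical allele pair → effects taken as-is;
    * swapped allele pair → outcome beta negated, outcome EAF complemented;
    * palindromic pair (A/T or C/G): textual alignment first, then the
      orientation is checked against allele frequency — both EAFs must lie
      outside ``eaf_window``; if they disagree in side the outcome is flipped
      once more; missing or ambiguous frequencies → dropped
      ``ambiguous_palindrome``;
    * anything else → dropped ``allele_mismatch``.

    The Wald-ratio SE is first-order (``se_out/|beta_exp|``, the convention
    underlying IVW weights); ``second_order_se=True`` adds the exposure
    measurement-error term.
    """
    lo, hi = eaf_window
    out: list[HarmonizedInstrument] = []
    for rec in exposure_instruments.records:
        orec = outcome.get(rec.snp_id)
        if orec is None:
            out.append(HarmonizedInstrument(
                rec.snp_id, rec.beta, rec.se, None, None, rec.eaf, None,
                status=DROPPED, drop_reason=MISSING_IN_OUTCOME))
            continue
        ea_x, oa_x = rec.effect_allele, rec.other_allele
        ea_y, oa_y = orec.effect_allele, orec.other_allele
        by, sy, eaf_y = orec.beta, orec.se, orec.eaf

        if (ea_y, oa_y) == (ea_x, oa_x):
            aligned = True
        elif (ea_y, oa_y) == (oa_x, ea_x):
            by = -by
            eaf_y = None if eaf_y is None else 1.0 - eaf_y
            aligned = True
        else:
            aligned = False

        palindromic = COMPLEMENT.get(ea_x) == oa_x
        if not aligned:
            out.append(HarmonizedInstrument(
                rec.snp_id, rec.beta, rec.se, orec.beta, orec.se, rec.eaf, orec.eaf,
                status=DROPPED, drop_reason=ALLELE_MISMATCH))
            continue
        if palindromic:
            eaf_x = rec.eaf
            resolvable = (
                eaf_x is not None and eaf_y is not None
                and not (lo < eaf_x < hi) and not (lo < eaf_y < hi))
            if not resolvable:
                out.append(HarmonizedInstrument(
                    rec.snp_id, rec.beta, rec.se, orec.beta, orec.se, rec.eaf, orec.eaf,
                    status=DROPPED, drop_reason=AMBIGUOUS_PALINDROME))
                continue
            if (eaf_x < 0.5) != (eaf_y < 0.5):
                # strand flip: the outcome's effect allele is the exposure's other allele
                by = -by
                eaf_y = 1.0 - eaf_y
        out.append(_wald(rec.snp_id, rec.beta, rec.se, by, sy, rec.eaf, eaf_y,
                         second_order_se=second_order_se))
    n_dropped = sum(1 for i in out if i.status == DROPPED)
    if n_dropped:
        logger.info("harmonize(%s -> %s): dropped %d of %d instruments",
                    exposure_instruments.trait_name, outcome.trait_name,
                    n_dropped, len(out))
    return HarmonizedSet(
        exposure_instruments.trait_name, outcome.trait_name, out,
        exposure_type=exposure_instruments.trait_type,
        outcome_type=outcome.trait_type)
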