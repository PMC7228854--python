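"""GWAS summary-statistics tables and LD matrices: domain types and text I/O.

The on-disk convention is plain delimited text with a header row, one SNP per
line.  Tab is the canonical delimiter on write; tab, comma and run-of-whitespace
dialects are sniffed on read.  ``NA``, ``.`` and the empty string all denote a
missing value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, FormatError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical column order used by :func:`write_sumstats`.
CANONICAL_COLUMNS = (
    "snp", "effect_allele", "other_allele", "eaf", "beta", "se",
    "pval", "n", "n_case", "n_control",
)

_NA_STRINGS = {"NA", "", "."}
_MIN_PVAL = float(np.nextafter(0.0, 1.0))


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is on the standardized scale for continuous traits and is a
    natural-log odds ratio for binary traits.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None
    n_case: float | None = None
    n_control: float | None = None
    trait_type: str = "continuous"

    def validation_errors(self) -> list[str]:
        """Reason codes for every violated invariant (empty when valid)."""
        reasons = []
        for allele in (self.effect_allele, self.other_allele):
            if not isinstance(allele, str) or len(allele) == 0:
                reasons.append("bad_allele")
            elif len(allele) > 1:
                reasons.append("indel")
            elif allele.upper() not in VALID_ALLELES:
                reasons.append("bad_allele")
        if (self.effect_allele or "").upper() == (self.other_allele or "").upper():
            reasons.append("alleles_identical")
        if not (math.isfinite(self.beta)):
            reasons.append("bad_beta")
        if not (math.isfinite(self.se) and self.se > 0):
            reasons.append("nonpositive_se")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            reasons.append("bad_eaf")
        if not (0.0 < self.pval <= 1.0):
            reasons.append("bad_pval")
        if self.trait_type == "binary" and self.n is None:
            if self.n_case is None or self.n_control is None:
                reasons.append("missing_n_binary")
        return reasons

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT.get(self.effect_allele.upper()) == self.other_allele.upper()

    def effective_n(self) -> float:
        """Sample size entering variance-explained formulas.

        For binary traits with case/control counts this is the effective N
        ``4 / (1/n_case + 1/n_control)``; otherwise the total N.
        """
        if self.trait_type == "binary" and self.n_case is not None and self.n_control is not None:
            return 4.0 / (1.0 / self.n_case + 1.0 / self.n_control)
        if self.n is None:
            from .exceptions import MissingDataError

            raise MissingDataError(f"record {self.snp_id}: sample size unavailable")
        return float(self.n)


@dataclass
class ValidationReport:
    """What happened to each input row during :func:`read_sumstats`."""

    n_read: int = 0
    n_kept: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (snp_id, reason)
    flagged: list[tuple[str, str]] = field(default_factory=list)  # (snp_id, note)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


@dataclass
class SummaryStatTable:
    """Ordered collection of :class:`SummaryStatRecord`, unique by ``snp_id``."""

    trait_name: str
    trait_type: str
    records: list[SummaryStatRecord] = field(default_factory=list)
    validation: ValidationReport | None = None

    def __post_init__(self) -> None:
        self._index = {r.snp_id: r for r in self.records}
        if len(self._index) != len(self.records):
            seen: set[str] = set()
            for r in self.records:
                if r.snp_id in seen:
                    raise FormatError(f"duplicate snp_id {r.snp_id!r} in table {self.trait_name!r}")
                seen.add(r.snp_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SummaryStatRecord]:
        return iter(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> SummaryStatRecord | None:
        return self._index.get(snp_id)

    def subset(self, snp_ids: Sequence[str]) -> "SummaryStatTable":
        wanted = set(snp_ids)
        recs = [r for r in self.records if r.snp_id in wanted]
        return SummaryStatTable(self.trait_name, self.trait_type, recs)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "snp": r.snp_id, "effect_allele": r.effect_allele,
                "other_allele": r.other_allele, "eaf": r.eaf, "beta": r.beta,
                "se": r.se, "pval": r.pval, "n": r.n, "n_case": r.n_case,
                "n_control": r.n_control,
            })
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


@dataclass
class LDMatrix:
    """Square matrix of pairwise LD correlations with unit diagonal."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise FormatError(
                f"LD matrix shape {self.r.shape} does not match {k} SNP ids")
        if np.any(np.abs(self.r) > 1.0 + 1e-12):
            raise FormatError("LD correlations must lie in [-1, 1]")
        if np.max(np.abs(self.r - self.r.T)) > 1e-8:
            raise FormatError("LD matrix asymmetric beyond 1e-8")
        if np.max(np.abs(np.diag(self.r) - 1.0)) > 1e-8:
            raise FormatError("LD matrix diagonal must be 1")
        # canonicalize: exact symmetry and unit diagonal
        self.r = (self.r + self.r.T) / 2.0
        np.fill_diagonal(self.r, 1.0)
        self._pos = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._pos

    def subset(self, snp_ids: Sequence[str]) -> "LDMatrix":
        from .exceptions import CoverageError

        try:
            idx = [self._pos[s] for s in snp_ids]
        except KeyError as exc:
            raise CoverageError(f"SNP {exc.args[0]!r} missing from LD matrix") from None
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])

    def corr(self, a: str, b: str) -> float:
        return float(self.r[self._pos[a], self._pos[b]])


def _sniff_delimiter(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return r"\s+"


def _get(row, col):
    if col is None:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, str) and v.strip() in _NA_STRINGS:
        return None
    return v


def read_sumstats(
    path: str,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
    trait_name: str | None = None,
) -> SummaryStatTable:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    column_map
        Mapping from standard field names (``snp``, ``effect_allele``,
        ``other_allele``, ``eaf``, ``beta`` *or* ``or``, ``se``, ``pval``,
        ``n``, ``n_case``, ``n_control``) to the file's column names.
        Defaults to the canonical names themselves.  When ``or`` is mapped
        instead of ``beta``, odds ratios are converted by natural log.

    Rows violating a record invariant are dropped and counted, with reason
    codes, in ``table.validation``; a p-value of exactly 0 is clamped to the
    smallest positive float and flagged rather than dropped.
    """
    if trait_type not in ("continuous", "binary"):
        raise FormatError(f"unknown trait_type {trait_type!r}")
    cmap = dict(column_map or {})
    for k in CANONICAL_COLUMNS:
        cmap.setdefault(k, k)
    sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, engine="python",
                         na_values=["NA", "."], keep_default_na=True)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    has_or = "or" in (column_map or {})
    mandatory = ["snp", "effect_allele", "other_allele", "se", "pval"]
    mandatory.append("or" if has_or else "beta")
    for fld in mandatory:
        if cmap.get(fld, fld) not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {cmap.get(fld, fld)!r} (field {fld!r})")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: header only, no rows")

    report = ValidationReport(n_read=len(df))
    records: list[SummaryStatRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        snp = _get(row, cmap["snp"])
        snp = str(snp) if snp is not None else "?"
        if snp in seen:
            report.dropped.append((snp, "duplicate_snp_id"))
            continue

        def fnum(fieldname):
            col = cmap.get(fieldname)
            v = _get(row, col) if col in df.columns else None
            return float(v) if v is not None else None

        ea = _get(row, cmap["effect_allele"])
        oa = _get(row, cmap["other_allele"])
        ea = str(ea).upper() if ea is not None else ""
        oa = str(oa).upper() if oa is not None else ""
        if has_or:
            or_col = (column_map or {}).get("or", "or")
            raw = _get(row, or_col)
            or_val = float(raw) if raw is not None else None
            if or_val is None or or_val <= 0:
                report.dropped.append((snp, "bad_odds_ratio"))
                continue
            beta = math.log(or_val)
            report.flagged.append((snp, "or_to_beta"))
        else:
            beta = fnum("beta")
        pval = fnum("pval")
        if pval == 0.0:
            pval = _MIN_PVAL
            report.flagged.append((snp, "pval_clamped"))
        se = fnum("se")
        rec = SummaryStatRecord(
            snp_id=snp, effect_allele=ea, other_allele=oa,
            beta=beta if beta is not None else float("nan"),
            se=se if se is not None else float("nan"),
            pval=pval if pval is not None else float("nan"),
            eaf=fnum("eaf"), n=fnum("n"), n_case=fnum("n_case"),
            n_control=fnum("n_control"), trait_type=trait_type,
        )
        reasons = rec.validation_errors()
        if reasons:
            report.dropped.append((snp, reasons[0]))
            continue
        seen.add(snp)
        records.append(rec)
    report.n_kept = len(records)
    if report.dropped:
        logger.info("%s: dropped %d/%d rows during validation", path,
                    report.n_dropped, report.n_read)
    name = trait_name if trait_name is not None else str(path)
    return SummaryStatTable(name, trait_type, records, validation=report)


def _fmt(v) -> str:
    if v is None:
        return "NA"
    return format(v, ".10g")


def write_sumstats(table: SummaryStatTable, path: str) -> str:
    """Write a table as tab-delimited text with the canonical header.

    Values round-trip at 10 significant digits; absent optional fields are
    written as ``NA``.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for r in table.records:
            fh.write("\t".join([
                r.snp_id, r.effect_allele, r.other_allele, _fmt(r.eaf),
                _fmt(r.beta), _fmt(r.se), _fmt(r.pval), _fmt(r.n),
                _fmt(r.n_case), _fmt(r.n_control),
            ]) + "\n")
    return path


def read_ld_matrix(path: str) -> LDMatrix:
    """Read a delimited square LD correlation matrix with SNP-id header row
    and first column."""
    sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: LD matrix is not square ({df.shape[0]}x{df.shape[1]})")
    ids = [str(s) for s in df.columns]
    row_ids = [str(s) for s in df.index]
    if ids != row_ids:
        raise FormatError(f"{path}: row and column SNP ids differ")
    return LDMatrix(ids, df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str) -> str:
    """Inverse of :func:`read_ld_matrix` (tab-delimited)."""
    pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep="\t", float_format="%.10g")
    return path


def or_to_beta(odds_ratio: float) -> float:
    """Natural-log transform of an odds ratio onto the beta scale."""
    return math.log(odds_ratio)


def beta_to_or(beta: float) -> float:
    """Exponential transform of a log-odds beta onto the odds-ratio scale."""
    return math.exp(beta)
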