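"""Exception hierarchy for tsmr."""


class MRError(Exception):
    """Base class for all tsmr errors."""


class FormatError(MRError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class EmptyInputError(MRError):
    """An input file or table contains no data rows."""


class EmptyInstrumentError(MRError):
    """No SNP survived instrument selection at the given threshold."""


class InsufficientInstrumentsError(MRError):
    """Fewer instruments than the estimator's minimum."""


class DegenerateWeightsError(MRError):
    """All weights are zero or undefined (e.g. every ratio SE is zero)."""


class MissingDataError(MRError):
    """A required per-record field (e.g. sample size) is absent."""


class ConfigurationError(MRError):
    """Invalid user-supplied configuration (policy, SIMEX grid, scenario)."""


class CoverageError(MRError):
    """The LD matrix does not cover every instrument SNP."""


class ConditioningError(MRError):
    """A covariance matrix is numerically singular or not positive definite."""


class ScenarioInfeasibleError(MRError):
    """A simulation scenario cannot satisfy its own constraints."""
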