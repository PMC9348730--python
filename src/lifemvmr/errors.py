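"""Exception hierarchy for lifemvmr."""


class LifemvmrError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(LifemvmrError, ValueError):
    """Invalid scenario configuration."""


class NoInstrumentsError(LifemvmrError, RuntimeError):
    """Instrument selection returned an empty set; estimation must not proceed."""


class AlignmentError(LifemvmrError, ValueError):
    """Exposure and outcome summary statistics could not be aligned on SNPs."""


class SingularDesignError(LifemvmrError, RuntimeError):
    """Exposure-association columns are (numerically) collinear."""


class UndefinedStatisticError(LifemvmrError, RuntimeError):
    """A diagnostic statistic is undefined for the given dimensions."""


class SummaryFileError(LifemvmrError, ValueError):
    """A GWAS summary-statistics file could not be parsed."""
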