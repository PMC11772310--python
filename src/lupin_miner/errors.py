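"""Exception hierarchy shared across the package."""


class LupinMinerError(Exception):
    """Base class for package-specific failures."""


class ConfigError(LupinMinerError):
    """A configuration value is missing, malformed, or inconsistent."""


class GenerationError(LupinMinerError):
    """A synthetic-data spec could not be realized (e.g. infeasible target PCC)."""


class ZeroVarianceError(LupinMinerError):
    """Pearson correlation requested on a constant vector.

    Constant expression profiles have no defined correlation; callers must
    exclude them explicitly rather than receive a silent 0.
    """


class MissingInternalStandardError(LupinMinerError):
    """Internal-standard peak absent or zero; the sample cannot be normalized."""


class BlankContradictionError(LupinMinerError):
    """The analyte peak itself matched a blank-run peak during %area purity."""
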