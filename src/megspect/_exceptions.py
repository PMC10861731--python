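"""Exception hierarchy.

Schema/configuration problems and numerically degenerate inputs raise
distinct types so callers (and the CLI exit-code mapping) can tell a
malformed run from an analysis that is undefined for the data at hand.
"""


class MegspectError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MegspectError, ValueError):
    """A run or cohort configuration field is invalid; message names the field."""


class SchemaError(MegspectError, ValueError):
    """Tabular input violates the expected schema (duplicate ids, missing columns...)."""


class NyquistError(ConfigurationError):
    """A filter band edge reaches or exceeds the Nyquist frequency."""


class LagError(MegspectError, ValueError):
    """Autocorrelation maximum lag is too long for the epoch."""


class EpochError(MegspectError, ValueError):
    """Recording too short to yield a single epoch."""


class DegenerateSpectrumError(MegspectError, ValueError):
    """Spectrum carries no power in the frequency range of interest."""


class DegenerateBandError(DegenerateSpectrumError):
    """No spectral mass inside a required sub-band (e.g. the extended alpha range)."""


class ConstantInputError(MegspectError, ValueError):
    """A rank correlation is undefined because one input vector is constant."""


class DegenerateControlError(MegspectError, ValueError):
    """Control standard deviation is zero or negative somewhere in the brain mask."""


class UndefinedRatioError(MegspectError, ArithmeticError):
    """Whole-brain exceedance is zero, so the VOI/brain extent ratio is undefined."""


class DegeneratePredictorError(MegspectError, ValueError):
    """A regression predictor is constant and cannot be unit-scaled."""
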