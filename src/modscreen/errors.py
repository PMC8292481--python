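"""Exception hierarchy shared across the package."""


class ModscreenError(Exception):
    """Base class for all package-specific errors."""


class TripletParseError(ModscreenError, ValueError):
    """A genotype-count triplet string could not be parsed."""


class UndefinedFrequencyError(ModscreenError, ValueError):
    """Allele frequency requested for an empty genotype group."""


class LookupError_(ModscreenError, KeyError):
    """Unknown variant or group label in a genotype matrix."""


class FormatError(ModscreenError, ValueError):
    """An input file does not conform to its declared format."""


class DegenerateTableError(ModscreenError, ValueError):
    """A 2x2 table is too degenerate for the requested statistic."""


class SeparationError(ModscreenError, RuntimeError):
    """Perfect separation detected while fitting a logistic model."""


class ConvergenceError(ModscreenError, RuntimeError):
    """A model fit failed to converge within the iteration budget."""


class InsufficientSamplesError(ModscreenError, ValueError):
    """Fewer individuals available than requested for sampling."""
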