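"""Exception hierarchy shared across the toolkit."""


class NirTasteError(Exception):
    """Base class for all toolkit errors."""


class DomainError(NirTasteError):
    """A value is outside the physically / mathematically valid domain."""


class FormatError(NirTasteError):
    """A file does not conform to the expected on-disk layout."""


class ConfigError(NirTasteError):
    """An option or configuration value is invalid."""


class JoinError(NirTasteError):
    """Spectra and chemistry tables cannot be aligned."""


class DegenerateInputError(NirTasteError):
    """Input is valid in shape but statistically degenerate (e.g. zero variance)."""


class ShapeError(NirTasteError):
    """Array dimensions are inconsistent."""


class RegistryError(NirTasteError):
    """An unknown name was requested from a function registry."""


class TrainingError(NirTasteError):
    """Numerical failure (divergence) during model training."""


class SizeError(NirTasteError):
    """A combinatorial or sample-size budget was exceeded / not met."""


class ProtocolError(NirTasteError):
    """The replicated evaluation protocol failed its integrity conditions."""


class CoverageError(NirTasteError):
    """A sample was never covered by any test split during aggregation."""
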