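"""Exception hierarchy for ftirseed.

All errors derive from :class:`FtirSeedError` so callers can catch the
package's failures with a single except clause; most also derive from
``ValueError`` because they signal invalid arguments or data.
"""


class FtirSeedError(Exception):
    """Base class for all ftirseed errors."""


class InvalidGridError(FtirSeedError, ValueError):
    """Wavenumber grid parameters are inconsistent (non-divisible span, etc.)."""


class DomainError(FtirSeedError, ValueError):
    """Unknown class label or location batch."""


class GridMismatchError(FtirSeedError, ValueError):
    """Spectra that must share a wavenumber grid do not."""


class InsufficientPeaksError(FtirSeedError, ValueError):
    """A spectrum has fewer local maxima than the requested peak count."""


class DegenerateAttributeError(FtirSeedError, ValueError):
    """All attribute columns are constant; fuzzy normalization is undefined."""


class NotTransitiveError(FtirSeedError, ValueError):
    """A lambda-cut was requested on a relation that is not max-min transitive."""


class ValidityUndefinedError(FtirSeedError, ValueError):
    """The cluster validity index needs at least two clusters."""


class InvalidPartitionError(FtirSeedError, ValueError):
    """A partition has empty clusters or does not cover the object set."""


class InsufficientLengthError(FtirSeedError, ValueError):
    """Signal too short for the requested number of decomposition levels."""


class CorruptDecompositionError(FtirSeedError, ValueError):
    """Wavelet coefficient arrays are inconsistent with the source length."""


class InvalidRegionError(FtirSeedError, ValueError):
    """A feature region refers to coefficients that do not exist."""


class DegenerateInputError(FtirSeedError, ValueError):
    """Training data too small or too uniform to select feature regions."""


class ConfigError(FtirSeedError, ValueError):
    """Invalid training or run configuration."""


class SchemaError(ConfigError):
    """A run-configuration mapping is missing keys or has the wrong types."""
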