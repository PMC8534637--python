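"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors exit 2 (click's default),
:class:`DataError` subclasses exit 3, :class:`NumericalError` subclasses exit 4.
"""


class SpecfreshError(Exception):
    """Base class for all package-specific errors."""


class DataError(SpecfreshError):
    """Problems with input data: schema, parsing, integrity, selection."""


class SchemaError(DataError):
    """A required column is missing or a header cannot be interpreted."""


class ParseError(DataError):
    """A cell could not be parsed; message carries row/column coordinates."""


class IntegrityError(DataError):
    """Internal consistency violated (duplicate ids, mismatched lengths)."""


class EmptySelectionError(DataError):
    """A subset predicate or index list selected no samples."""


class NumericalError(SpecfreshError):
    """Numerical or convergence failures."""


class InsufficientDataError(NumericalError):
    """Too few samples for the requested computation."""


class SingularCovarianceError(NumericalError):
    """Covariance matrix is singular; lower the number of PCA components
    or pass ``pseudo_inverse=True`` explicitly."""


class ConfigError(SpecfreshError):
    """Invalid configuration value (architecture, training, generator)."""


class BuildError(ConfigError):
    """A model cannot be built from the given configuration, e.g. the
    sequence length underflows in some stage."""


class NotFittedError(SpecfreshError):
    """Transform or predict called before fit."""


class FoldError(SpecfreshError):
    """A cross-validation fold is unusable (e.g. single-class training set)."""
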