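"""Exception hierarchy shared across the pipeline.

Contract violations (bad arguments, malformed configuration) raise
:class:`ContractError` subclasses; problems with the data content itself
(degenerate variances, too few strains) raise :class:`DataError` subclasses.
The CLI maps the two branches to exit codes 2 and 3 respectively.
"""


class PanelmarkError(Exception):
    """Base class for all errors raised by this package."""


class ContractError(PanelmarkError, ValueError):
    """An argument or precondition was violated by the caller."""


class ConfigurationError(ContractError):
    """A configuration value is invalid; the message names the field."""


class SchemaError(ContractError):
    """A table is structurally malformed (missing columns, duplicate keys)."""


class DataError(PanelmarkError):
    """The data content cannot support the requested computation."""


class DegenerateDataError(DataError):
    """All-zero variance or otherwise degenerate input."""


class InsufficientDataError(DataError):
    """Fewer observations than the method requires."""


class SeparationWarning(UserWarning):
    """Quasi-complete separation detected in a logistic fit."""


class ShrinkageFallbackWarning(UserWarning):
    """Variance-shrinkage hyperparameters hit a boundary case."""
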