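"""Exception hierarchy.

All package errors derive from :class:`EcShockError` so callers can catch one
base class; subtypes distinguish configuration mistakes from data problems
and evaluation degeneracies.
"""


class EcShockError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EcShockError, ValueError):
    """Invalid configuration value (bad rate, non-positive multiplier, ...)."""


class DomainError(EcShockError, ValueError):
    """Input outside the physical/mathematical domain of an operation."""


class ProtocolError(EcShockError, ValueError):
    """Stage timing inconsistent with window/exclusion requirements."""


class DataError(EcShockError, ValueError):
    """Structurally invalid data (duplicates, missing required rows)."""


class SchemaError(EcShockError, KeyError):
    """Feature/column set does not match what a fitted object expects."""


class EvaluationError(EcShockError, ValueError):
    """Diagnostic evaluation impossible (e.g. single-class labels)."""


class TrainingError(EcShockError, RuntimeError):
    """Model training failed for every candidate setting."""
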