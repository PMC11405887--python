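"""Exception hierarchy.

Errors are split by who can fix them: ``ConfigurationError`` (caller named a
column or option wrong), ``InputError`` (the file itself is malformed),
``ValidationError`` (the data violate a domain invariant; carries the QC
report when one exists), and design/model specific failures.
"""

from __future__ import annotations


class BlotKitError(Exception):
    """Base class for all blotkit errors."""


class ConfigurationError(BlotKitError):
    """A requested column, option or parameter does not exist."""


class InputError(BlotKitError):
    """The input file or table is malformed (empty, non-numeric, ...)."""


class ValidationError(BlotKitError):
    """The data violate a domain invariant (e.g. a subject in two groups)."""

    def __init__(self, message: str, qc_report=None):
        super().__init__(message)
        self.qc_report = qc_report


class InfeasibleDesignError(BlotKitError):
    """The requested gel layout cannot satisfy the counterbalancing rules."""


class StrategyError(BlotKitError):
    """An analysis strategy is incompatible with the data (e.g. random-effect
    replication with a single replicate)."""


class ModelError(BlotKitError):
    """A model fit is impossible (singular design, one group, ...)."""
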