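"""Exception hierarchy shared by all modules."""


class CophyloError(Exception):
    """Base class for all package errors."""


class TreeFormatError(CophyloError):
    """Raised when a Newick source cannot be parsed."""


class ValidationError(CophyloError):
    """Raised when an input violates a documented precondition."""


class InfeasibleReconciliationError(CophyloError):
    """Raised when constraints (e.g. time zones) admit no valid reconciliation."""
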