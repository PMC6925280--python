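"""Exception hierarchy shared across the package."""


class MetagrsError(Exception):
    """Base class for all package errors."""


class ValidationError(MetagrsError, ValueError):
    """An argument or parameter violates a stated precondition."""


class FormatError(MetagrsError, ValueError):
    """A file does not conform to the expected tabular/binary layout."""


class EmptyOverlapError(MetagrsError, ValueError):
    """No variants shared between a weight table and a genotype panel."""


class HarmonizationError(MetagrsError, ValueError):
    """Conflicting allele frames that cannot be reconciled."""


class DegenerateError(MetagrsError, ValueError):
    """A fit or transform is undefined (zero variance, no events, ...)."""
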