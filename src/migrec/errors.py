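"""Exception hierarchy shared across the package.

CLI exit-code mapping: :class:`ValidationError` -> 2,
:class:`SizeCapError` -> 3, everything else -> 1.
"""


class MigrecError(Exception):
    """Base class for all errors raised by migrec."""


class DomainError(MigrecError, ValueError):
    """An argument lies outside the mathematical domain of an operation
    (mismatched ground sets, a non-subset restriction, wrong site count...)."""


class ValidationError(MigrecError, ValueError):
    """Model data violates a structural invariant (non-stochastic matrix,
    probabilities that do not sum to one, unknown deme label...)."""


class SizeCapError(MigrecError):
    """A combinatorial enumeration would exceed its configured size cap."""

    def __init__(self, what: str, requested: int, cap: int):
        self.what = what
        self.requested = requested
        self.cap = cap
        super().__init__(
            f"{what}: requested size {requested} exceeds the configured cap {cap}"
        )
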