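"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: :class:`InputError` -> 2,
:class:`DegenerateDataError` -> 3.
"""


class SeedsortError(Exception):
    """Base class for all errors raised by seedsort."""


class InputError(SeedsortError):
    """Malformed files, mismatched shapes, unknown options."""


class FormatError(InputError):
    """A file on disk does not conform to its declared format."""


class DomainError(SeedsortError):
    """Values outside the mathematical domain of a transform."""


class DegenerateDataError(SeedsortError):
    """Data that makes an operation ill-defined (single class, zero
    variance, empty batch, standard condition at k=0 or k=N)."""


class PreprocessMismatchError(SeedsortError):
    """A model was asked to score spectra prepared with a different
    preprocessing variant; scores would be meaningless."""
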