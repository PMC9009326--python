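class OperonMergeError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(OperonMergeError):
    """A file did not conform to its declared format."""


class ValidationError(OperonMergeError):
    """In-memory data violated a structural invariant."""
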