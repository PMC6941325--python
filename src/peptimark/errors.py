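"""Exception hierarchy shared across the pipeline."""


class PeptimarkError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PeptimarkError):
    """Input violates a documented invariant or precondition."""


class FormatError(PeptimarkError):
    """A file does not conform to the documented dialect."""


class NormalizationError(PeptimarkError):
    """Internal-standard normalization cannot be performed."""
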