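"""Exception hierarchy.

All package-specific failures derive from :class:`CuitransError` so callers
can catch a single base class at pipeline boundaries.
"""


class CuitransError(Exception):
    """Base class for all cuitrans errors."""


class CorpusFormatError(CuitransError):
    """A corpus file does not conform to the expected dialect (bad header,
    malformed line, unknown syntax)."""


class CorpusValidationError(CuitransError):
    """A corpus violates a data-model invariant (dangling document reference,
    offset out of range, span/text mismatch, malformed CUI)."""


class OverlapError(CuitransError):
    """Two annotations on the same document overlap (equal, nested or
    crossing spans), which the inline marker grammar cannot represent."""


class MarkerCollisionError(CuitransError):
    """An annotation's span text contains marker syntax ("[[", "][" or "]]")
    and therefore cannot be embedded."""


class TranslatorError(CuitransError):
    """A translator backend failed to produce a translation."""


class ConfigurationError(CuitransError):
    """An adapter or generator configuration is invalid or incomplete."""


class MismatchError(CuitransError):
    """Two corpora that must share a document-id set do not."""
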