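"""Exception hierarchy for glycankit.

Every error raised by the library derives from :class:`GlycanError`, so
callers (and the CLI) can distinguish library failures from programming
errors with a single except clause.
"""


class GlycanError(Exception):
    """Base class for all glycankit errors."""


class VocabularyError(GlycanError):
    """A name is not in the closed dictionary (monosaccharide, substituent,
    template)."""


class MissingResidueError(GlycanError):
    """A residue id does not name an existing residue."""


class ConflictError(GlycanError):
    """An edit collides with existing content (e.g. duplicate substituent at
    the same known position)."""


class ValidationError(GlycanError):
    """A value is outside its allowed enumeration or violates a structural
    constraint (ring bounds, empty attachment-site set, bad config)."""


class NoParentError(GlycanError):
    """A linkage edit addressed the root residue, which has no parent."""


class DependencyError(GlycanError):
    """A delete would strand dependent structure (core root while fragments
    exist, or a fragment left without attachment sites)."""


class OrderingError(GlycanError):
    """An operation requires the core part to exist first."""


class TruncationError(GlycanError):
    """Enumeration produced more results than the caller allowed."""


class EmptyDocumentError(GlycanError):
    """Serialization of an empty document was requested."""


class GlycoCTParseError(GlycanError):
    """Malformed GlycoCT condensed text.

    Carries the 1-based line number where parsing failed.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnsupportedFeatureError(GlycanError):
    """The input uses a format feature outside scope (GlycoCT REP/ALT)."""


class WurcsParseError(GlycanError):
    """Malformed WURCS text."""


class WurcsVersionError(WurcsParseError):
    """WURCS version other than 2.0."""


class UnsupportedResidueError(GlycanError):
    """A residue has no entry in the WURCS encoding dictionary."""
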