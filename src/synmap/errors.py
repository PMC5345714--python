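"""Exception hierarchy for synmap.

All package errors derive from :class:`SynmapError` so callers can catch one
type at a pipeline boundary. ``FormatError`` is raised for malformed input
files (wrong columns, wrong field counts); ``ValidationError`` for inputs that
parse but violate a domain invariant (negative cM, duplicate locus ids,
coordinates off the end of a chromosome).
"""


class SynmapError(Exception):
    """Base class for all synmap errors."""


class FormatError(SynmapError):
    """An input file does not match the expected tabular schema."""


class ValidationError(SynmapError):
    """Parsed input violates a domain invariant."""
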