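"""Exception hierarchy shared across the package."""


class IgLineageError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(IgLineageError):
    """An input file could not be parsed (malformed, truncated, wrong dialect)."""


class AssemblyError(IgLineageError):
    """Parsed inputs could not be assembled into a valid lineage tree."""
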