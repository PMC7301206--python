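"""Exception hierarchy.

``BescanError`` is the base for all package-raised errors; the CLI maps
``TargetError`` subclasses and bad arguments to exit code 2 and everything
else to exit code 1.
"""


class BescanError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(BescanError):
    """Input file could not be parsed or is structurally empty."""


class TargetError(BescanError):
    """Problems resolving a user target query (exit code 2 in the CLI)."""


class TargetNotFoundError(TargetError):
    """No feature or contig matched the query."""


class AmbiguousTargetError(TargetError):
    """More than one feature matched the query."""

    def __init__(self, query: str, matches: list[str]):
        self.query = query
        self.matches = matches
        super().__init__(
            f"query {query!r} matches {len(matches)} features: {', '.join(matches)}"
        )


class BoundsError(TargetError):
    """A coordinate range falls outside the contig."""


class ConsistencyError(BescanError):
    """Internal invariant violated (e.g. a guide failed to find itself)."""
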