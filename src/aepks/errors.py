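"""Exception hierarchy for the toolkit.

Parse and validation failures are structured: they name the offending
feature, gene or position so that a malformed cluster file can be fixed
without reading a stack trace.
"""


class AEPKSError(Exception):
    """Base class for all toolkit errors."""


class ClusterParseError(AEPKSError):
    """A cluster file violates the annotation dialect (missing, malformed
    or overlapping features). ``feature`` names the offender."""

    def __init__(self, message: str, feature: str | None = None):
        self.feature = feature
        super().__init__(message if feature is None else f"{message} (feature: {feature})")


class FrameError(AEPKSError):
    """A coding sequence cannot be translated cleanly. ``gene`` names the
    CDS; ``codons`` lists 0-based codon indices of internal stops."""

    def __init__(self, message: str, gene: str | None = None, codons: list[int] | None = None):
        self.gene = gene
        self.codons = codons or []
        super().__init__(message)


class AmbiguousBaseError(AEPKSError):
    """Nucleotide sequence contains characters outside {A,C,G,T};
    ``positions`` lists the 0-based offending offsets."""

    def __init__(self, positions: list[int]):
        self.positions = positions
        shown = ", ".join(map(str, positions[:10]))
        more = "" if len(positions) <= 10 else f" (+{len(positions) - 10} more)"
        super().__init__(f"ambiguous/invalid bases at positions {shown}{more}")


class ValidationError(AEPKSError):
    """A constructed object violates a model invariant."""


class InfeasibleSpecError(AEPKSError):
    """A synthetic-data specification cannot be realised (e.g. the
    requested identity is below what random sequences of that length
    can reach)."""
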