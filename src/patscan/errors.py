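"""Exception hierarchy for the patscan package."""

from __future__ import annotations


class PatScanError(Exception):
    """Base class for all patscan errors."""


class InvalidResidueError(PatScanError):
    """A sequence contains a letter outside the declared alphabet."""

    def __init__(self, char: str, position: int, context: str = ""):
        self.char = char
        self.position = position  # 1-based position in the raw input
        where = f" in {context}" if context else ""
        super().__init__(
            f"invalid residue {char!r} at position {position}{where}"
        )


class PatternSyntaxError(PatScanError):
    """The pattern expression could not be tokenized/parsed."""

    def __init__(self, message: str, offset: int, hint: str = ""):
        self.offset = offset  # 0-based character offset into the expression
        self.hint = hint
        suffix = f" (expected {hint})" if hint else ""
        super().__init__(f"syntax error at offset {offset}: {message}{suffix}")


class PatternValidationError(PatScanError):
    """The pattern parsed but violates a semantic rule."""

    def __init__(self, violations):
        self.violations = list(violations)
        summary = "; ".join(str(v) for v in self.violations)
        super().__init__(f"invalid pattern: {summary}")


class FastaFormatError(PatScanError):
    """Malformed FASTA input."""


class FixtureError(PatScanError):
    """Infeasible synthetic-data request (e.g. motifs do not fit)."""


class OracleBoundError(PatScanError):
    """The brute-force oracle refused a combinatorially unbounded case."""
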