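"""Exception hierarchy.

Every error raised on malformed input carries enough locational context
(line number, column index) to find the offending record in a multi-megabyte
tab file.
"""


class VarinetError(Exception):
    """Base class for all package errors."""


class MitabParseError(VarinetError):
    """A MITAB cell could not be tokenised (bad quoting, empty item)."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        loc = []
        if line is not None:
            loc.append(f"line {line}")
        if column is not None:
            loc.append(f"column {column}")
        suffix = f" ({', '.join(loc)})" if loc else ""
        super().__init__(message + suffix)
        self.line = line
        self.column = column


class MitabFormatError(VarinetError):
    """A line has a column count outside every supported MITAB dialect."""

    def __init__(self, message: str, line: int | None = None):
        suffix = f" (line {line})" if line is not None else ""
        super().__init__(message + suffix)
        self.line = line


class RecordValidationError(VarinetError):
    """A record violates a type invariant (e.g. score outside [0, 1])."""


class ConfigurationError(VarinetError):
    """A filter/generator configuration references unknown terms or is infeasible."""


class ProteinChangeError(VarinetError):
    """A protein-change string is not HGVS-like and cannot be normalised."""


class AggregationError(VarinetError):
    """Duplicate term ids within one enrichment list during comparison."""
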