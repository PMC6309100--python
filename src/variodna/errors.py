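"""Exception hierarchy shared by all variodna modules."""


class VariOError(Exception):
    """Base class for all variodna errors."""


class StructuralError(VariOError):
    """The term table or graph violates a structural requirement."""


class CycleError(StructuralError):
    """The is_a graph contains a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(f"is_a cycle: {' -> '.join(str(a) for a in self.cycle)}")


class ConflictError(StructuralError):
    """One accession is claimed by two different term names."""


class NotFoundError(VariOError, KeyError):
    """An accession or term name is not in the graph."""

    def __init__(self, key):
        self.key = key
        super().__init__(f"unknown term: {key!r}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class LabelSyntaxError(VariOError):
    """An annotation label string does not match 'VariO:NNNN name'."""


class LabelConsistencyError(VariOError):
    """A label's accession and name disagree with the graph."""


class HgvsSyntaxError(VariOError):
    """An HGVS DNA description could not be parsed."""

    def __init__(self, message: str, text: str = "", column: int | None = None):
        self.text = text
        self.column = column
        if column is not None:
            message = f"{message} (column {column} of {text!r})"
        super().__init__(message)


class NonVariationError(VariOError):
    """Reference and alternate states are identical: not a variation."""


class UnsupportedKindError(VariOError):
    """Edit kind outside the supported DNA chain variation categories."""


class DomainError(VariOError):
    """A base outside the DNA alphabet A/C/G/T."""


class AmbiguityError(VariOError):
    """A position overlaps region intervals with conflicting labels."""

    def __init__(self, message: str, intervals=()):
        self.intervals = list(intervals)
        super().__init__(message)


class RegionLookupError(VariOError):
    """Sequence name absent from the region model."""


class EvidenceFormatError(VariOError):
    """An evidence code does not match the ECO:NNNNNNN pattern."""


class VcfFormatError(VariOError):
    """A VCF file is structurally unreadable (e.g. missing #CHROM header)."""


class VcfRecordError(VariOError):
    """A single VCF record could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ParameterError(VariOError, ValueError):
    """A generator parameter is outside its allowed range."""
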