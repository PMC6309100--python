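"""Automatic classification of DNA variants into VariO term paths.

Two things are inferred from sequence-level input alone:

* the variation type (the five DNA chain variation categories, with
  transition/transversion subtyping of substitutions), and
* the affected DNA level (mitochondrial vs. chain location: exon,
  intron, intergenic), from the HGVS prefix and an optional region
  model of labeled genomic intervals.

Everything else in the vocabulary — origin, function, property and the
non-level structure terms — reflects experimental knowledge and is only
*validated* against its branch, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from intervaltree import IntervalTree

from .errors import (
    AmbiguityError,
    DomainError,
    NonVariationError,
    NotFoundError,
    RegionLookupError,
    StructuralError,
    UnsupportedKindError,
)
from .hgvs_dna import DNA_BASES, EditKind, HgvsDescription, UtrAnchor
from .term_model import BRANCH_QUERY_ROOTS, OntologyGraph, load_packaged_graph

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

# accessions used by the automatic classifiers
ROOT_TYPE = 129
CLASSIFICATION = 322
CHAIN_VARIATION = 135
SUBSTITUTION = 136
DELETION = 141
INSERTION = 142
INDEL = 143
TRANSLOCATION = 144
INVERSION = 145
TRANSITION = 313
PYRIMIDINE_TRANSITION = 314
PURINE_TRANSITION = 315
TRANSVERSION = 316
ROOT_STRUCTURE = 155
AFFECTED_LEVEL = 159
CHAIN_AFFECTED = 160
IN_INTRON = 161
IN_EXON = 162
INTERGENIC = 163
EXTRACHROMOSOMAL = 72
ORGANELLAR = 448
MITOCHONDRIAL = 450


class EditClass(str, Enum):
    """Normalized, format-independent edit categories."""

    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"
    INDEL = "indel"
    INVERSION = "inversion"
    TRANSLOCATION = "translocation"


@dataclass(frozen=True)
class NormalizedEdit:
    """Reference/alternate edit after affix trimming, any input format.

    ``position`` is 1-based; for insertions it is the base after which
    the new sequence is inserted.
    """

    kind: EditClass
    position: int
    ref: str = ""
    alt: str = ""

    def __post_init__(self):
        k = self.kind
        if k is EditClass.SUBSTITUTION:
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError("substitution requires single-base ref and alt")
            if self.ref == self.alt:
                raise NonVariationError(f"{self.ref}>{self.alt} is not a variation")
        elif k is EditClass.DELETION and (self.alt or not self.ref):
            raise ValueError("deletion requires nonempty ref and empty alt")
        elif k is EditClass.INSERTION and (self.ref or not self.alt):
            raise ValueError("insertion requires empty ref and nonempty alt")
        elif k is EditClass.INDEL:
            if not (self.ref and self.alt):
                raise ValueError("indel requires nonempty ref and alt")
            if len(self.ref) == 1 and len(self.alt) == 1:
                raise ValueError("single-base replacement is a substitution, not an indel")


@dataclass(frozen=True)
class TermPath:
    """Root-to-deepest chain of is_a-linked accessions."""

    accessions: tuple[int, ...]

    def __post_init__(self):
        if not self.accessions:
            raise ValueError("empty term path")

    @property
    def deepest(self) -> int:
        return self.accessions[-1]

    def verify(self, graph: OntologyGraph) -> None:
        """Assert each consecutive pair is a parent -> child edge."""
        for parent, child in zip(self.accessions, self.accessions[1:]):
            if parent not in graph.get_term(child).parents:
                raise StructuralError(
                    f"{parent} -> {child} is not an is_a edge in the graph"
                )

    def __iter__(self):
        return iter(self.accessions)


# -- substitution subtype ------------------------------------------------------


def classify_substitution_subtype(ref: str, alt: str) -> TermPath:
    """Subtype path below "DNA substitution" for one ordered base pair.

    Transitions stay within the purines (A<->G) or within the
    pyrimidines (C<->T) and are refined to the purine/pyrimidine leaf;
    every purine<->pyrimidine exchange is a transversion.
    """
    ref, alt = ref.upper(), alt.upper()
    for b in (ref, alt):
        if b not in DNA_BASES:
            raise DomainError(f"not a DNA base: {b!r}")
    if ref == alt:
        raise NonVariationError(f"{ref}>{alt} is not a variation")
    if ref in PURINES and alt in PURINES:
        return TermPath((TRANSITION, PURINE_TRANSITION))
    if ref in PYRIMIDINES and alt in PYRIMIDINES:
        return TermPath((TRANSITION, PYRIMIDINE_TRANSITION))
    return TermPath((TRANSVERSION,))


# -- variation type ------------------------------------------------------------

_CHAIN_HEAD = (ROOT_TYPE, CLASSIFICATION, CHAIN_VARIATION)

_HGVS_KIND_TO_CLASS = {
    EditKind.SUBSTITUTION: EditClass.SUBSTITUTION,
    EditKind.DELETION: EditClass.DELETION,
    EditKind.INSERTION: EditClass.INSERTION,
    EditKind.DELINS: EditClass.INDEL,
    EditKind.DUPLICATION: EditClass.INSERTION,  # dup inserts bases vs. reference
    EditKind.INVERSION: EditClass.INVERSION,
}


def classify_variation_type(edit: NormalizedEdit | HgvsDescription) -> TermPath:
    """Full variation-type path for one edit.

    Returns the chain from the variation-type root through the DNA chain
    variation category down to the deepest assignable term; substitutions
    continue into the transition/transversion subtree.
    """
    if isinstance(edit, HgvsDescription):
        cls = _HGVS_KIND_TO_CLASS[edit.edit_kind]
        ref, alt = edit.ref_bases or "", edit.alt_bases or ""
    else:
        cls, ref, alt = edit.kind, edit.ref, edit.alt

    if cls is EditClass.SUBSTITUTION:
        tail = classify_substitution_subtype(ref, alt)
        return TermPath(_CHAIN_HEAD + (SUBSTITUTION,) + tail.accessions)
    if cls is EditClass.DELETION:
        return TermPath(_CHAIN_HEAD + (DELETION,))
    if cls is EditClass.INSERTION:
        return TermPath(_CHAIN_HEAD + (INSERTION,))
    if cls is EditClass.INDEL:
        return TermPath(_CHAIN_HEAD + (INDEL,))
    if cls is EditClass.INVERSION:
        return TermPath(_CHAIN_HEAD + (TRANSLOCATION, INVERSION))
    if cls is EditClass.TRANSLOCATION:
        return TermPath(_CHAIN_HEAD + (TRANSLOCATION,))
    raise UnsupportedKindError(f"unsupported edit kind: {cls!r}")


# -- region model and affected level ------------------------------------------

REGION_LABELS = frozenset({"exon", "intron", "gene"})


@dataclass
class RegionModel:
    """Labeled genomic intervals (exon / intron / gene), 0-based half-open."""

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self):
        self._trees: dict[str, IntervalTree] = {}
        for seq, start, end, label in self.intervals:
            if label not in REGION_LABELS:
                raise ValueError(f"unknown region label {label!r}")
            if not start < end:
                raise ValueError(f"empty interval [{start}, {end}) on {seq}")
            self._trees.setdefault(seq, IntervalTree()).addi(start, end, label)

    @property
    def sequences(self) -> list[str]:
        return sorted(self._trees)

    def overlapping(self, sequence: str, hgvs_pos: int):
        """Intervals overlapping an HGVS 1-based position."""
        tree = self._trees.get(sequence)
        if tree is None:
            return []
        return sorted(tree.overlap(hgvs_pos - 1, hgvs_pos))

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionModel":
        """Read a 4-column BED file (chrom, start, end, label)."""
        intervals = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cells = line.split("\t")
            if len(cells) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs 4 columns (label in col 4)")
            intervals.append((cells[0], int(cells[1]), int(cells[2]), cells[3]))
        return cls(intervals)


_MITO_PATH = (ROOT_STRUCTURE, AFFECTED_LEVEL, EXTRACHROMOSOMAL, ORGANELLAR, MITOCHONDRIAL)
_LEVEL_HEAD = (ROOT_STRUCTURE, AFFECTED_LEVEL, CHAIN_AFFECTED)


def _resolve_sequence(regions: RegionModel, sequence: str | None) -> str | None:
    if sequence is not None:
        if regions.sequences and sequence not in regions.sequences:
            raise RegionLookupError(
                f"sequence {sequence!r} not in region model "
                f"(has {', '.join(regions.sequences) or 'none'})"
            )
        return sequence
    if len(regions.sequences) == 1:
        return regions.sequences[0]
    if not regions.sequences:
        return None
    raise RegionLookupError(
        "region model covers several sequences; a sequence name is required"
    )


def classify_affected_level(
    desc: HgvsDescription,
    regions: RegionModel | None = None,
    sequence: str | None = None,
) -> list[TermPath]:
    """Affected-DNA-level path(s) for one parsed description.

    Rules: an m. prefix maps to mitochondrial DNA affected; a c.
    coordinate is exonic unless it carries an intron offset (coding and
    UTR positions lie in exons); a g. position is located in the region
    model when one is supplied, falling back to the bare "DNA chain
    affected" term when nothing more specific can be said.
    """
    if desc.prefix == "m":
        return [TermPath(_MITO_PATH)]
    if desc.prefix == "c":
        offsets = [desc.start.intron_offset] + (
            [desc.end.intron_offset] if desc.end else []
        )
        leaf = IN_INTRON if any(offsets) else IN_EXON
        return [TermPath(_LEVEL_HEAD + (leaf,))]
    # g. prefix: locate the position in the region model
    return genomic_level_paths(desc.start.position, regions, sequence)


def genomic_level_paths(
    position: int,
    regions: RegionModel | None = None,
    sequence: str | None = None,
) -> list[TermPath]:
    """Affected-level path(s) for a genomic (1-based) position.

    With no region model, or none covering the sequence, only the bare
    "DNA chain affected" term is assignable; a position overlapping no
    interval on a covered sequence is intergenic.
    """
    if regions is None:
        return [TermPath(_LEVEL_HEAD)]
    seq = _resolve_sequence(regions, sequence)
    if seq is None or seq not in regions.sequences:
        # no intervals at all on this sequence: nothing more specific to say
        return [TermPath(_LEVEL_HEAD)]
    hits = regions.overlapping(seq, position)
    labels = {iv.data for iv in hits}
    if "exon" in labels and "intron" in labels:
        raise AmbiguityError(
            f"position {position} on {seq} overlaps both exon and "
            f"intron intervals",
            hits,
        )
    if "exon" in labels:
        return [TermPath(_LEVEL_HEAD + (IN_EXON,))]
    if "intron" in labels:
        return [TermPath(_LEVEL_HEAD + (IN_INTRON,))]
    if "gene" in labels:
        return [TermPath(_LEVEL_HEAD)]
    return [TermPath(_LEVEL_HEAD + (INTERGENIC,))]


# -- manual-term branch validation --------------------------------------------


@dataclass
class BranchValidationReport:
    """Outcome of checking manual accessions against one branch."""

    branch: str
    valid: list[int] = field(default_factory=list)
    violations: list[tuple[int, str]] = field(default_factory=list)
    redundant: list[int] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_branch_terms(
    accessions: list[int],
    branch: str,
    graph: OntologyGraph | None = None,
) -> BranchValidationReport:
    """Check that each accession is a strict descendant of the branch root.

    When two supplied terms are ancestor/descendant of each other the
    ancestor is flagged redundant (keep the most specific term).
    Unknown accessions raise :class:`~variodna.errors.NotFoundError`.
    """
    graph = graph or load_packaged_graph()
    if branch not in BRANCH_QUERY_ROOTS:
        raise ValueError(
            f"unknown branch {branch!r}; expected one of {sorted(BRANCH_QUERY_ROOTS)}"
        )
    root = BRANCH_QUERY_ROOTS[branch]
    report = BranchValidationReport(branch)
    for acc in accessions:
        graph.get_term(acc)  # raises NotFoundError
        if acc == root or not graph.is_a(acc, root):
            report.violations.append(
                (acc, f"not a strict descendant of branch root {root}")
            )
        else:
            report.valid.append(acc)
    for acc in report.valid:
        if any(
            other != acc and graph.is_a(other, acc) for other in report.valid
        ):
            report.redundant.append(acc)
    return report


def most_specific(accessions: list[int], graph: OntologyGraph) -> list[int]:
    """Drop accessions that are ancestors of other supplied accessions."""
    return sorted(
        a for a in set(accessions)
        if not any(b != a and graph.is_a(b, a) for b in set(accessions))
    )
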