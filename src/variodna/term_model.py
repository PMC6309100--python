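"""VariO DNA-branch term graph: loading, validation, traversal, labels.

The vocabulary covers DNA variation types (including their genetic or
non-genetic origin) and variations affecting DNA function, property and
structure.  Terms are keyed by numeric accessions and arranged in a
directed acyclic is_a graph with four branch roots:

=================  =========  ======================================
branch             root       meaning
=================  =========  ======================================
variation_type     VariO:0129 what kind of change occurred
function           VariO:0148 effect on a DNA function
property           VariO:0227 effect on a DNA property
structure          VariO:0155 effect on DNA structure / architecture
=================  =========  ======================================

The origin sub-branch (VariO:0127, under the variation-type root)
classifies variations by the process class that produced them and is
addressable as its own branch for validation purposes.

An annotation label is the two-part rendering ``VariO:NNNN name`` with
the accession zero-padded to four digits, e.g. ``VariO:0132 chromosomal
variation``.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from .errors import (
    ConflictError,
    CycleError,
    LabelConsistencyError,
    LabelSyntaxError,
    NotFoundError,
    StructuralError,
)

#: Branch-root accessions used for reachability validation.
BRANCH_ROOTS: dict[str, int] = {
    "variation_type": 129,
    "function": 148,
    "property": 227,
    "structure": 155,
}

#: Roots accepted by branch-membership queries; "origin" (127) lives under
#: the variation-type root, and "type" is a short alias.
BRANCH_QUERY_ROOTS: dict[str, int] = {
    **BRANCH_ROOTS,
    "type": 129,
    "origin": 127,
}

#: Terms documented as attached to no branch ("mutation" is a process term).
ISOLATED_ACCESSIONS: frozenset[int] = frozenset({139})

#: Accessions at or above this value are local sentinels for terms whose
#: official accession collides with another term (see the conflict ledger).
SENTINEL_FLOOR = 9000

_LABEL_RE = re.compile(r"^VariO:(\d{1,4}) (\S.*)$")


@dataclass(frozen=True)
class Term:
    """One VariO term."""

    accession: int
    name: str
    parents: tuple[int, ...]
    definition: str = ""
    branch: str | None = None

    def label(self) -> str:
        return format_label(self)


@dataclass(frozen=True)
class AnnotationLabel:
    """A parsed or rendered two-part annotation label."""

    accession: int
    name: str

    @property
    def rendered(self) -> str:
        return f"VariO:{self.accession:04d} {self.name}"

    @classmethod
    def from_term(cls, term: Term) -> "AnnotationLabel":
        return cls(term.accession, term.name)


@dataclass
class ValidationReport:
    """Outcome of structural validation of a term graph."""

    cycles: list[list[int]] = field(default_factory=list)
    unreachable: list[int] = field(default_factory=list)
    cross_branch: list[int] = field(default_factory=list)
    sentinels: list[int] = field(default_factory=list)
    branch_of: dict[int, str | None] = field(default_factory=dict)

    @property
    def defects(self) -> list[str]:
        out = []
        out += [f"cycle: {c}" for c in self.cycles]
        out += [f"unreachable: {a}" for a in self.unreachable]
        out += [f"cross-branch: {a}" for a in self.cross_branch]
        return out

    @property
    def ok(self) -> bool:
        return not self.defects


class OntologyGraph:
    """Validated directed acyclic is_a graph of VariO DNA terms.

    Edges in the underlying :class:`networkx.DiGraph` run parent -> child,
    so ``nx.descendants(g.nx, root)`` is the subtree below ``root``.
    """

    def __init__(self, terms: Iterable[Term]):
        self._terms: dict[int, Term] = {}
        self._by_name: dict[str, int] = {}
        g = nx.DiGraph()
        for t in terms:
            if t.accession in self._terms:
                other = self._terms[t.accession]
                raise ConflictError(
                    f"accession {t.accession} claimed by both "
                    f"{other.name!r} and {t.name!r}"
                )
            key = t.name.casefold()
            if key in self._by_name:
                raise StructuralError(
                    f"name {t.name!r} claimed by accessions "
                    f"{self._by_name[key]} and {t.accession}"
                )
            self._terms[t.accession] = t
            self._by_name[key] = t.accession
            g.add_node(t.accession)
        for t in self._terms.values():
            for p in t.parents:
                if p not in self._terms:
                    raise StructuralError(
                        f"term {t.accession} ({t.name!r}) has missing parent {p}"
                    )
                g.add_edge(p, t.accession)
        if not self._terms:
            raise StructuralError("empty term table: no branch roots found")
        if not nx.is_directed_acyclic_graph(g):
            raise CycleError(next(iter(nx.simple_cycles(g))))
        self.nx = g
        self._assign_branches()

    # -- construction helpers -------------------------------------------------

    def _assign_branches(self) -> None:
        branch_of: dict[int, str | None] = {}
        reach: dict[int, set[str]] = {a: set() for a in self._terms}
        for branch, root in BRANCH_ROOTS.items():
            if root not in self._terms:
                continue
            reach[root].add(branch)
            for a in nx.descendants(self.nx, root):
                reach[a].add(branch)
        origin_root = BRANCH_QUERY_ROOTS["origin"]
        origin = set()
        if origin_root in self._terms:
            origin = {origin_root} | nx.descendants(self.nx, origin_root)
        for a in self._terms:
            branches = reach[a]
            if len(branches) == 1:
                branch_of[a] = "origin" if a in origin else next(iter(branches))
            else:
                branch_of[a] = None  # unreachable or cross-branch; see validate()
        self._branch_of = branch_of
        self._reach = reach
        self._terms = {
            a: Term(t.accession, t.name, t.parents, t.definition, branch_of[a])
            for a, t in self._terms.items()
        }

    # -- lookup ---------------------------------------------------------------

    def __len__(self) -> int:
        return len(self._terms)

    def __contains__(self, accession: int) -> bool:
        return accession in self._terms

    def __iter__(self) -> Iterator[Term]:
        return iter(self._terms[a] for a in sorted(self._terms))

    @property
    def roots(self) -> dict[str, int]:
        return dict(BRANCH_ROOTS)

    def get_term(self, key: int | str) -> Term:
        """Look a term up by accession or (case-insensitive) exact name."""
        if isinstance(key, str) and not isinstance(key, bool):
            acc = self._by_name.get(key.casefold())
            if acc is None:
                raise NotFoundError(key)
            return self._terms[acc]
        if key in self._terms:
            return self._terms[key]
        raise NotFoundError(key)

    # -- traversal ------------------------------------------------------------

    def parents(self, accession: int) -> list[int]:
        return sorted(self.get_term(accession).parents)

    def children(self, accession: int) -> list[int]:
        self.get_term(accession)
        return sorted(self.nx.successors(accession))

    def ancestors(self, accession: int) -> list[int]:
        """All transitive ancestors, nearest first.

        Breadth-first by depth; within one depth level ties break by
        ascending accession.  The query term itself is excluded and each
        ancestor appears once, at its minimum depth.
        """
        self.get_term(accession)
        seen: set[int] = set()
        out: list[int] = []
        frontier = [accession]
        while frontier:
            level = sorted(
                {p for a in frontier for p in self.nx.predecessors(a)} - seen
            )
            out.extend(level)
            seen.update(level)
            frontier = level
        return out

    def descendants(self, accession: int) -> list[int]:
        self.get_term(accession)
        return sorted(nx.descendants(self.nx, accession))

    def is_a(self, accession: int, candidate_ancestor: int) -> bool:
        """Reflexive subsumption test: is ``accession`` a kind of the candidate?"""
        self.get_term(accession)
        self.get_term(candidate_ancestor)
        if accession == candidate_ancestor:
            return True
        return nx.has_path(self.nx, candidate_ancestor, accession)

    def branch(self, accession: int) -> str | None:
        return self.get_term(accession).branch

    # -- validation -----------------------------------------------------------

    def validate(self) -> ValidationReport:
        """Structural report: cycles, reachability, branch assignment.

        Cycles can never appear in a constructed graph (construction raises),
        but the report carries the field so external checks read uniformly.
        """
        report = ValidationReport()
        if not nx.is_directed_acyclic_graph(self.nx):  # pragma: no cover
            report.cycles = [list(c) for c in nx.simple_cycles(self.nx)]
        for a in sorted(self._terms):
            branches = self._reach[a]
            if len(branches) == 0 and a not in ISOLATED_ACCESSIONS:
                report.unreachable.append(a)
            elif len(branches) > 1:
                report.cross_branch.append(a)
            if a >= SENTINEL_FLOOR:
                report.sentinels.append(a)
        report.branch_of = dict(self._branch_of)
        return report

    # -- OBO interoperability -------------------------------------------------

    def to_obo(self) -> str:
        """Render the graph as OBO format text (id / name / def / is_a)."""
        lines = ["format-version: 1.2", "ontology: vario-dna", ""]
        for t in self:
            lines.append("[Term]")
            lines.append(f"id: VariO:{t.accession:04d}")
            lines.append(f"name: {t.name}")
            if t.definition:
                escaped = t.definition.replace("\\", "\\\\").replace('"', '\\"')
                lines.append(f'def: "{escaped}" []')
            for p in sorted(t.parents):
                lines.append(f"is_a: VariO:{p:04d} ! {self._terms[p].name}")
            lines.append("")
        return "\n".join(lines)

    def write_obo(self, path: str | Path) -> None:
        Path(path).write_text(self.to_obo(), encoding="utf-8")

    def diff_against_obo(self, path: str | Path) -> dict[str, list]:
        """Compare this graph with an externally supplied OBO file.

        Returns a report with accessions missing from either side, name
        mismatches, and is_a edges present in only one of the two; an
        all-empty report means the OBO file carries identical content.
        """
        import obonet

        other = obonet.read_obo(str(path))

        def acc(node_id: str) -> int:
            return int(node_id.rsplit(":", 1)[1])

        theirs = {acc(n): (data.get("name", "")) for n, data in other.nodes(data=True)}
        ours = {t.accession: t.name for t in self}
        their_edges = {
            (acc(u), acc(v))
            for u, v, k in other.edges(keys=True)
            if k == "is_a"
        }
        our_edges = {
            (t.accession, p) for t in self for p in t.parents
        }
        return {
            "missing_here": sorted(set(theirs) - set(ours)),
            "missing_there": sorted(set(ours) - set(theirs)),
            "name_mismatch": sorted(
                a for a in set(ours) & set(theirs)
                if ours[a].casefold() != theirs[a].casefold()
            ),
            "edges_only_here": sorted(our_edges - their_edges),
            "edges_only_there": sorted(their_edges - our_edges),
        }


# -- labels -------------------------------------------------------------------


def format_label(term: Term | AnnotationLabel) -> str:
    """Render the two-part label, accession zero-padded to four digits."""
    return f"VariO:{term.accession:04d} {term.name}"


def parse_label(text: str, graph: OntologyGraph) -> AnnotationLabel:
    """Parse ``VariO:NNNN name`` and check it against the graph.

    Unpadded accession digits are accepted; the rendered form is always
    padded.  The accession/name pair must match the graph exactly
    (name comparison is case-insensitive).
    """
    m = _LABEL_RE.match(text)
    if not m:
        raise LabelSyntaxError(f"not a 'VariO:NNNN name' label: {text!r}")
    accession = int(m.group(1))
    name = m.group(2).strip()
    try:
        term = graph.get_term(accession)
    except NotFoundError:
        raise LabelConsistencyError(f"unknown accession in label: {text!r}") from None
    if term.name.casefold() != name.casefold():
        raise LabelConsistencyError(
            f"label {text!r}: accession {accession} names {term.name!r}, "
            f"not {name!r}"
        )
    return AnnotationLabel(accession, term.name)


# -- loading ------------------------------------------------------------------


def _parse_parents(cell: str) -> tuple[int, ...]:
    cell = cell.strip()
    if cell in ("", "."):
        return ()
    return tuple(int(p) for p in cell.split(","))


def load_term_table(path: str | Path) -> OntologyGraph:
    """Load and validate a TSV term table.

    Format: UTF-8, header row, ``#`` comment lines, columns
    ``accession<TAB>name<TAB>parent_accessions<TAB>definition`` with
    parents comma-separated (``.`` or empty = none).
    """
    terms: list[Term] = []
    seen_at: dict[int, tuple[int, str]] = {}
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # header row is mandatory and skipped
                continue
            cells = line.split("\t")
            if len(cells) < 3:
                raise StructuralError(
                    f"line {lineno}: expected at least 3 tab-separated columns"
                )
            try:
                accession = int(cells[0])
            except ValueError:
                raise StructuralError(
                    f"line {lineno}: non-integer accession {cells[0]!r}"
                ) from None
            definition = cells[3].strip() if len(cells) > 3 else ""
            name = cells[1].strip()
            if accession in seen_at:
                prev_line, prev_name = seen_at[accession]
                raise ConflictError(
                    f"accession {accession} claimed by {prev_name!r} (line "
                    f"{prev_line}) and {name!r} (line {lineno})"
                )
            seen_at[accession] = (lineno, name)
            terms.append(Term(accession, name, _parse_parents(cells[2]), definition))
    return OntologyGraph(terms)


def _data_path(name: str) -> Path:
    return Path(resources.files("variodna") / "data" / name)


@lru_cache(maxsize=1)
def load_packaged_graph() -> OntologyGraph:
    """The term graph shipped with the package."""
    return load_term_table(_data_path("vario_dna_terms.tsv"))


def load_conflict_ledger() -> list[dict[str, str]]:
    """Accession-collision records shipped with the packaged table."""
    rows = []
    with open(_data_path("conflict_ledger.tsv"), encoding="utf-8") as fh:
        header = next(fh).rstrip("\n").split("\t")
        for line in fh:
            if line.strip():
                rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    return rows


def load_accession_checklist() -> list[int]:
    """Accessions that the packaged table is required to contain."""
    out = []
    for line in _data_path("accession_checklist.txt").read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(int(line))
    return out
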