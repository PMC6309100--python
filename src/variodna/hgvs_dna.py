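"""Parser and canonical renderer for the DNA subset of HGVS nomenclature.

Supported grammar (positions 1-based, bases A/C/G/T):

    prefix "." coord [ "_" coord ] edit
    prefix := g | c | m
    coord  := [- | *] digits [ (+|-) digits ]      # anchor/offset: c. only
    edit   := REF ">" ALT                          # substitution
            | "del" [bases]                        # deletion
            | "del" [bases] "ins" bases            # deletion-insertion (indel)
            | "ins" bases                          # insertion
            | "dup" [bases]                        # duplication
            | "inv"                                # inversion

Deviations from strict HGVS, kept deliberately: whitespace around ``>``
is tolerated on input (some sources print ``C > G``); a single-position
insertion such as ``g.101374623insT`` is accepted as a dialect and read
as insertion after that base.  IUPAC ambiguity codes are rejected: the
downstream classifiers are defined only on A/C/G/T.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum

from .errors import HgvsSyntaxError, NonVariationError

DNA_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def complement(bases: str) -> str:
    """Base-wise complement of an A/C/G/T string (not reversed)."""
    return bases.translate(_COMPLEMENT)


class UtrAnchor(str, Enum):
    """Anchor of a c. coordinate relative to the coding sequence."""

    NONE = "none"
    UPSTREAM = "upstream"      # 5' UTR, rendered "-"
    DOWNSTREAM = "downstream"  # 3' UTR, rendered "*"


class EditKind(str, Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"
    DELINS = "delins"
    DUPLICATION = "duplication"
    INVERSION = "inversion"


@dataclass(frozen=True, order=False)
class CoordRef:
    """One HGVS DNA coordinate.

    ``position`` is the unsigned printed number (>= 1); for an upstream
    anchor the biological position is ``-position``.  ``intron_offset``
    and ``utr_anchor`` are meaningful only with the c. prefix.
    """

    position: int
    intron_offset: int = 0
    utr_anchor: UtrAnchor = UtrAnchor.NONE

    def sort_key(self) -> tuple[int, int, int]:
        rank = {UtrAnchor.UPSTREAM: -1, UtrAnchor.NONE: 0, UtrAnchor.DOWNSTREAM: 1}
        signed = -self.position if self.utr_anchor is UtrAnchor.UPSTREAM else self.position
        return (rank[self.utr_anchor], signed, self.intron_offset)

    def render(self) -> str:
        anchor = {UtrAnchor.UPSTREAM: "-", UtrAnchor.DOWNSTREAM: "*", UtrAnchor.NONE: ""}
        offset = ""
        if self.intron_offset:
            offset = f"{self.intron_offset:+d}"
        return f"{anchor[self.utr_anchor]}{self.position}{offset}"


@dataclass(frozen=True)
class HgvsDescription:
    """Structured parse of one HGVS DNA variant description."""

    prefix: str
    start: CoordRef
    end: CoordRef | None
    edit_kind: EditKind
    ref_bases: str | None = None
    alt_bases: str | None = None
    raw: str = ""

    def canonical(self) -> "HgvsDescription":
        return replace(self, raw=to_string(self))


_COORD_RE = re.compile(r"([-*]?)(\d+)([+-]\d+)?")
_BASES_RE = re.compile(r"[A-Za-z]+")


class _Cursor:
    """Tracks the parse position so errors can point at a column."""

    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def fail(self, message: str) -> "HgvsSyntaxError":
        return HgvsSyntaxError(message, self.text, self.pos + 1)

    def match(self, pattern: re.Pattern) -> re.Match | None:
        m = pattern.match(self.text, self.pos)
        if m:
            self.pos = m.end()
        return m

    def literal(self, token: str) -> bool:
        if self.text.startswith(token, self.pos):
            self.pos += len(token)
            return True
        return False

    @property
    def rest(self) -> str:
        return self.text[self.pos:]


def _check_bases(bases: str, cursor: _Cursor, what: str) -> str:
    bases = bases.upper()
    for i, b in enumerate(bases):
        if b not in DNA_BASES:
            raise HgvsSyntaxError(
                f"non-DNA base {b!r} in {what}", cursor.text, cursor.pos - len(bases) + i + 1
            )
    return bases


def _parse_coord(cursor: _Cursor, prefix: str) -> CoordRef:
    m = cursor.match(_COORD_RE)
    if not m:
        raise cursor.fail("expected a coordinate")
    anchor_ch, digits, offset = m.group(1), m.group(2), m.group(3)
    anchor = {"": UtrAnchor.NONE, "-": UtrAnchor.UPSTREAM, "*": UtrAnchor.DOWNSTREAM}[anchor_ch]
    position = int(digits)
    if position < 1:
        raise cursor.fail("coordinate must be >= 1")
    intron_offset = int(offset) if offset else 0
    if prefix != "c" and (anchor is not UtrAnchor.NONE or intron_offset):
        raise cursor.fail(
            f"UTR anchors and intron offsets are valid only with the c. prefix, not {prefix}."
        )
    return CoordRef(position, intron_offset, anchor)


def parse_hgvs(text: str) -> HgvsDescription:
    """Parse one HGVS DNA description (g., c. or m. prefix).

    Raises :class:`~variodna.errors.HgvsSyntaxError` with a 1-based column
    position on malformed input, including the non-variation cases
    ``ref == alt``.
    """
    stripped = text.strip()
    cursor = _Cursor(stripped)
    if len(stripped) < 2 or stripped[1] != "." or stripped[0] not in "gcm":
        raise cursor.fail("expected prefix 'g.', 'c.' or 'm.'")
    prefix = stripped[0]
    cursor.pos = 2
    start = _parse_coord(cursor, prefix)
    end: CoordRef | None = None
    if cursor.literal("_"):
        end = _parse_coord(cursor, prefix)
        if end.sort_key() < start.sort_key():
            raise cursor.fail("interval end precedes start")

    rest = cursor.rest
    # keyword edits first: "del", "delins", "ins", "dup", "inv"
    if rest.startswith("delins") or rest.startswith("del"):
        cursor.pos += 3
        # deleted bases, if listed, stop where the "ins" keyword begins
        m = cursor.match(re.compile(r"(?:(?!ins)[A-Za-z])+"))
        deleted: str | None = None
        if m:
            deleted = _check_bases(m.group(0), cursor, "deleted bases")
        if cursor.literal("ins"):
            m = cursor.match(_BASES_RE)
            if not m:
                raise cursor.fail("empty insertion")
            inserted = _check_bases(m.group(0), cursor, "inserted bases")
            if cursor.rest:
                raise cursor.fail("trailing characters")
            if deleted is not None and deleted == inserted:
                raise cursor.fail("not a variation relative to reference (del == ins)")
            return HgvsDescription(prefix, start, end, EditKind.DELINS,
                                   deleted, inserted, stripped)
        if cursor.rest:
            raise cursor.fail("trailing characters")
        return HgvsDescription(prefix, start, end, EditKind.DELETION,
                               deleted, None, stripped)
    if rest.startswith("ins"):
        cursor.pos += 3
        m = cursor.match(_BASES_RE)
        if not m:
            raise cursor.fail("empty insertion")
        inserted = _check_bases(m.group(0), cursor, "inserted bases")
        if cursor.rest:
            raise cursor.fail("trailing characters")
        return HgvsDescription(prefix, start, end, EditKind.INSERTION,
                               None, inserted, stripped)
    if rest.startswith("dup"):
        cursor.pos += 3
        m = cursor.match(_BASES_RE)
        dupped = _check_bases(m.group(0), cursor, "duplicated bases") if m else None
        if cursor.rest:
            raise cursor.fail("trailing characters")
        return HgvsDescription(prefix, start, end, EditKind.DUPLICATION,
                               dupped, None, stripped)
    if rest.startswith("inv"):
        cursor.pos += 3
        if cursor.rest:
            raise cursor.fail("trailing characters")
        return HgvsDescription(prefix, start, end, EditKind.INVERSION,
                               None, None, stripped)

    # substitution: REF ">" ALT, whitespace around ">" tolerated
    m = re.match(r"([A-Za-z])\s*>\s*([A-Za-z])$", rest)
    if not m:
        raise cursor.fail("unrecognized edit")
    ref = _check_bases(m.group(1), cursor, "reference base")
    alt = _check_bases(m.group(2), cursor, "alternate base")
    if end is not None:
        raise cursor.fail("substitution takes a single position, not an interval")
    if ref == alt:
        raise HgvsSyntaxError(
            "not a variation: reference and alternate base are identical",
            stripped, cursor.pos + 1,
        )
    return HgvsDescription(prefix, start, None, EditKind.SUBSTITUTION,
                           ref, alt, stripped)


def to_string(desc: HgvsDescription) -> str:
    """Canonical rendering: no spaces, uppercase bases, padded offsets."""
    coords = desc.start.render()
    if desc.end is not None:
        coords += f"_{desc.end.render()}"
    k = desc.edit_kind
    if k is EditKind.SUBSTITUTION:
        edit = f"{desc.ref_bases}>{desc.alt_bases}"
    elif k is EditKind.DELETION:
        edit = f"del{desc.ref_bases or ''}"
    elif k is EditKind.INSERTION:
        edit = f"ins{desc.alt_bases}"
    elif k is EditKind.DELINS:
        edit = f"del{desc.ref_bases or ''}ins{desc.alt_bases}"
    elif k is EditKind.DUPLICATION:
        edit = f"dup{desc.ref_bases or ''}"
    else:
        edit = "inv"
    return f"{desc.prefix}.{coords}{edit}"


def read_hgvs_lines(lines) -> list[str]:
    """Strip and drop blank lines from an iterable of raw input lines."""
    return [ln.strip() for ln in lines if ln.strip()]
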