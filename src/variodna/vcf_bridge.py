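"""Read VCF records and turn each ALT allele into a normalized edit.

The bridge keeps only what classification needs: CHROM, POS, REF, ALT.
Sequence alleles are reduced to a minimal edit by trimming the longest
shared prefix and then the longest shared suffix of REF/ALT (prefix
first, deterministically); symbolic alleles <DEL>, <INS>, <DUP>, <INV>
and breakend notation map straight to edit categories.  Genotypes,
INFO and FORMAT are ignored; the raw header is kept for passthrough.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pysam

from .classify import EditClass, NormalizedEdit
from .errors import (
    DomainError,
    NonVariationError,
    UnsupportedKindError,
    VcfFormatError,
    VcfRecordError,
)
from .hgvs_dna import DNA_BASES

_SYMBOLIC = {
    "<DEL>": EditClass.DELETION,
    "<INS>": EditClass.INSERTION,
    "<DUP>": EditClass.INSERTION,  # duplication inserts bases vs. reference
    "<INV>": EditClass.INVERSION,
}

#: Placeholder for bases a symbolic allele leaves unspecified.
UNKNOWN_BASES = "N"


@dataclass(frozen=True)
class VcfRecord:
    """One VCF data line reduced to its locus and alleles."""

    chrom: str
    pos: int  # 1-based, per VCF
    ref: str
    alts: tuple[str, ...]

    def locus(self) -> str:
        return f"{self.chrom}:{self.pos}"


class VcfReader:
    """Iterate :class:`VcfRecord` from a VCF v4.x file (plain or gzip).

    ``header_text`` preserves the original header for passthrough.
    """

    def __init__(self, path: str | Path):
        self.path = str(path)
        try:
            self._vf = pysam.VariantFile(_materialize(self.path))
        except (ValueError, OSError) as exc:
            raise VcfFormatError(f"{self.path}: not a readable VCF: {exc}") from exc
        self.header_text = str(self._vf.header)
        self._header_lines = self.header_text.count("\n")

    def __iter__(self) -> Iterator[VcfRecord]:
        yielded = 0
        try:
            for rec in self._vf:
                alts = tuple(a for a in (rec.alts or ()) if a is not None)
                yield VcfRecord(rec.chrom, rec.pos, rec.ref, alts)
                yielded += 1
        except (OSError, ValueError) as exc:
            raise VcfRecordError(
                f"{self.path}: unparseable record: {exc}",
                line=self._header_lines + yielded + 1,
            ) from exc


def _materialize(path: str) -> str:
    """Give htslib a file it can seek: plain-gzip input (not BGZF) is
    decompressed to a temporary file first."""
    with open(path, "rb") as fh:
        head = fh.read(18)
    if head[:2] != b"\x1f\x8b":
        return path
    # BGZF marks itself with an FEXTRA 'BC' subfield
    if len(head) >= 14 and head[3] & 4 and head[12:14] == b"BC":
        return path
    import gzip
    import tempfile

    tmp = tempfile.NamedTemporaryFile("wb", suffix=".vcf", delete=False)
    with gzip.open(path, "rb") as src:
        tmp.write(src.read())
    tmp.close()
    return tmp.name


def read_vcf(path: str | Path) -> VcfReader:
    """Open a VCF file for record streaming."""
    return VcfReader(path)


def _check_sequence_allele(allele: str, role: str) -> str:
    allele = allele.upper()
    bad = set(allele) - DNA_BASES
    if bad:
        raise DomainError(f"non-ACGT base(s) {sorted(bad)} in {role} allele {allele!r}")
    return allele


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Shared-affix trimming: longest common prefix first, then suffix.

    Returns ``(position of first differing base, trimmed ref, trimmed alt)``.
    """
    p = 0
    while p < min(len(ref), len(alt)) and ref[p] == alt[p]:
        p += 1
    r, a = ref[p:], alt[p:]
    s = 0
    while s < min(len(r), len(a)) and r[len(r) - 1 - s] == a[len(a) - 1 - s]:
        s += 1
    if s:
        r, a = r[:-s], a[:-s]
    return pos + p, r, a


def allele_to_edit(pos: int, ref: str, alt: str) -> NormalizedEdit:
    """Convert one REF/ALT allele pair into a :class:`NormalizedEdit`.

    Raises :class:`~variodna.errors.NonVariationError` when REF equals
    ALT after trimming and :class:`~variodna.errors.UnsupportedKindError`
    for symbolic alleles outside <DEL>/<INS>/<DUP>/<INV> and breakends.
    """
    if alt.startswith("<"):
        cls = _SYMBOLIC.get(alt.upper())
        if cls is None:
            raise UnsupportedKindError(f"unsupported symbolic allele {alt!r}")
        if cls is EditClass.DELETION:
            return NormalizedEdit(cls, pos, ref=UNKNOWN_BASES)
        if cls is EditClass.INSERTION:
            return NormalizedEdit(cls, pos, alt=UNKNOWN_BASES)
        return NormalizedEdit(cls, pos)
    if "[" in alt or "]" in alt or alt.startswith(".") or alt.endswith("."):
        # breakend notation; pairs are not joined, each end is a translocation
        return NormalizedEdit(EditClass.TRANSLOCATION, pos)

    ref = _check_sequence_allele(ref, "REF")
    alt = _check_sequence_allele(alt, "ALT")
    tpos, r, a = trim_alleles(pos, ref, alt)
    if not r and not a:
        raise NonVariationError(f"REF and ALT are identical at {pos}: {ref!r}")
    if len(r) == 1 and len(a) == 1:
        return NormalizedEdit(EditClass.SUBSTITUTION, tpos, ref=r, alt=a)
    if not a:
        return NormalizedEdit(EditClass.DELETION, tpos, ref=r)
    if not r:
        # insertion recorded after the last shared base
        return NormalizedEdit(EditClass.INSERTION, tpos - 1, alt=a)
    return NormalizedEdit(EditClass.INDEL, tpos, ref=r, alt=a)


def record_to_edits(record: VcfRecord) -> list[tuple[str, NormalizedEdit]]:
    """One edit per ALT allele, in ALT order."""
    return [(alt, allele_to_edit(record.pos, record.ref, alt)) for alt in record.alts]
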