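"""Synthetic, fully labeled test corpora with truth known by construction.

The generator emits HGVS descriptions (plus VCF equivalents for the
genomic ones), a labeled region model over a toy reference sequence,
and a truth table assigning each case its expected deepest
variation-type accession and affected-level accession.  Truth comes
from the generation recipe — which kind of edit was built where —
never from the classifiers under test, so corpus agreement is a real
check and not a tautology.

All sampling flows through one seeded :class:`numpy.random.Generator`;
identical ``(seed, n, reference)`` inputs give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classify import RegionModel
from .errors import ParameterError

BASES = "ACGT"

#: All 12 ordered substitution pairs, row-major over (ref, alt).
ORDERED_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (r, a) for r in BASES for a in BASES if r != a
)

#: Edit kinds the generator stratifies over.
KINDS = ("substitution", "deletion", "insertion", "delins", "dup", "inversion")

#: Deepest type accession per non-substitution kind.
_KIND_TRUTH = {"deletion": 141, "insertion": 142, "delins": 143,
               "dup": 142, "inversion": 145}

_TRANSITIONS = {("A", "G"): 315, ("G", "A"): 315, ("C", "T"): 314, ("T", "C"): 314}

#: Five fixed cases taken from published XLA / BTK variant reports.
FIXED_CASES: tuple[tuple[str, int, tuple[int, ...]], ...] = (
    ("g.101362620C>G", 316, (160,)),
    ("c.82C>T", 314, (162,)),
    ("c.1684_1685delinsT", 143, (162,)),
    ("g.101374535del", 141, (160,)),
    ("g.101374623insT", 142, (160,)),
)

SEQUENCE_NAME = "toy"


@dataclass(frozen=True)
class FixtureCase:
    """One labeled corpus entry."""

    case_id: str
    hgvs: str
    expected_type: int             # deepest variation-type accession
    expected_level: tuple[int, ...]  # deepest affected-level accession(s)
    recipe: str                    # generation recipe tag
    with_regions: bool             # classify the level against the bundled model?
    vcf: tuple[str, int, str, str] | None = None  # chrom, pos, ref, alt


def make_toy_reference(seed: int, length: int) -> str:
    """Deterministic uniform-composition reference of at least 100 bases."""
    if length < 100:
        raise ParameterError(f"reference length must be >= 100, got {length}")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(BASES), size=length))


def make_region_model(length: int) -> RegionModel:
    """Fixed region layout over a toy reference (0-based half-open).

    One gene occupies [0.1L, 0.6L): alternating exon/intron blocks with a
    short unlabeled (gene-only) stretch at its end; everything outside is
    intergenic.  The layout depends only on the length, so a corpus and
    its region model stay in register.
    """
    g0, g1 = length // 10, (6 * length) // 10
    block = max((g1 - g0) // 8, 20)
    intervals = [(SEQUENCE_NAME, g0, g1, "gene")]
    pos = g0
    labels = ["exon", "intron"]
    i = 0
    while pos + block <= g1 - block:  # leave the gene tail unlabeled
        intervals.append((SEQUENCE_NAME, pos, pos + block, labels[i % 2]))
        pos += block
        i += 1
    return RegionModel(intervals)


def _interval_positions(model: RegionModel, length: int) -> dict[str, list[int]]:
    """1-based positions per level stratum, from the model layout."""
    strata: dict[str, list[int]] = {"exon": [], "intron": [], "gene": [], "intergenic": []}
    for p in range(2, length):  # keep 1 base of margin at both ends
        hits = {iv.data for iv in model.overlapping(SEQUENCE_NAME, p)}
        if "exon" in hits:
            strata["exon"].append(p)
        elif "intron" in hits:
            strata["intron"].append(p)
        elif "gene" in hits:
            strata["gene"].append(p)
        else:
            strata["intergenic"].append(p)
    return strata


_LEVEL_TRUTH = {"exon": (162,), "intron": (161,), "gene": (160,), "intergenic": (163,)}
_LEVEL_CYCLE = ("exon", "intron", "intergenic", "gene")


def generate_fixture_set(
    seed: int,
    n: int,
    reference: str,
    kinds: tuple[str, ...] = KINDS,
) -> list[FixtureCase]:
    """Generate ``n`` labeled cases plus the five fixed published ones.

    Stratification cycles the requested ``kinds``; substitution cases
    additionally cycle the 12 ordered base pairs and the g/c/m prefixes,
    and genomic cases cycle the exon/intron/intergenic/gene-only strata
    of the bundled region model.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    unknown = set(kinds) - set(KINDS)
    if unknown:
        raise ParameterError(f"unknown kinds: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    length = len(reference)
    model = make_region_model(length)
    strata = _interval_positions(model, length)
    by_base: dict[str, dict[str, list[int]]] = {
        s: {b: [p for p in ps if reference[p - 1] == b] for b in BASES}
        for s, ps in strata.items()
    }

    cases: list[FixtureCase] = []
    pair_i = 0
    sub_prefix_i = 0
    level_i = 0

    def sample(positions: list[int]) -> int:
        return int(positions[rng.integers(len(positions))])

    for i in range(n):
        kind = kinds[i % len(kinds)]
        cid = f"case{i + 1:04d}"
        if kind == "substitution":
            ref_b, alt_b = ORDERED_PAIRS[pair_i % len(ORDERED_PAIRS)]
            pair_i += 1
            expected = _TRANSITIONS.get((ref_b, alt_b), 316)
            prefix = "gcm"[sub_prefix_i % 3]
            sub_prefix_i += 1
            if prefix == "g":
                stratum = _LEVEL_CYCLE[level_i % 4]
                level_i += 1
                pool = by_base[stratum][ref_b]
                if not pool:  # tiny references: fall back to any stratum with the base
                    stratum = next(s for s in _LEVEL_CYCLE if by_base[s][ref_b])
                    pool = by_base[stratum][ref_b]
                pos = sample(pool)
                truth_level = _LEVEL_TRUTH[stratum]
                cases.append(FixtureCase(
                    cid, f"g.{pos}{ref_b}>{alt_b}", expected, truth_level,
                    f"sub:{ref_b}>{alt_b}:g:{stratum}", True,
                    (SEQUENCE_NAME, pos, ref_b, alt_b),
                ))
            elif prefix == "c":
                pos = int(rng.integers(1, 2000))
                if rng.integers(2):  # intronic coordinate
                    off = int(rng.integers(1, 50)) * (1 if rng.integers(2) else -1)
                    hgvs = f"c.{pos}{off:+d}{ref_b}>{alt_b}"
                    level = (161,)
                else:
                    hgvs = f"c.{pos}{ref_b}>{alt_b}"
                    level = (162,)
                cases.append(FixtureCase(
                    cid, hgvs, expected, level, f"sub:{ref_b}>{alt_b}:c", False,
                ))
            else:
                pos = int(rng.integers(1, 16569))  # within a mitochondrial genome
                cases.append(FixtureCase(
                    cid, f"m.{pos}{ref_b}>{alt_b}", expected, (450,),
                    f"sub:{ref_b}>{alt_b}:m", False,
                ))
            continue

        # all remaining kinds are genomic, with a VCF equivalent
        stratum = _LEVEL_CYCLE[level_i % 4]
        level_i += 1
        truth_level = _LEVEL_TRUTH[stratum]
        pool = strata[stratum]
        if kind == "deletion":
            pos = sample(pool)
            span = int(rng.integers(1, 6))
            span = min(span, length - pos)  # stay inside the reference
            seg = reference[pos - 1: pos - 1 + span]
            hgvs = f"g.{pos}del" if span == 1 else f"g.{pos}_{pos + span - 1}del"
            anchor = reference[pos - 2]
            vcf = (SEQUENCE_NAME, pos - 1, anchor + seg, anchor)
            cases.append(FixtureCase(cid, hgvs, 141, truth_level,
                                     f"del:{span}:{stratum}", True, vcf))
        elif kind == "insertion":
            pos = sample(pool)
            ins = "".join(rng.choice(list(BASES), size=int(rng.integers(1, 6))))
            hgvs = f"g.{pos}_{pos + 1}ins{ins}"
            base = reference[pos - 1]
            vcf = (SEQUENCE_NAME, pos, base, base + ins)
            cases.append(FixtureCase(cid, hgvs, 142, truth_level,
                                     f"ins:{len(ins)}:{stratum}", True, vcf))
        elif kind == "delins":
            pos = sample(pool)
            d = int(rng.integers(1, 4))
            d = min(d, length - pos)
            seg = reference[pos - 1: pos - 1 + d]
            ins = _delins_alt(rng, seg)
            hgvs = (f"g.{pos}delins{ins}" if d == 1
                    else f"g.{pos}_{pos + d - 1}delins{ins}")
            vcf = (SEQUENCE_NAME, pos, seg, ins)
            cases.append(FixtureCase(cid, hgvs, 143, truth_level,
                                     f"delins:{d}>{len(ins)}:{stratum}", True, vcf))
        elif kind == "dup":
            pos = sample(pool)
            span = int(rng.integers(1, 4))
            span = min(span, length - pos)
            end = pos + span - 1
            seg = reference[pos - 1: end]
            hgvs = f"g.{pos}dup" if span == 1 else f"g.{pos}_{end}dup"
            base = reference[end - 1]
            vcf = (SEQUENCE_NAME, end, base, base + reference[pos - 1: end])
            cases.append(FixtureCase(cid, hgvs, 142, truth_level,
                                     f"dup:{span}:{stratum}", True, vcf))
        else:  # inversion
            pos = sample(pool)
            span = int(rng.integers(2, 7))
            span = min(span, length - pos + 1)  # >= 2 since pos <= length - 1
            end = pos + span - 1
            hgvs = f"g.{pos}_{end}inv"
            vcf = (SEQUENCE_NAME, pos, reference[pos - 1], "<INV>")
            cases.append(FixtureCase(cid, hgvs, 145, truth_level,
                                     f"inv:{span}:{stratum}", True, vcf))

    for j, (hgvs, t, lvl) in enumerate(FIXED_CASES, start=1):
        cases.append(FixtureCase(f"fixed{j:02d}", hgvs, t, lvl, "fixed", False))
    return cases


def _delins_alt(rng, seg: str) -> str:
    """Inserted bases for a delins that survive VCF affix trimming as an indel."""
    d = len(seg)
    i = int(rng.integers(1, 4))
    if d == 1 and i == 1:
        i = 2
    while True:
        ins = "".join(rng.choice(list(BASES), size=i))
        if ins != seg and ins[0] != seg[0] and ins[-1] != seg[-1]:
            return ins


# -- file emission -------------------------------------------------------------


def write_fixture_set(
    cases: list[FixtureCase],
    outdir: str | Path,
    reference: str,
) -> dict[str, Path]:
    """Write fixtures.hgvs, fixtures.vcf, regions.bed and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hgvs": outdir / "fixtures.hgvs",
        "vcf": outdir / "fixtures.vcf",
        "bed": outdir / "regions.bed",
        "truth": outdir / "truth.tsv",
    }
    paths["hgvs"].write_text("".join(c.hgvs + "\n" for c in cases), encoding="utf-8")

    vcf_lines = [
        "##fileformat=VCFv4.3",
        f"##contig=<ID={SEQUENCE_NAME},length={len(reference)}>",
        '##ALT=<ID=INV,Description="Inversion">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in cases:
        if c.vcf is not None:
            chrom, pos, ref, alt = c.vcf
            vcf_lines.append(f"{chrom}\t{pos}\t{c.case_id}\t{ref}\t{alt}\t.\t.\t.")
    paths["vcf"].write_text("\n".join(vcf_lines) + "\n", encoding="utf-8")

    model = make_region_model(len(reference))
    bed = "".join(
        f"{seq}\t{start}\t{end}\t{label}\n"
        for seq, start, end, label in sorted(model.intervals, key=lambda t: (t[1], t[2]))
    )
    paths["bed"].write_text(bed, encoding="utf-8")

    rows = ["case_id\thgvs\texpected_type\texpected_level\twith_regions\trecipe"]
    for c in cases:
        lvl = ",".join(str(a) for a in c.expected_level)
        rows.append(
            f"{c.case_id}\t{c.hgvs}\t{c.expected_type}\t{lvl}\t"
            f"{int(c.with_regions)}\t{c.recipe}"
        )
    paths["truth"].write_text("\n".join(rows) + "\n", encoding="utf-8")
    return paths
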