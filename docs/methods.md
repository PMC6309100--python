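# Methods

## The term graph

The packaged vocabulary covers the DNA branch of the Variation Ontology:
138 terms in a directed acyclic `is_a` graph rooted at four branch roots —
DNA variation type (`0129`), variation affecting DNA function (`0148`),
variation affecting DNA property (`0227`) and variation affecting DNA
structure (`0155`). The origin sub-branch (`0127`, two children: genetic
`0130` and non-genetic `0146`) sits under the type root but is addressable
as its own branch for validation. The graph is a DAG, not a tree: two
terms carry two parents each, both within the structure branch —
nucleosome positioning (`0158`, under chromatin structure variation `0226`
and epigenetic DNA modification `0156`) and copy number variation (`0187`,
under chromosomal amplification `0183` and chromosomal deletion `0193`,
since a CNV can be either).

Transcription policy. The table was transcribed from the published
description of the vocabulary. Where the source states parentage in an
explicit sentence ("DNA substitutions are either transitions or
transversions") that sentence is encoded directly; where it does not,
parentage follows the section nesting and figure captions (e.g.
heterodisomy and isodisomy under uniparental disomy; dicentric,
reciprocal and Robertsonian translocations under interchromosomal
translocation; chromosomal inversion under intrachromosomal
translocation). A committed checklist file lists every accession the
transcription must contain, and a test enforces it.

Two accessions are printed in the source for two different terms each:
`0391` (plasmid affected / genome affected) and `0455` (effect on single
stranded DNA structure / effect on A-motif). The official accession is
kept for the term defined in its own dedicated sentence; the displaced
term is stored under a local sentinel accession (`9001`, `9002`, i.e. at
or above 9000) so that no official-looking accession is fabricated. The
shipped conflict ledger (`data/conflict_ledger.tsv`) records both
collisions, and graph validation checks that sentinels and ledger match.
"Mutation" (`0139`, *any process generating variation*) is a process
term attached to no branch; it is packaged as a documented isolated term
and excluded from reachability checks.

Validation requires: no cycles (construction refuses cyclic tables), every
non-isolated term reachable from exactly one branch root, unique names,
unique accessions (duplicates abort loading with both claiming lines
named). Ordered outputs (children, ancestors-by-depth, descendants) break
ties by ascending accession for determinism. Labels render as
`VariO:` + zero-padded 4-digit accession + space + name; parsing accepts
unpadded digits but always re-renders padded, and rejects accession/name
pairs that disagree with the graph.

Interoperability: the graph exports to OBO format, and
`OntologyGraph.diff_against_obo` compares the packaged content against an
externally supplied OBO release (missing accessions, name mismatches,
edge differences) without any live download.

## HGVS parsing

The parser covers the DNA subset used in annotation workflows: prefixes
`g.`, `c.`, `m.`; one coordinate or an interval; edits `REF>ALT`, `del`,
`ins`, `delins` (with optionally listed deleted bases), `dup`, `inv`.
Coordinates are 1-based; `c.` coordinates may carry an intron offset
(`c.123+5`) or a UTR anchor (`c.-12`, `c.*45`). Two deliberate dialect
choices: whitespace around `>` is normalized away (published text often
prints `C > G`), and a single-position insertion (`g.101374623insT`) is
accepted and read as insertion after that base, because real LSDB entries
use the form. IUPAC ambiguity codes are rejected at parse time — the
classification rules are defined only on A/C/G/T. Identity edits
(`g.12A>A`, `delACinsAC`) are rejected as non-variations, since
annotations are always made relative to a reference state. Rendering is
canonical (no spaces, uppercase bases) and parse∘render is the identity
on canonical forms; syntax errors carry a 1-based column.

## Classification rules

**Variation type.** Every edit maps to a path
`0129 → 0322 → 0135 → category`: deletion `0141`, insertion `0142`, indel
`0143` (any `delins`, including same-length replacements — HGVS has no
multi-base `>`), substitution `0136`, inversion `0144 → 0145`.
Duplications map to insertion `0142` (the five chain categories contain
no duplication term; a duplication inserts bases relative to the
reference) and the record carries a `dup_as_insertion` flag. Bare
translocations (`0144`) arise only from VCF breakends; there is no HGVS
translocation syntax in scope. Substitutions continue into the subtype:
transition `0313` with purine (`0315`: A↔G) or pyrimidine (`0314`: C↔T)
leaf, or transversion `0316`. Of the 12 ordered base pairs, 4 are
transitions and 8 transversions; transition status is invariant under
strand complementation while the purine/pyrimidine leaves swap.

**Affected level.** Only location-derivable structure terms are inferred,
all under `0155 → 0159`: an `m.` prefix gives
`0072 → 0448 → 0450` (mitochondrial DNA affected); a `c.` coordinate is
exonic (`0162`) unless it has a nonzero intron offset (`0161`) — coding
and UTR positions lie in exons; a `g.` position is located in an optional
region model of labeled BED intervals (exon → `0162`, intron → `0161`,
inside a gene but unlabeled → `0160` only, overlapping nothing on a
covered sequence → intergenic `0163`). With no region model, or none
covering the sequence, only the generic `0160` is assignable —
intergenicity is asserted only when gene intervals exist to be missed. A
position overlapping both exon- and intron-labeled intervals is an
ambiguity error listing the intervals. Region coordinates are 0-based
half-open internally (HGVS position p ↔ interval [p−1, p)).

**Everything else** — origin, function, property, chromosomal/chromatin
structure vocabulary — reflects experimental knowledge (ECO-documented)
and is never inferred from sequence. Supplied accessions are validated as
strict descendants of their branch root, and when two supplied terms are
ancestor/descendant of each other the ancestor is flagged redundant
(most-specific policy). Emitters print leaf-only labels by default with a
full-path option.

## VCF bridge

Reading goes through pysam (plain, BGZF, or plain-gzip text, the latter
transparently decompressed first). Each ALT allele is reduced
independently: trim the longest shared prefix, then the longest shared
suffix (prefix-first is fixed for determinism; full left-alignment
against a reference is out of scope), then classify by remaining lengths.
The trimmed position is the first differing base; insertions record the
base after which the sequence is inserted. Symbolic `<DEL>/<INS>/<DUP>`
map to deletion/insertion/insertion (mirroring the dup decision), `<INV>`
to inversion, `<CNV>` is rejected (chromosomal amplification terms are
manual vocabulary), and each breakend allele independently yields a
translocation without joining mates. Multi-allelic records yield one edit
per ALT. Genotypes, INFO and FORMAT are ignored; the header is preserved
for passthrough.

## Synthetic corpus

The generator emulates an LSDB-style stream of small variants on a toy
reference (default 10 000 bp, uniform base composition, seeded). Cases
are stratified by cycling the six edit kinds; substitution cases
additionally cycle the 12 ordered base pairs and the `g.`/`c.`/`m.`
prefixes, and genomic cases cycle the exon/intron/intergenic/gene-only
strata of a fixed region layout (one gene in [0.1 L, 0.6 L) with
alternating exon/intron blocks and an unlabeled tail). Expected terms are
assigned by the recipe at generation time — never by the classifiers —
so corpus agreement is an end-to-end check, not a tautology. Genomic
cases carry VCF equivalents built from the actual reference bases
(inversions as symbolic `<INV>`, since a sequence-allele inversion would
re-trim into an indel); `c.`/`m.` cases are HGVS-only because VCF has no
transcript or unplaced coordinates. Five fixed published example
descriptions are appended to every set. Delins recipes constrain the
inserted bases to share no affix with the deleted ones so the HGVS and
VCF forms normalize to the same indel.

What this does and does not show: the corpus exercises parsing,
normalization, typing and location logic exhaustively, but its variants
are uniform and independent — it does not emulate mutational spectra
(e.g. transition bias, CpG effects), overlapping gene architecture,
multi-sample VCFs, or chromosomal-scale events beyond symbolic stubs, so
passing says nothing about those.

Default sizes: the standard corpus is seed 7 with n = 1000 generated
cases (+5 fixed) on the seed-1 reference of 10 000 bp, large enough that
every reachable variation-type leaf and level stratum occurs tens of
times while the full suite runs in seconds.

## Numerical and degenerate-input choices

All randomness flows through one `numpy` Generator per operation,
seeded explicitly; outputs are byte-reproducible. Empty term tables,
empty annotation streams and empty region models are valid degenerate
inputs (structural error, empty output, and generic-level fallback
respectively). Failed records in a stream become error rows — output row
count always equals input count. ECO evidence codes are carried as opaque
`ECO:NNNNNNN` strings, idempotently appended.

## Known limitations

No transcript model: `c.` coordinates are never projected to genomic
space, so region models apply only to `g.` input. No reference-sequence
validation of stated HGVS bases. No ISCN karyotype parsing; chromosomal
and chromatin terms are manual vocabulary. The packaged table is a
transcription, not a synchronized copy of the hosted ontology release —
the OBO diff exists precisely to audit that gap.
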