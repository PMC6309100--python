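# variodna

The DNA branch of the **Variation Ontology (VariO)** as a validated term
graph, plus an automatic annotator that classifies DNA variants — given as
HGVS descriptions or VCF records — into VariO variation-type and
affected-DNA-level terms.

## Who this is for

Curators of locus-specific variation databases (LOVD-style LSDBs) and
bioinformaticians who need *systematic, machine-readable* descriptions of
DNA variants rather than free text. VariO describes the **outcome** of a
variation relative to a reference state at four sublevels — variation type,
effect on DNA function, effect on DNA structure, and DNA properties — with
terms keyed by numeric accessions and rendered as two-part labels:

```
VariO:0132 chromosomal variation
└────┬───┘ └────────┬──────────┘
 zero-padded        term name (derivable from the number)
 accession
```

## What the package contains

* **`term_model`** — the packaged DNA term table (138 terms) as a directed
  acyclic `is_a` graph with four branch roots (variation type `0129`,
  function `0148`, property `0227`, structure `0155`), validated for
  cycles, reachability and accession conflicts; ancestor/descendant
  traversal; label formatting/parsing; OBO export and diff against an
  external OBO release.
* **`hgvs_dna`** — a parser and canonical renderer for the DNA subset of
  HGVS nomenclature (`g.`/`c.`/`m.` prefixes; substitution, del, ins,
  delins, dup, inv; intron offsets and UTR anchors on `c.` coordinates).
* **`classify`** — the classification rules. Substitutions partition into
  **transitions** (within purines A↔G → `VariO:0315`, within pyrimidines
  C↔T → `VariO:0314`, both under `VariO:0313`) and **transversions**
  (purine↔pyrimidine, `VariO:0316`, 8 of the 12 ordered base pairs). The
  five DNA chain variation categories under `VariO:0135` are deletion
  `0141`, insertion `0142`, indel `0143`, substitution `0136` and
  translocation `0144` (inversion `0145` nests under translocation).
  Affected-DNA-level terms (`0159` subtree) come from the HGVS prefix and
  an optional BED region model (exon `0162` / intron `0161` / intergenic
  `0163` / mitochondrial `0450`). Origin, function, property and other
  structure terms are never inferred — only branch-validated.
* **`vcf_bridge`** — VCF v4.x input via pysam; each ALT allele is reduced
  to a minimal edit by shared prefix-then-suffix trimming; symbolic
  `<DEL>/<INS>/<DUP>/<INV>` and breakend alleles map to edit categories.
* **`annotate`** — per-variant records grouped by branch, ECO evidence
  codes, TSV/JSON writers and readers (LOVD column preset available), and
  the `variodna` CLI.
* **`fixtures`** — a seeded generator of labeled synthetic corpora (HGVS +
  VCF + BED + truth table) whose expected terms are fixed by the
  generation recipe, independent of the classifiers.

## Worked example

```python
import variodna as v

for record in v.annotate_stream(["g.101362620C>G", "c.82C>T", "m.100A>G"]):
    print(record.variant,
          record.labels["type"][-1].rendered, "|",
          record.labels["level"][-1].rendered)
```

prints

```
g.101362620C>G VariO:0316 transversion | VariO:0160 DNA chain affected
c.82C>T VariO:0314 pyrimidine transition | VariO:0162 variation in exon
m.100A>G VariO:0315 purine transition | VariO:0450 mitochondrial DNA affected
```

The C>G exchange swaps a pyrimidine for a purine, hence *transversion*;
C>T stays within the pyrimidines, hence *pyrimidine transition*; a
coding-DNA coordinate without an intron offset lies in an exon; the `m.`
prefix pins the variant to mitochondrial DNA. See `examples/` for
narrative scripts covering graph traversal, VCF annotation with a region
model, and the synthetic corpus.

Command-line equivalents:

```sh
variodna term --id 136 --children
variodna annotate --hgvs variants.txt --regions regions.bed --format tsv
variodna annotate --vcf calls.vcf --out annotated.json --format json
variodna validate-graph
variodna fixtures --seed 7 --n 1000 --out fixtures/
```

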