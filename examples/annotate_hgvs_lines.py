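"""Annotate a handful of HGVS DNA descriptions with VariO terms.

Runs the automatic classifiers on five published BTK-gene variants plus
a mitochondrial substitution and prints one line per variant: the
variation-type label (deepest term) and the affected-DNA-level label.
"""

import variodna as v

variants = [
    "g.101362620C>G",      # G-to-C exchange (reported on the opposite strand)
    "c.82C>T",             # coding substitution
    "c.1684_1685delinsT",  # C replaced by TG, written as a delins
    "g.101374535del",      # single-base deletion in an intron region
    "g.101374623insT",     # single-base insertion (single-position dialect)
    "m.100A>G",            # mitochondrial substitution
]

for record in v.annotate_stream(variants):
    type_label = record.labels["type"][-1].rendered
    level_label = record.labels["level"][-1].rendered
    print(f"{record.variant:22s} type: {type_label:32s} level: {level_label}")

# The type column is the deepest variation-type term the sequence change
# itself determines (e.g. transversion for C>G); the level column says what
# kind of DNA region the variant sits in, judged from the HGVS prefix alone
# here (c. coordinates without an intron offset lie in exons; m. means
# mitochondrial DNA; bare g. allows only the generic "DNA chain affected").
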