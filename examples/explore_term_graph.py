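"""Walk the packaged VariO DNA term graph.

Shows lookups by accession and name, ancestor chains, direct children,
and the two-part annotation-label round trip.
"""

import variodna as v

graph = v.load_packaged_graph()
print(f"packaged terms: {len(graph)}")

term = graph.get_term("DNA substitution")
print("lookup by name ->", v.format_label(term))

print("children of DNA chain variation (0135):")
for child in graph.children(135):
    print("  ", v.format_label(graph.get_term(child)))

print("ancestors of pyrimidine transition (0314), nearest first:")
for acc in graph.ancestors(314):
    print("  ", v.format_label(graph.get_term(acc)))

label = v.parse_label("VariO:0136 DNA substitution", graph)
print("parsed label:", label.accession, "->", label.rendered)

report = graph.validate()
print("structural defects:", report.defects or "none")
# Every term is reachable from exactly one of the four branch roots
# (variation type 0129, function 0148, property 0227, structure 0155);
# the validation report would list any cycle, orphan or cross-branch term.
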