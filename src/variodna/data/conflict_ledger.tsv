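accession	claimed_names	resolution
391	plasmid affected;genome affected	0391 kept for "plasmid affected" (defined in its own dedicated sentence); "genome affected" stored under sentinel accession 9001
455	effect on single stranded DNA structure;effect on A-motif	0455 kept for "effect on single stranded DNA structure"; "effect on A-motif" stored under sentinel accession 9002
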