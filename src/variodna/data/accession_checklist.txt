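# Transcription checklist: every VariO DNA-branch accession cited in the source
# literature for this vocabulary, one per line. Each must be present in
# vario_dna_terms.tsv (sentinel reassignments are tracked in conflict_ledger.tsv).
0072
0127
0129
0130
0131
0132
0133
0134
0135
0136
0139
0141
0142
0143
0144
0145
0146
0147
0148
0149
0150
0151
0152
0153
0154
0155
0156
0157
0158
0159
0160
0161
0162
0163
0164
0166
0167
0168
0169
0170
0171
0172
0173
0174
0175
0176
0177
0178
0179
0180
0181
0182
0183
0184
0185
0186
0187
0188
0189
0190
0192
0193
0194
0195
0196
0197
0198
0199
0200
0201
0202
0203
0204
0206
0207
0208
0209
0210
0211
0212
0213
0215
0218
0219
0220
0221
0226
0227
0229
0230
0231
0303
0313
0314
0315
0316
0322
0337
0377
0378
0379
0380
0388
0390
0391
0392
0405
0407
0412
0419
0420
0421
0422
0423
0424
0427
0428
0429
0430
0431
0432
0433
0434
0444
0445
0446
0447
0448
0449
0450
0451
0452
0453
0454
0455
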