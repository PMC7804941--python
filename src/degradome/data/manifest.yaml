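description: Per-class checksum totals for the packaged inventory (classes ordered aspartic, glutamic,
  threonine, cysteine, serine, metallo).
classes:
- aspartic
- glutamic
- threonine
- cysteine
- serine
- metallo
gene_models:
- 17
- 5
- 14
- 41
- 72
- 83
clans:
- 2
- 1
- 1
- 5
- 8
- 9
subfamilies:
- 2
- 1
- 1
- 15
- 17
- 35
unassigned:
- 1
- 0
- 0
- 2
- 4
- 7
new_members:
- 6
- 5
- 6
- 21
- 34
- 30
new_active_sites:
- 4
- 0
- 4
- 15
- 36
- 51
inactive:
- 2
- 0
- 4
- 1
- 1
- 4
secreted:
- 11
- 4
- 0
- 2
- 32
- 13
characterized:
- 6
- 1
- 0
- 0
- 11
- 1
ec_buckets:
  3.4.11: 17
  3.4.13: 16
  3.4.14: 24
  3.4.16: 14
  3.4.17: 5
  3.4.19: 33
  3.4.21: 31
  3.4.22: 13
  3.4.23: 22
  3.4.24: 30
  3.4.25: 14
  3.4.99: 1
  unknown: 12
proteome_size: 14165
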