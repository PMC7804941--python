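# degradome

Motif-architecture scanning and MEROPS-style classification of the
*Aspergillus niger* protease repertoire.

Filamentous fungi such as *A. niger* encode hundreds of peptidases — the
**degradome** — spanning six catalytic classes (aspartic, glutamic,
threonine, cysteine, serine, metallo) organised into MEROPS clans and
families/subfamilies.  Annotating a degradome means deciding, for every
candidate protein, which family architecture it carries, whether its
consensus catalytic residues are intact (putatively active vs inactive
vs non-peptidase homologue), whether it is secreted, and how the
repertoire breaks down by class and EC sub-subfamily.  This package
implements that pipeline for people who study fungal proteolysis or who
need a reproducible, scriptable reimplementation of consensus-residue
annotation:

* a **motif grammar** for the compact active-site notation
  (`HEXXH`, `GXSXX(T/S/G)`, `HXXGHXXGX_3-8_H`, `NEXXT/A`, …) with an
  exact scanner and ordered multi-motif architecture matching;
* a packaged, validated **catalogue** of 71 family rules and a curated
  **inventory** of the 232 *A. niger* (CBS 513.88 / ATCC 1015)
  proteases, with per-class checksum validation;
* a **classifier** producing class/clan/subfamily and activity calls,
  plus tribe reassignment of metallopeptidases by zinc-site
  architecture (metzincin, gluzincin, inverzincin, funnelin,
  αβα-exopeptidases, AAA);
* **consensus secretome voting** over six localization predictors and
  EC exo/endo bucketing;
* **composition statistics** reproducing the summary grid and
  percentages of the repertoire;
* a seeded **synthetic-data generator** planting family architectures
  with optional catalytic knockouts and noisy predictor calls, so the
  whole pipeline is testable without downloads.

## The model in brief

A family rule is an ordered architecture of motif components with roles,
e.g. subtilisins (S8A): `D(D/T)G + GXSXX(T/S/G)` (Asp/His/Ser triad), or
pitrilysins (M16A): inverted zinc site `HXXEHX_76_EXXV/H + E`.  A query
is assigned to the rule maximising the number of catalytic components
present (ties: catalytic specificity, then total specificity, then
catalogue order); it is *active* iff all catalytic components are
present, *putatively inactive* if some but not all, and a
*non-peptidase homologue* when similarity evidence asserts a family
whose catalytic and metal-binding residues are all absent.  Secretion
is a strict majority over per-predictor calls (ties are non-secreted).

## Worked example

```
$ python analysis/02_composition_summary.py
232 proteases = 1.64% of the 14165-protein proteome
class composition: aspartic 7.3%, glutamic 2.2%, threonine 6.0%, cysteine 17.7%, serine 31.0%, metallo 35.8%
clans 26, families/subfamilies 71; EC: exo 109, endo 111, unknown 12
four largest subfamilies (A1A, T1A, C19, S10) hold 24.1% of the degradome
```

i.e. the packaged inventory covers 1.64% of the predicted proteome;
metallopeptidases are the largest class (35.8%), serine peptidases
second (31.0%); 109 exopeptidases, 111 endopeptidases and 12 proteases
without an assignable EC number; and the pepsin (A1A), proteasome
(T1A), ubiquitin-specific protease (C19) and serine-carboxypeptidase
(S10) subfamilies alone hold roughly a quarter of the repertoire.

The same operations run from the CLI on your own files:

```
degradome simulate --n 50 --seed 42 --out run/          # synthetic demo input
degradome classify --in run/synthetic.fasta --out run/  # class/clan/subfamily + activity
degradome vote --in run/calls.tsv --out run/            # secretome consensus
degradome summarize --out run/                          # composition grid
degradome validate --out run/                           # inventory checksums
degradome scan --in run/synthetic.fasta --motif "HEXXH" --out run/scan
```

`analysis/01_validate_inventory.py` re-derives every per-class total
(gene models, clans, subfamilies, inactive, secreted, characterized, EC
buckets) from the record table and confirms each of the 76 checksum
cells; `analysis/03_recovery_benchmarks.py` reports 100% family and
activity recovery on noiseless synthetic data, 100% putatively-inactive
calls under total catalytic knockout, and consensus-vote accuracy
within a fraction of a standard error of the closed-form binomial
prediction.

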