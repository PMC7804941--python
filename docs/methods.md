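# Methods

## Scope and model

The package annotates a protease repertoire ("degradome") the way genome
surveys of peptidases are done under the MEROPS classification: each
protein is assigned a catalytic class (aspartic, glutamic, threonine,
cysteine, serine, metallo), a clan, and a family/subfamily, and is called
putatively active or inactive from the presence or absence of its
consensus active-site residues.  The package implements this as a
motif-architecture model:

* a **motif** is a short pattern over the 20 amino acids written in the
  conventional compact notation — fixed residues (`DTG`), wildcards
  (`GXSXG`), alternations (`GXSXX(T/S/G)`, `NEXXT/A`), and bounded
  spacers (`HXXGHXXGX_3-8_H`, `HXXEHX_76_EXXV/H`, `EX_nHXHX_10D`);
* an **architecture** is an ordered list of motifs with per-component
  roles (catalytic, metal-binding, Met/Ser-Gly-turn, accessory),
  separated by `+` in the printed form;
* a **family rule** binds an architecture to a subfamily, clan, class,
  EC sub-subfamily bucket and (for metallopeptidases) a tribe.

A protein *carries* an architecture when each component occurs in order,
without overlap.  This is deliberately exact matching — no PSSMs, HMMs,
E-values or alignments; the model captures the consensus-residue rule
used for activity calls, not remote homology detection (which the
pipeline consumes as an optional evidence table instead).

## Motif grammar semantics

`X` is a wildcard over the 20 standard residues.  `X_a-b` is a spacer of
`a`–`b` arbitrary residues, `X_k` a fixed spacer, and `X_n` an open
spacer bounded by a configurable `xn_max` (default 100 — the JAMM-type
`EX_nHXHX_10D` architecture gives no printed bound, and 100 residues
comfortably covers the distance between its glutamate and the zinc
site in known structures).  A trailing `/B` alternation binds to the
single preceding position (`NEXXT/A` = Asn-Glu-X-X-[Thr|Ala]).  The
ideographic comma that appears in some printed architecture cells is
treated as the `+` separator.  Input sequences are upper-cased; `*` and
`-` are stripped with a warning; the ambiguity codes B/J/O/U/Z/X are
tolerated in sequences but satisfy only wildcard positions.

Scanning reports one match per feasible start position, using the
shortest feasible spacer assignment, minimised left to right (ties
between spacer assignments cannot otherwise arise).  Patterns compile
to anchored regular expressions with lazy quantifiers, whose backtracking
order realises exactly this rule; the test suite checks the scanner
against an independent exhaustive-enumeration oracle on thousands of
random sequences.  Matches are reported 1-based and inclusive, the
protein-residue convention.

Architecture location is greedy leftmost: components are placed in
order, each starting after the previous component's end (plus the
minimum inter-component gap, default 0 with no upper bound, since the
printed architectures carry no inter-motif distances).  Components are
never reordered; a missing component is recorded as absent, not an
error.

## Classification and activity calls

Every rule with motif components is located on the query; the winner is
the rule with the most catalytic-role components present.  Ties are
broken by the specificity of the matched *catalytic* components (number
of fully specified residue positions), then by total matched
specificity, then by catalogue order (classes ordered aspartic,
glutamic, threonine, cysteine, serine, metallo; subfamilies in
catalogue order).  Catalytic-first specificity is a deliberate choice:
a few families' catalytic consensus is a single residue (the
proteasome's N-terminal Thr, the isoaspartyl dipeptidase's nucleophilic
Asp), which any random sequence contains; ranking by total specificity
would let such a rule, padded by accidental accessory hits, outrank a
genuine family member that has lost one catalytic residue.  Sequences
whose top two rules tie across different catalytic classes are flagged
`ambiguous`.

Activity follows the consensus-residue rule:

* **active** — every catalytic-role component of the best rule present
  (accessory components are not required by default; they are listed
  with the architectures but are not consensus catalytic residues —
  a `require_accessory` switch makes them mandatory);
* **putatively inactive** — the best rule is recognisable (≥1 component)
  but at least one catalytic component is missing;
* **non-peptidase homologue** — no catalytic motif evidence anywhere,
  and a homology table asserts a family whose catalytic *and*
  metal-binding components are all absent.  Motif evidence always
  overrides homology; homology is authoritative only in the motif-free
  case, which is precisely the non-peptidase-homologue definition;
* **unclassified** — neither motif nor homology evidence, or the
  sequence is shorter than 20 residues (too short to carry an
  architecture plus context; a warning is emitted).

## Metallopeptidase tribes

Metallopeptidases are routed to tribes by zinc-site architecture, in
this order: the extended three-histidine motif
(`H(Q/E)XXHXXGXXH/D`, `HEXXHXX(H/F)XXH`) → **metzincin**; the inverted
`HXXEH` → **inverzincin**; the `HEXXH`/`HEXXXH` core → **gluzincin**;
`HXXE` → **funnelin**; the `(S/G/A)HXDXV + P/GXXD + XEE + D/E + H`
exopeptidase architecture → **aminoacylase-1** (αβα-exopeptidases); the
`EE` pair → **EEM2-MPs** (αβα-exopeptidases); otherwise unassigned.
Two context exceptions are encoded in the catalogue rather than the
motif logic, because the architecture alone cannot express them: the
FtsH-like ATP-dependent families are **AAA** proteases, and the ATP23
family is left unassigned despite its `HEXXH` core.  A test asserts
that the motif-only inference agrees with every catalogue tribe label
except exactly these two.

## Consensus secretome voting

Calls from up to six localization predictors are combined per protein:
secreted iff (secreted calls)/(non-missing calls) strictly exceeds the
threshold (default 0.5).  A 3–3 split is therefore non-secreted — the
conservative reading of a "majority" over six tools — and calls for
other compartments count against secretion, matching the binary
secreted/intracellular framing of secretome surveys.  The threshold is
configurable up to unanimity.  Proteins with fewer than four usable
calls are left undetermined rather than decided on thin evidence.

For independent per-predictor error `p`, the probability that the
consensus recovers the truth has a closed form: a truly secreted
protein survives ≤ 2 flips of 6 (needs ≥ 4 votes), a truly non-secreted
one ≤ 3 flips, so accuracy = f·P[Bin(6,p) ≤ 2] + (1−f)·P[Bin(6,p) ≤ 3]
with f the secreted fraction.  The simulation tests check the empirical
accuracy against this formula within three standard errors.

## Composition statistics

Percentages round half-up: class-composition shares to one decimal,
genome-coverage fractions to two (the precisions used in genome
surveys).  The proteome size defaults to 14,165 protein-coding genes
(the A. niger CBS 513.88 annotation) and is overridable.

Clan counting needs care with unassigned groups.  The packaged
inventory's per-class totals follow the convention that a pseudo-clan
is counted only when a class contains a *classified family* that is
itself not assigned to any clan (the metallopeptidase family M79);
proteases with neither family nor clan do not create a pseudo-clan.
The alternative bookkeeping (a pseudo-clan for any class with any
unassigned member) is also computed and reported in the summary footer,
since both conventions appear in the literature.

## The packaged catalogue and inventory

`data/catalogue.yaml` holds 71 family rules; `data/inventory.tsv` holds
232 locus-tagged records for the two sequenced strains (CBS 513.88 and
ATCC 1015); `data/manifest.yaml` holds the per-class checksum totals
that `validate_inventory` recomputes cell by cell.  Schema notes:

* `catalogue.yaml`: one rule per family/subfamily with `subfamily`,
  `clan`, `catalytic_class`, `archetype`, `ec_bucket`,
  `residue_arrangement`, ordered `components` (`motif` in the grammar
  above + `role`), optional `tribe` (metallo only), and `motif_free`
  for families whose catalytic residues have no printed linear motif
  (e.g. the glutamic Gln/Glu dyad, the M24A bidentate ligands).
* `inventory.tsv`: one row per protease with locus tag, strain,
  class/clan/subfamily, provisional identification, activity, secretion
  flag, EC bucket, characterized flag, printed motif annotation, tribe
  and a free-text note.  Numeric locus tags are JGI protein IDs of
  ATCC 1015-only genes.  Three placeholder rows (`unlisted-S1`,
  `unlisted-M1`, `unlisted-M2`) stand for unassigned proteases that are
  counted in the class totals but not individually named in the
  curation source; they are synthetic identifiers, flagged in the note
  column.
* `new_member` / `new_active_site` flags reproduce the per-class
  *totals* of reassigned members (102) and recharacterized active
  sites (110); their per-record attribution is not part of the
  transcription and should not be interpreted record by record.
* Per-record EC buckets are resolved so that subfamilies hosting both
  exo- and endopeptidases (e.g. S33 prolyl aminopeptidases vs
  tripeptidyl-peptidases, M24B dipeptidases vs aminopeptidases) match
  the per-sub-subfamily totals; records without a defensible bucket
  carry `unknown`.

## Synthetic data generator

Each synthetic protein carries exactly one planted family architecture:
components instantiated left to right (one residue per
wildcard/alternation position, one length per spacer), flanked and
separated by background residues (uniform over the 20 standard residues
by default; a composition table can be supplied).  Flank lengths are
drawn uniformly from 20–60 residues.  A candidate is rejected and
redrawn when the random flanks accidentally contain another rule's full
catalytic architecture *that would outrank the planted one* under the
classifier's comparator — rejecting any accidental motif at all would
never terminate, since several catalytic consensi are single residues.
Rejection is capped at 100 attempts per record.

Knockouts model putatively inactive family members: one catalytic-role
fixed position is replaced by a residue outside that element's allowed
set, applied after the intact sequence is accepted and then
re-validated — the knocked component must not survive via an accidental
copy elsewhere, and the degraded architecture must still outrank rival
rules so the record remains attributable to its family.  The default
family mix ({A1A: 0.3, S8A: 0.3, S53: 0.2, S54: 0.2}) uses families
whose rules carry at least two catalytic components, so a single
knockout leaves the family recognisable, mirroring real inactive
homologues that retain part of their consensus.

Predictor call tables emit six calls per protein, each flipped from the
true secretion label independently with `predictor_error_rate`.  The
default true-secretion fraction is 62/232 ≈ 0.267, the secretome share
of the packaged inventory.

What the generator does *not* emulate: real A. niger residue
composition, paralog families, signal-peptide sequence structure,
intron/gene-model noise, or correlated predictor errors.  Passing
recovery tests therefore demonstrate the internal consistency of the
scanner/classifier/vote chain on the statistical structure it assumes,
not performance on real proteomes.

## Numerical and degenerate-input choices

* Seeds are mandatory for all simulation entry points; identical
  configurations give byte-identical FASTA/TSV outputs
  (`numpy.random.default_rng`).
* Empty sequences scan to an empty match list; an empty FASTA
  classifies to an empty result list; an empty inventory summarises to
  an all-zero grid; an empty rule file is an error.
* Duplicate sequence IDs, duplicate locus tags, conflicting duplicate
  predictor calls and unknown subfamily references are hard errors that
  name the offending entry.
* Vote threshold is a strict inequality; problem sizes in the checks
  (100 records for recovery, 1,000 for vote calibration, ~1,000
  scanner-oracle cases) keep the full suite under half a minute while
  making the binomial three-standard-error bands discriminating.

## Known limitations

* Exact motif matching cannot detect family members whose consensus
  degenerated beyond the printed patterns; the real surveys back the
  motif rule with similarity searches, which this package only consumes
  as evidence tables.
* The inventory transcription resolves a handful of ambiguities in its
  curation source (secretion flags summing to the stated secretome
  size, per-record EC buckets within fixed sub-subfamily totals); the
  affected records carry notes, and the checksum manifest pins the
  intended totals.
* Tribe routing covers the architectures present in the catalogue; it
  is a decision list, not a general fold classifier.
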