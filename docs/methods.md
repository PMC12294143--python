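# Methods

## Scope and data model

`lysmod` analyzes *annotated* phage genomes: it consumes CDS features with
product strings (GenBank or GFF3+FASTA), HMMER3 per-domain hit tables, and
optional tabular BLASTp-style evidence (transporter-database hits, taxonomy
tables, supplemental domain rows). It performs no gene calling, no homology
searches and no network access; wherever a published workflow would call an
external search service, the corresponding evidence enters as a table. All
coordinates are 1-based inclusive (GenBank convention), features are kept in
ascending genomic order regardless of strand, and on-the-fly translation uses
the bacterial/phage code (table 11).

## Role assignment

Roles are assigned per ORF by precedence: (1) product-keyword match,
(2) domain evidence, (3) supplemental evidence rows. Keywords are matched as
whole, case-insensitive tokens, so "lysin" never fires inside "holin". The
shipped lexicon ("holin"→holin; "endolysin"/"lysin"/"lysozyme"/"amidase"/
"muramidase"→endolysin; "endonuclease"→endonuclease) is a reconstruction of
common annotation vocabulary and is deliberately editable YAML, since product
strings vary across annotation pipelines. Two decisions matter here:

* **Keyword beats domain evidence on conflict** (with a logged warning):
  curated annotation is treated as the primary signal and database evidence
  as the cross-check. `evidence_first=True` flips the precedence.
* **"hypothetical" is a fallback, not a competing keyword.** A product of
  "hypothetical protein" never blocks evidence-based rescue; it only applies
  when no evidence resolves the ORF. Without this reading, obfuscated
  endolysins could never be rescued by their domain hits.

Role assignment is a pure function of (product, hits, supplemental rows,
lexicon); hit order is irrelevant.

## Module delineation and the organization catalogue

A lysis module is a maximal run of holin/endolysin genes in which consecutive
lysis genes are separated by at most `max_intercalated` non-lysis ORFs
(default 2) and at most `max_gap_nt` of intergenic distance per junction
(default 1000 nt). These defaults jointly admit a two-gene
endonuclease/hypothetical intercalation between endolysins while rejecting a
cassette dispersed across 18 unrelated genes — in the latter case the genome
yields zero modules plus a diagnostic carrying the intervening ORF count. A
module must contain at least one H and one E; modules never begin or end with
an intercalated gene. Members are reported in transcription order (reverse
the genomic order for reverse-strand modules), with module direction taken
from the majority member strand ("mixed" when strands differ).

Organization classification matches the module's role signature against an
ordered catalogue after stripping X (other/hypothetical) symbols but
**retaining N (endonuclease)**: pattern `H [N] E` (organization C) can then
claim endonuclease-intercalated modules, while a plain `H E` signature falls
to organization A first (catalogue order breaks ties). The per-label layouts
(`A=H·E, B=H·H·E, C=H·[N]·E, D=E·H, E=E·E·H`) encode the constraints fixed by
the published description — at most two ORFs per role, holin-first for A–C,
endolysin-first for D–E, endonuclease variably present in C — and live in
editable YAML because the exact drawings are not printed as text. Signatures
exceeding two H or two E are "unclassified" by design.

## Endolysin architecture typing

Hits with independent (per-domain) E-value ≥ 0.01 are discarded at parse
time. Overlap resolution keeps, for any pair overlapping by more than half
the shorter hit, the lower-E-value hit (ties: higher bit score, then
lexicographic domain name). The surviving domains, ordered by alignment
start, define the canonical architecture string (`name & name & ...`;
`(none)` for hit-less proteins). Identity is arrangement-sensitive and
repeat-preserving. Labels A1…An are assigned per panel by decreasing
frequency, count ties breaking lexicographically; `label_map` pins labels to
a reference table for cross-run comparability, because frequency ranks are
meaningful only relative to a panel. The shipped 25-layout reference table is
a documented reconstruction: the text-pinned layouts (A1, A2, A10, A20, A21,
the no-CBD and no-EAD label sets) are fixed, the remainder are plausible
fillers over the shipped domain lexicon, and the file says so.

EAD-less architectures are cross-referenced against their co-encoded,
catalytically active partners per genome; an EAD-less endolysin with no
active partner is reported as an exception requiring supplemental evidence,
and `augment_architecture` folds such rows (e.g. a PGRP + pneumo_PspA pair on
a CBD-only protein) into the architecture, updating flags and activities.
Endolysin gene lengths outside 228–1386 bp trigger a warning, never a
rejection — the bound is descriptive, not a rule.

## Gene overlaps

Every pair of intersecting feature spans yields one record (default filter:
endolysin–endolysin pairs). The start offset is measured start-to-start,
5′→3′ on the upstream gene's coding strand; the frame offset is that value
mod 3 for same-strand pairs and a sentinel (−1) otherwise. Because "starting
N nt downstream" can also be read as a stop-to-start distance, the record
carries both spans and `stop_to_start_nt` recomputes the alternative reading.

## Holin characterization

Transmembrane segments are called from a Kyte–Doolittle sliding-window
profile: centered moving average (window 19, truncated at the termini;
proteins shorter than the window collapse to their global mean; unknown
residues score 0 with a warning), maximal runs at or above threshold 1.6,
runs shorter than 15 residues discarded, survivors closer than 5 residues
merged. This is a deliberately transparent hydropathy method, not an emulation
of neural topology predictors; all parameters are config, and externally
computed TMD tables can override the prediction per protein (`--tmd-table`).
Orientation/topology is out of scope.

Transporter families are the first three dot-fields of the best qualifying
hit's subject accession (lowest E < 0.01, ties to higher bit score, then
lexicographic subject); no qualifying hit → "unclassified". The consistency
report checks (1) that two-holin genomes carry holins from different families
(pairs involving "unclassified" are indeterminate), (2) that each family has
a single TMD count across its members, and (3) lists two-holin genomes where
both holins have a single TMD; violations are reported rows, never dropped.

## Synthetic data generator

The generator emulates the structures the analysis assumes, at desk scale:
multi-ORF genomes (default 3–6 decoy ORFs drawn from a phage-structural
lexicon: hypothetical/capsid/terminase/portal) carrying exactly one lysis
cassette realizing an assigned organization layout; endolysins with planted
N→C domain layouts and a matching per-domain hit table; overlapping
endolysin pairs at stated nucleotide offsets; holins of 60–160 aa with 1–3
planted 21-aa hydrophobic helices separated by ≥10-aa hydrophilic linkers;
optional product obfuscation ("hypothetical protein" plus a planted domain
hit) to exercise evidence-based rescue; and noise hits whose E-values are
all ≥ 0.01 by construction, so the filtered pipeline is provably invariant
to the noise rate.

Numerical choices worth knowing:

* **TMD blocks are shuffled multisets over {L, I, V}** (8/7/6 of 21) and
  linkers shuffled serine-rich multisets over {S, N, K, D, E}. With the
  default caller (window 19, threshold 1.6, minimum run 15), a 21-aa helix
  sits near the geometric limit of detectability: compositions admitting many
  Ala/Phe can drop below a 15-residue supra-threshold run. Restricting blocks
  to the strongly hydrophobic core and keeping linkers only mildly
  hydrophilic makes every planted helix recoverable by construction, which is
  the property the recovery tests assert.
* Holin families are drawn coherently with a fixed family→TMD-count map
  (1 TMD: 1.E.26, 1.E.65; 2 TMDs: 1.E.11, 1.E.18, 1.E.24; 3 TMDs: 1.E.10,
  1.E.16, 1.E.19, 1.E.21), and tandem holins in one genome are forced into
  different families, so the consistency analyses run against structured
  truth.
* DNA is a random backbone with uniform-codon back-translated genes written
  onto it; for overlapping pairs the downstream gene's codons win on the
  shared span. The DNA is never analyzed downstream — only coordinates and
  proteins — so no codon-usage or regulatory realism is attempted.
* One RNG stream per panel, seeded from the spec: regeneration is
  byte-identical, and the whole pipeline is deterministic under a fixed
  seed/config.

What passing on synthetic panels does **not** show: robustness to divergent
real-world product vocabularies beyond the configurable lexicon, to
fragmented or multi-contig assemblies (unsupported), to marginal hydropathy
of real holin helices (real TM segments vary in length and composition; the
transparent caller will disagree with neural predictors on borderline cases),
or to annotation boundary errors — the package takes whichever single
annotation it is given.

## Problem sizes

The shipped tests and the acceptance script run on panels of 5–25 genomes,
90-protein holin panels, and 20-module ordering panels. These sizes fully
exercise every code path (all five organizations, all 25 reference
architectures, all three TMD counts, both ordering directions); the ordering
split uses 20 modules (17 holin-first, 3 endolysin-first), the smallest panel
realizing an exact 85%/15% split.

## Known limitations

* Organization labels beyond the five shipped patterns require catalogue
  edits; signatures with >2 H or >2 E are reported but unclassified.
* Architecture labels are panel-relative unless pinned with a label map.
* Supplemental evidence rows carry no coordinates, so augmented domains are
  appended in row order rather than positioned.
* The hydropathy caller reports segment count and positions only, not
  membrane topology.
* Panel selection externalizes representative priority as an injected score;
  by default ties resolve to the lexicographically smallest accession.
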