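# Methods

This note documents the models and procedures behind each module, the
parameter defaults and why they were chosen, what the synthetic fixtures do
and do not demonstrate, and the numerical choices that make runs
reproducible.

## Curated reference tables

The packaged TSVs under `beetaqp/data/` transcribe the published sugar-beet
aquaporin catalog (28 proteins with locus tag, length, MW, pI, TMH count),
the conserved-residue table (NPA loop-B/loop-E triplets, ar/R quartet,
Froger P1–P5 per protein) and the SDP substrate patterns with the observed
per-protein SDP residues grouped by substrate heading. They are treated as
ground truth; the toolkit never re-derives them from a genome.

Notes on the transcription:

* Two residue-table cells (BvPIP1;2 P4/P5) are blank in the source and are
  stored as missing (`*`); they are excluded from any full-match
  requirement.
* The two SIP1;1 transcripts carry Greek suffixes in the source; identifiers
  normalise them to ASCII `alpha`/`beta`, the display layer restores α/β.
  The catalog exposes both transcript-level (28) and gene-level (27)
  counting; callers choose.
* The nine SDP positions are substrate-specific in the source data — one
  protein can appear under several substrate headings with different
  residues. The per-substrate observations live in
  `table3_residues.tsv`; the single SDP1–SDP9 column set annotated on the
  packaged anchor is this package's normative definition for profile
  extraction from novel sequences.

## Candidate screen

A protein passes the screen when all of the following hold (each violated
filter is named in `fail_reasons`):

* **≥ 2 NPA-like motifs** (N-P-{A,S,T,L,V}; exactly the third-position
  variants observed in the family) with at least one pair spaced 60–180
  residues apart — the loop-B→loop-E distance across three transmembrane
  helices of an hourglass fold;
* **≥ 5 predicted TM helices** (family members have 5–7);
* **length within 150–400 aa** (catalog range is 236–327);
* **global-alignment identity ≥ 0.30** to at least one reference panel
  sequence — the self-contained stand-in for profile-HMM domain detection,
  which is out of scope.

TM helices come from Kyte–Doolittle hydropathy: every window (length 19,
odd) whose mean reaches 1.6 marks the residues it covers; marked runs closer
than 3 residues are merged and runs shorter than 15 are discarded. This is
a deliberately simple stand-in for dedicated topology predictors, so
per-protein TMH counts from the published catalog are not an accuracy
surface for it.

Molecular weight is the sum of average residue masses plus one water
(ExPASy-style table, reported in kDa to 2 decimals). The isoelectric point
is the root of the Henderson–Hasselbalch net-charge function (N-/C-termini
plus D, E, C, Y, K, R, H) found by bisection on [0, 14] to 1e-4 pH units;
pKa sets: EMBOSS (default) or Bjellqvist.

## Anchor alignment and residue extraction

Diagnostic residues are transferred by a **pairwise** global alignment of
the query to an annotated anchor (BLOSUM62, gap open 10, gap extend 0.5 —
conventional defaults; the source workflow used a GUI aligner's defaults).
A pairwise anchor alignment replaces a multiple alignment because it is
deterministic, testable per query, and sufficient for column transfer. The
packaged anchor is a synthetic PIP2-type scaffold (water-typical F-H-T-R
filter, Q-S-A-F-W Froger residues) with hand-annotated columns; any
annotated anchor can be substituted.

Rules: the residue aligned to each anchor column is reported; a gap at a
diagnostic column is reported as a gap, never a neighbouring residue; an
NPA triplet with any gapped column is missing. Alignment scores are verified
against an independent quadratic-space affine-gap DP oracle in the tests.
Coordinates are 0-based half-open internally.

## Classification

Distances are 1 − global-alignment identity (identity = identical columns /
alignment length). No substitution-model correction is applied — the
original tree-building settings are unstated, and at within-family
distances the p-distance ordering is what the assignment uses.

Neighbor-joining is implemented in-house with deterministic tie-breaking:
the Q-criterion is computed as (m−2)·D − (rᵢ + rⱼ) with the row-sum sum
formed first (the naive left-to-right subtraction is not exactly symmetric
in floating point), and the joined pair is the row-major argmin over the
upper triangle — i.e. lowest (i, j) among ties. Negative branch lengths are
clamped to zero. On additive matrices the tree metric reproduces the input
to 1e-9 (tested to 8 taxa, cross-checked against scikit-bio's NJ).

A query inherits the subgroup of its smallest enclosing clade containing
references, provided those references vote unanimously; a mixed clade falls
back to the nearest reference by distance (ties break lexicographically),
and the method used is recorded. Proposed names take the next free integer
within the subgroup; transcripts of one gene take α/β suffixes. Support is
1 − distance to the nearest reference of the assigned subgroup.

Bootstrap support: sequences are projected onto the columns of the first
record (query insertions dropped, deletions gapped) to form a
reference-anchored pseudo-alignment; columns are resampled with replacement,
p-distance NJ trees are rebuilt, and each split of the main tree gets the
fraction of replicate trees containing it. Default 1,000 replicates in the
CLI; 100 in tests for speed. The single-reference projection loses columns
absent from the reference — acceptable here because supports are only used
comparatively.

## Substrate calling

A 9-residue SDP vector matches a substrate pattern position-by-position
(set membership; a gap is a mismatch, never a wildcard). Calls: **FULL** at
9/9, **NEAR** at 1–2 mismatches, **NO** otherwise. The NEAR band is two
because the observed "novel-type" rows in the curated data deviate at one
position (NH₃: SDP2) or two (CO₂: SDP2 plus SDP6 or SDP8); both thresholds
are configurable. On the packaged observations this yields 20 FULL + 2 NEAR
urea calls (the two NEAR rows deviate at SDP6), 5 boric-acid FULL, 7 H₂O₂
FULL, 3 CO₂ NEAR, 1 NH₃ NEAR, and no silicic-acid match of any kind.

ar/R annotation rules (water-typical F-H-T-R; formamide-associated H-I-G-R;
the AtNIP5;1-like NPS/NPV + A-I-G-R boric-acid configuration) are data in a
packaged JSON registry, not code; they fire on exact residue predicates and
attach notes, not transport claims.

## Genome context

Locus tags `Bv<chr><scheme><number>_<code>.t<k>` are parsed structurally;
numbers step by 10 between adjacent loci (observed in the catalog), so
tandem duplication is called for same-chromosome, same-subgroup pairs within
`max_gap` (default 2) steps. `ug` (unplaced-scaffold) tags share the
chromosome numbering with `g` tags; `TE` (transposable-element scaffold)
tags do not, so cross-scheme pairs are reported at low confidence rather
than dropped. Transcripts of a single gene are never paired. The
locus-number rule is a documented stand-in: the source reports tandem
events without stating a distance criterion.

Exon chains come from GFF3 (1-based inclusive; minus-strand chains reversed
into transcription order). A transcript pair is an **exon-skipping** event
when the shorter chain equals the longer one minus exactly one internal
exon, with coordinate equality of all shared exons; any other difference is
`other`. The skipped exon's 1-based ordinal in the longer chain is
reported.

## Expression

The contract boundary is a genes × samples RPKM TSV plus sample metadata
(organ; condition ∈ control/salt/heat) — read alignment and quantification
are upstream. Defaults, all configurable and recorded in the run manifest:
pseudocount 1 for log₂ transforms, detection floor RPKM 1, strong-response
cut |log₂ fold change| > 1 (the threshold the source text uses for "strong
induction"). The toolkit reports no differential-expression statistics — no
replicates, dispersions or p-values — matching the descriptive design of
the source study.

## Synthetic fixtures

The generator plants known truth at every stage: aquaporins are built on a
276-residue six-TM scaffold (hydrophobic helices, hydrophilic loops) with
each subgroup's observed diagnostic residues overwritten at fixed columns
and everything else mutated at a configurable rate (≤ 0.2); decoys are
random sequences scrubbed of NPA-like motifs; the annotation follows the
family exon-count conventions (PIP 4, TIP 3, NIP 5, SIP 3, XIP 2) with two
adjacent-locus tandem pairs and one exon-2-skipping transcript pair; the
expression matrix plants silent, organ-specific and ±4×/±1.5× stress
responders over log-normal baselines (clipped to ≥ 5 RPKM) with
multiplicative log-normal noise, σ = 0.1 by default. All outputs are
bit-reproducible under a fixed seed.

What passing on these fixtures does **not** show: recovery of the published
per-protein MW/pI/TMH values or residue tables from real sequences (those
require the original proteome), robustness to indels in queries (the
generator mutates by substitution only), realistic sequence composition, or
read-level RNA-seq noise. The fixtures demonstrate that each algorithm
recovers exactly what was planted under the stated noise models.

Problem sizes used by the tests and the acceptance script — 10 + 40
proteins for the screen, 20 queries for assignment, trees to 8 taxa, 100
bootstrap replicates, 200 planted expression genes — were chosen as the
smallest sizes at which every planted structure is represented several
times per class.

## Known limitations

* The identity-floor screen is weaker than profile-HMM domain detection;
  distant family members below 30% identity to every panel member would be
  missed.
* Subfamily assignment assumes the reference panel spans the subgroups
  present; novel subgroups are forced into the nearest existing one (the
  recorded `method` and support make such calls auditable).
* The TM predictor reports hydrophobic segments, not topology; counts can
  differ from dedicated predictors by ±1 around marginal helices.
* Substrate calls are sequence-based annotations, not transport assays.
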