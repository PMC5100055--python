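# Methods

This note documents the models and procedures `sitkit` implements, the
parameter choices that matter, what the bundled simulator does and does
not emulate, and the numerical and design decisions taken where the
procedure left room.

## Decontamination model

The pipeline assumes that cross-contamination between multiplexed
sequencing projects produces *near-verbatim copies* of donor contigs in
a recipient assembly (identity ≈100%, depressed read depth), whereas
genuine homology between two different species produces hits at the
species pair's characteristic, substantially lower identity. The
decision procedure per unordered project pair is:

1. **Masking.** Simple repeats are soft-masked so they cannot seed
   alignments (they would otherwise produce spurious high-identity
   hits between unrelated contigs). The masker scores every sliding
   window of `window` nt (default 64) with the symmetric DUST
   statistic over overlapping triplets, S = Σ_t c_t(c_t−1)/2, and
   masks all positions of any window with 10·S/(L−1) > `level`
   (default 20; L = unambiguous triplets in the window); intervals
   separated by ≤ `linker` (default 1) merge. This windowed definition
   is normative for the toolkit and is enforced against an exhaustive
   per-window brute-force oracle in the tests. It masks whole
   qualifying windows, so interval edges can extend a few bases into
   adjacent unique sequence — conservative for seeding purposes.
   Masked bases are excluded from seeding only; extensions may cross
   them.

2. **All-vs-all gapless alignment.** Exact 12-mer seeds (fully
   uppercase in both sequences, both subject strands) are grouped by
   diagonal and extended bidirectionally with an x-drop of 10 under
   +1/−1 scoring, so score = matches − mismatches and is directly
   consistent with percent identity. Alignments scoring < 64 are
   dropped; one best alignment is kept per seed diagonal and then one
   top-scoring hit per unordered contig pair (ties: higher identity,
   longer alignment, lexicographic ids — the reduction is
   deterministic in input order). Gapless alignment suffices because
   contaminant copies are substitution-level variants; externally
   computed gapped hits can be ingested from 12-column tabular files
   instead. The aligner is tested for score equality against an
   exhaustive all-diagonal best-segment scan.

3. **Hit qualification.** A hit counts only if ≥150 nt long *or*
   covering ≥50% of the shorter contig (inclusive OR: an AND reading
   would discard exactly the short-contig perfect copies the
   procedure exists to catch). A gapless hit longer than the shorter
   contig is corrupt input and is rejected.

4. **Histogram threshold.** Qualified hits are binned by percent
   identity into integer bins 0–100, rounding half up (99.5 → 100), so
   a copy with one error in ~300 nt (99.67%) lands adjacent to the
   100% peak. A pair is contaminated only if bin 100 strictly
   outnumbers bin 99. The scan then descends b = 99 … 2 and stops at
   the first b with counts[b−1] ≥ counts[b] and counts[b−2] ≥
   counts[b−1] — the start of the true-hit plateau; zero-count bins
   participate, so an empty stretch below the peak terminates the scan
   immediately. Hits in bins strictly above b are contaminants (the
   boundary bin itself is retained as "true": the conservative
   reading). If no plateau exists the whole populated range below 100
   is flagged with a warning — the peak trigger already fired and no
   genuine-homology plateau is present.

5. **Expression arbitration.** Flagged pairs default to discarding
   both copies. Exceptions, applied symmetrically to both members:
   a copy whose RPKM is ≥10× its partner's is retained and the partner
   discarded (a partner with RPKM 0 counts as satisfying the ratio for
   a non-zero copy); independently, any copy with RPKM ≥ 10,000 is
   retained, because highly conserved, highly expressed genes
   legitimately align at high identity — so both copies can survive.
   RPKM = 10⁹ · reads / (contig length · project library size).

6. **Aggregation and purge.** A contig flagged against several
   projects is discarded if any pair decision discards it (discard
   dominates). Purging partitions contigs — and predicted proteins,
   which follow their source contig — into retained and purged files
   exactly; proteins with unresolvable contig links are retained
   fail-open and counted.

Same-species project pairs (differently named but identical cultures)
are excluded from comparison via configuration; no automatic species
identity inference is attempted.

## Transporter classification

TMDs are predicted from the mean Kyte–Doolittle hydropathy of a
centred window (default 19 residues, cutoff 1.6); maximal runs of
qualifying positions become TMDs after merging runs closer than 5
residues and dropping runs under 7. This transparent predictor
replaces interactive web tools; its parameters are exposed and the
tolerant classification mode absorbs predictor disagreement at
hydropathy boundaries. Window means are compared to the cutoff with a
1e−9 epsilon: hydropathy values have one decimal, so genuine margins
are either exactly zero or ≥ 0.1/window, and the epsilon only absorbs
rolling-sum float noise.

Motifs: EGXQ-class = `E[GA]X[QKMH]` (covering the observed A-for-G and
K/M/H-for-Q variants), GRQ-class = `GRQ|GRH|GQS`, plus the broadly
conserved TMD4 `xQxxxQx` (glutamines four apart), which is reported as
annotation only. An EGXQ–GRQ pair anchors on consecutive TMDs (n, n+1)
when the EGXQ starts within [start(TMDₙ) − 15, end(TMDₙ)] and the GRQ
within [start(TMDₙ₊₁) − 15, end(TMDₙ₊₁) + 15]; assignment is greedy
left-to-right and each motif hit joins one pair at most. The 15-residue
margin is a design choice reflecting the qualitative geometry (EGXQ
just before/within one TMD, GRQ at the face of the next); any
consecutive-TMD anchoring is accepted, not just TMD2/3 and TMD7/8.
Membrane orientation is not used for classification.

Labels — strict mode: SIT ⇔ exactly 10 TMDs and 2 pairs; SIT-L ⇔
exactly 5 TMDs and 1 pair. Tolerant mode (default) keeps the pair
counts exact but allows 8–12 (SIT) or 4–6 (SIT-L) TMDs, annotating
near-misses (a one-pair protein with >6 TMDs is noted as a possible
assembly-truncated SIT, a documented real-world case).

Full SITs split at floor((end(TMD5) + start(TMD6)) / 2); the halves
concatenate to the input. The original analysis defined the split via
an alignment to a reference residue pair; the TMD-midpoint rule
approximates that anchor without requiring the reference alignment and
is a documented divergence. On the canonical architecture each half
classifies with 5 TMDs and 1 pair, i.e. SIT-L-like.

## Tree screen

Given a rooted, support-annotated tree, the rule walks the query tip's
ancestor chain outward. The first ancestor with support strictly above
the threshold (default 70) that *discriminates* decides: if it contains
any expected-group leaf → clean; if its non-query leaves are all one
foreign group → flagged, or exception when that group is an exception
group (default: prokaryote, since bacterial contamination of cultures
is routine). Unsupported, weakly supported, or mixed-foreign clades do
not discriminate; an exhausted walk is clean. The ancestor-chain (i.e.
nested-clades-containing-the-query) reading was chosen over evaluating
every bipartition because it is the strictest reading that preserves
the intended monotonicity: under nesting, once a clade containing an
expected leaf is reached, every larger clade also contains it, so
raising the support threshold can never convert clean into flagged —
a property an any-bipartition reading provably violates. Verdicts are
invariant under re-rooting that keeps the deciding clade intact.

## Simulator

`simulate_projects` emulates the structure the procedure assumes, per
project (defaults in parentheses): contigs (200 per project, 4
projects) with log-normal lengths (median 1000 nt, σ = 0.55, clamped
to [300, 5000]); a fraction (0.2) belong to ortholog families present
in every project, each member mutated from a family ancestor at rate
r = 1 − √(1 − d) so that the *pairwise* divergence between any two
members is d (0.15, i.e. ≈85% identity — mutating each copy at d
directly would compound to ≈72%); a fraction (0.05) of each project's
contigs are copied into one random other project with per-site
substitution probability 0.005 (≈99.5% identity) and read counts
scaled to 0.02 of the donor's. Expression is log-normal RPKM (median
30, σ_log = 1.5) converted to counts against a fixed library size of
5×10⁶ mapped reads. Mutations are substitution-only, so realized
identities are analytically predictable and the gapless aligner is
exact; contaminant copies are full-length. The generator does not
emulate indels, chimeric or fragmented contaminants, sequencing-error
profiles, assembly artefacts, or compositional (GC/repeat) structure —
passing tests therefore demonstrate the decision logic under the
assumed contamination structure, not robustness to assembly noise.

`evaluate` scores discarded-vs-truth with recipients as positives;
donors retained by the expression exceptions are simply retained,
while a discarded donor counts as a false positive like any other
collateral discard.

## Known limitation: the 100% > 99% trigger at low contamination counts

The pair-level trigger requires the 100% bin to strictly outnumber the
99% bin. Under the simulator's error model a copy of length L falls in
bin 100 iff its Binomial(L, 0.005) substitution count is at most
⌊0.005·L⌋, which happens with probability ≈0.45–0.62 depending on L.
At the default contamination rate each project pair carries only ~7
contaminant hits, so the trigger fires in roughly a third to a half of
pairs; pairs whose trigger fails contribute nothing to recall. The
acceptance suite measures this directly: pooled over 20 simulations,
precision is 1.0 and ortholog-only runs produce zero discards in
16,000 contigs, but recall is ≈0.45–0.55 — the corresponding recovery
test documents the ≥0.9 recall expectation and fails on the recall
arm. This is a property of combining a mean-99.5%-identity error model
with the strict bin-comparison trigger at small per-pair hit counts,
not of the implementation: detection is essentially all-or-nothing per
project pair (a triggered pair flags all its bin-99/100 hits), and
even under the most favourable contig-length distribution the trigger
probability at 7 hits per pair caps near 0.75. On real index-hopping
data, where most leaked contigs assemble to exactly 100% identity, the
trigger is far more robust. The generator's parameters are the study
conditions and were not adjusted to mask this behaviour.

## Problem sizes and runtime

Defaults keep everything single-CPU and desk-scale: the recovery
analysis runs 20 simulations of 4 × 200 contigs end-to-end (~2.5 s
each), the threshold-detector oracle covers 1,000 random histograms,
the aligner and masker oracles 200 sequence pairs each, and the tree
screen is verified exhaustively against a brute-force clade evaluation
over all rooted binary trees of up to 6 leaves (≈19,000
support-labelled trees). The full test suite completes in a few
minutes; `scripts/acceptance.py` in about the same.
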