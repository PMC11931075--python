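# Methods

## Problem setting

Covariance-model (CM) scans of a whole genome with miRNA family models
report every locus resembling a family member in sequence and secondary
structure. At mammalian genome scale the significant hit list is
dominated by false candidates with characteristic signatures: hits below
a database-size-appropriate score threshold, re-discoveries of already
annotated genes, duplicate copies on unplaced assembly scaffolds,
repeat-derived copies, and opposite-strand "shadow" hits at real loci
(an RNA hairpin's reverse complement also folds, so CMs fire on both
strands). mirseed implements the deterministic post-processing cascade
that removes each class, an operationalized curation of the survivors,
and the downstream naming/coordinate/expression bookkeeping.

## Coordinate model

All intervals are 0-based, half-open, with an explicit `+`/`-` strand.
The tool formats involved disagree (tblout and RepeatMasker `.out` and
GFF3 are 1-based inclusive; BED and chain files are 0-based half-open;
minus-strand tblout records have seq-from > seq-to), so every conversion
happens at the I/O boundary and nowhere else. Minus-strand hits are
normalized to `start < end` at parse time, which makes all downstream
overlap logic strand-agnostic except where strandedness is the point
(reverse-complement resolution, read counting).

## Filter cascade

Stages run in a fixed canonical order — significance, known-overlap,
unfinished-duplicates, repeat-overlap, reverse-complement — chosen so
that cheap interval filters run before the stage that must extract and
compare sequences. Each stage returns an exact partition of its input
and the report asserts `n_in(k+1) = n_out(k)`.

* **Significance.** `e ≤ e_cutoff` (default 0.01) and
  `score ≥ ⌈log₂(2·G)⌉` bits, the reporting threshold recommended for CM
  database searches scaled to genome size *G* (33 bits at 2.87 Gb). The
  cutoff can be pinned numerically instead of derived.
* **Known overlap.** Any overlap (≥ 1 bp, either strand) with an
  existing annotation removes the hit. Placed early because it needs no
  sequence access; the order relative to the repeat filter is
  configurable in principle but fixed here.
* **Unfinished duplicates.** "Unfinished" sequences are identified by a
  configurable regular expression on the seq_id (default: anything not
  matching `chr<number|X|Y|M>`), since assemblies differ in scaffold
  naming. Duplication means *exact identity* of the extracted,
  strand-corrected precursor — the strictest reading; near-duplicates
  fall to curation later. A scaffold hit loses to any primary-chromosome
  hit with the same sequence, and to a strictly-lower-e-value hit on
  another unfinished sequence. For exact e-value ties between scaffold
  copies, the deterministically smaller `(seq_id, start, end, strand)`
  key survives, so exactly one copy of a tied pair remains.
* **Repeat overlap.** Overlap of ≥ `min_repeat_overlap` bp (default 1)
  with any repeat tract, strand-agnostic.
* **Reverse complement.** Interpreted positionally: hits on the same
  sequence whose intervals overlap on opposite strands conflict. The
  conflict graph's connected components are each resolved to the single
  hit with the smallest e-value (ties: higher bit score, then smallest
  coordinate key). The positional reading matches the both-strand
  failure mode of CM scans; global sequence reverse-complement matching
  is deliberately not used.

Stage idempotence (re-applying a stage to its own output removes
nothing) and monotonicity in the significance cutoffs are asserted by
property tests.

## Hairpin and conservation curation

The upstream criteria are qualitative: a candidate must fold into a
hairpin, and its mature/mature\* regions must be conserved in the family
alignment. mirseed operationalizes both, as an explicit in-package
surrogate for interactive family-curation tooling (whose
precursor-correction moves are out of scope):

* **Folding** is maximum-cardinality nested base pairing (dynamic
  programming, O(n³)) over {AU, UA, GC, CG, GU, UG} with a minimum
  hairpin loop of 3 nt; `N` pairs with nothing. Base-pair maximization
  rather than thermodynamic free energy because the criterion is shape,
  not stability: the optimum is exact, dependency-free, and checkable
  against explicit structure enumeration (the test suite verifies
  equality on hundreds of random sequences of length ≤ 12). Among
  co-optimal structures the traceback deterministically prefers pairing
  the outermost ends over leaving the left end unpaired or bifurcating.
* **Hairpin classification** requires exactly one stem-loop (one
  innermost pair), ≥ 14 pairs and ≥ 50 % of nucleotides paired. A ~72 nt
  precursor with a 22 bp stem satisfies this with margin; tRNA-like
  multi-loop folds and open chains fail.
* **Conservation** is computed after inserting the candidate into the
  family alignment by global alignment to the family's ungapped modal
  consensus (match +1, mismatch −1, gap open −5, extend −1); candidate
  insertions become new all-gap columns for existing rows and member arm
  spans are remapped. The family's arm columns are the columns covered
  by at least half of the members' arm annotations (a deterministic
  majority rule, robust to slightly discordant member spans). The score
  is the fraction of arm columns where the candidate matches the
  members' modal character; the candidate is accepted when the better of
  its mature / mature\* scores reaches `min_conservation` *and* the
  hairpin test passed.

The thresholds (0.75 conservation, 14 pairs, 0.5 paired fraction, loop
≥ 3) are this package's defaults for a step that was interactive in the
original setting; they are surfaced in `CurationParams`, never
hard-coded, and were chosen to separate hairpin-preserving homologs from
composition-matched shuffles with a wide margin. Acceptance is monotone:
relaxing any threshold never rejects a previously accepted candidate.

## Naming

Names follow the miRBase grammar `prefix-base[letter][-copy]`
(typographic dashes normalized to ASCII on ingest, since published
tables mix glyphs). The naming homolog is the family member with the
highest mature-column identity to the inserted candidate (ties: full-row
identity, then lexically smallest name) — a deterministic stand-in for a
manual choice. Collisions follow miRBase convention: identical mature
sequences at distinct loci receive copy indices `-1, -2, …` in genomic
order (a bare pre-existing name implicitly occupies index 1); diverged
matures receive the next free letter variant. When several same-named
loci are assigned in one run, the batch assigner indexes them together
so no bare/indexed mixture arises. Whether a *pre-existing* annotation's
mature matches cannot be decided from a name list alone, so the pipeline
treats an existing same-base name as the identical-mature case; callers
with sequence access can pass the flag explicitly.

Renaming of previously misassigned annotations is strictly table-driven
— the generalization behind individual corrections (index dropped here,
re-familied there) is not inferable from a rule — and the curated rat
table ships as package data (`rno_rename_table.tsv`, 10 entries).
Applying a table is idempotent when, as in the shipped table, no updated
name is also a previous name.

Subtype diagnostics mirror the paralog-lineage analysis used when a new
candidate must be placed into an `a/b` or `-1/-2` split family:
diagnostic columns are those where each lineage is unanimous (non-gap)
and the lineages differ; a candidate is classified by majority vote over
those columns, with ties or majority-gapped candidates reported as
ambiguous.

## Coordinate recovery and liftover

Because curated precursors originate from the scanned genome itself,
exact (or near-exact) ungapped matching suffices to recover coordinates;
a gapped local aligner would add dependencies without changing the
answer. `locate_sequence` scans both strands; mismatch tolerance uses
the pigeonhole principle (k+1 non-overlapping exact seeds of length
⌊L/(k+1)⌋, each extension verified by Hamming distance). Multi-hit
queries (e.g. a survivor whose sequence was also planted on a scaffold)
are reported in full; the pipeline takes the hit overlapping the
originating CM hit and flags the multiplicity, erroring if none
overlaps.

Liftover projects both endpoints through the single highest-scoring
chain that spans the whole interval; both must land in aligned blocks.
Failure is a value with a reason — `no_chain`, `split_across_chains`,
`endpoint_in_gap` — not an error. A `-` destination strand flips
coordinates and strand. Fragmented/partial mapping is out of scope; the
both-endpoints contract is what makes the forward-then-inverse
round-trip property exactly testable. Chain inversion is implemented
for `+`-destination chains (sufficient for round-trip testing); strand
flips themselves are tested directly against hand-built `-` chains.

## Read support

Reads arrive as per-sample BED intervals (upstream alignment is out of
scope). A read supports a precursor when at least `min_fraction`
(default 0.5) of the read overlaps it on the same strand — conventional
small-RNA counting defaults, both configurable, since neither the
overlap fraction nor strandedness is dictated by the setting. A miRNA
counts as detected in a tissue when ≥ `min_reads` (default 1) reads
appear in ≥ `min_samples` (default 1) of that tissue's samples; the
union over tissues is reported alongside per-tissue counts.
Distribution summaries use log(count + 1) to admit zeros on the log
scale used in survey boxplots.

## Synthetic instances

The generator emulates the real inputs at desk scale and writes a
ground-truth manifest. Defaults: 3 chromosomes × 10 kb plus 3
accession-named scaffolds × 3 kb; 5 families × 5 members; precursors of
72 nt = 9 flank + 22 mature arm + 8 loop + (22 + 2 bulge) star arm + 9
flank, echoing the ~70 nt pre-miRNA; members mutated from the consensus
at 10 % outside arms and 2 % inside (arms are the conserved part);
5 planted true candidates (both strands used) and 2–3 decoys per cascade
stage; 75 read libraries (40 thyroid + 35 liver). Flanks and loops are
drawn from {A, C} only so they cannot pair with each other — planted
precursors therefore fold into a single stem-loop by construction, and
every generated family, candidate and decoy is additionally validated at
generation time (folded, classified, curated) with explicit margins:
true candidates must clear conservation by +0.05, conservation decoys
must fall below by −0.10, decoy scores sit ≥ 5 bits or an order of
magnitude in e-value away from the thresholds. Instances are
regenerated-by-draw until the margins hold, so acceptance tests are
never knife-edge; all draws flow from one seed and identical
(params, seed) give byte-identical files.

A separate support mode plants a 55-locus read set realizing an exact
30-both / 5-thyroid-only / 2-liver-only detection pattern (37 union,
35 thyroid, 32 liver) over 40 + 35 samples, with per-sample counts
log-uniform in 1..2000 and antisense noise reads that must never count.

What the generator does *not* emulate: CM score statistics (e-values are
drawn log-uniformly per decoy class, scores anti-correlated with them),
realistic transposon sequence models, read-level sequences, alignment
gaps within generated families (members differ by substitutions only;
gapped insertion is exercised separately in unit tests), and
genome-scale hit counts. Passing end-to-end tests therefore demonstrates
the correctness of the filtering/curation logic under controlled
conditions, not recovery rates on real genomes.

## Numerical and degenerate-input choices

* Folding requires length ≥ min_loop + 2; invalid alphabet is an error.
* All-gap alignment columns score 0 conservation; modal-character ties
  break lexicographically.
* Tie-breaks throughout (duplicate e-values, reverse-complement
  components, homolog ranking, annotation output order) are resolved by
  deterministic lexical keys so reruns are reproducible byte-for-byte.
* `compute_bitscore_threshold` demands a positive genome size; empty hit
  lists produce an all-zero report rather than an error.
* The tblout parser accepts the classic 18-column cmsearch layout
  (trailing description text ignored); which tblout variant an upstream
  scan used is not always recorded, and this choice is documented rather
  than auto-detected.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run on generated instances of
the default size above (20 planted hits per instance; 20 seeds in the
end-to-end test, 3 in the acceptance script), 200–500 random short
sequences for the folding oracle, 100 fuzzed instances per filter-stage
oracle, and 1,000 intervals for the liftover round trip — sizes at which
the brute-force oracles are exact and fast.

## Known limitations

* The curation surrogate does not reproduce interactive curation's
  precursor-correction moves (trimming/extending precursors); a
  candidate is accepted or rejected as extracted.
* Base-pair maximization can over-pair relative to thermodynamic folds;
  the shape classifier (single stem-loop, paired fraction) absorbs most
  of the difference, but borderline real precursors could classify
  differently than under an energy model.
* Letter-variant assignment for pre-existing annotations assumes the
  identical-mature case when only names are available (see Naming).
* Chain inversion is limited to `+`-destination chains.
* Arm-specific (-5p/-3p) mature naming and cross-species ortholog
  inference beyond the provided family membership are out of scope.
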