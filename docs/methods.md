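# Methods

This note documents the models, rules and numerical choices behind each
stage of the pipeline, the assumptions of the synthetic-data generator, and
what the tests do and do not establish about real data.

## Homology engine

The core primitive is an exhaustive full-length substitution-only scan: for
a precursor query of length *m* and identity threshold *t* (default 0.90),
every window of every genome strand with Hamming distance
≤ ⌊(1 − *t*)·*m*⌋ is a hit. We chose a Hamming scan over a seed-and-extend
local aligner deliberately: the acceptance rule is a *full-length* identity
fraction and all mismatch bookkeeping downstream is substitution counting,
which the exhaustive scan reproduces exactly — and which lets a brute-force
window enumeration serve as an exact oracle in the tests. The cost is that
indel-containing homologs are invisible; true loci whose divergence includes
insertions or deletions will be reported `not_found` or found at inflated
mismatch counts. This is a known fidelity limit, accepted in exchange for
exactness and auditability. Heuristic aligners (BLAST-style) can find those
loci but introduce scoring-dependent, non-reproducible tie-breaking that
this pipeline's acceptance criteria cannot express.

Practical details: ambiguity codes in the genome always count as mismatches;
queries with more than 10% non-ACGT characters are rejected; queries shorter
than 18 nt are rejected (they are mature-length, not precursor-length, and
would flood the hit list). Coordinates are 0-based half-open internally,
1-based inclusive in GFF3 and 0-based half-open in BED on export.
Minus-strand annotations store the reverse complement of the genomic window,
so precursor-local offsets are always in precursor sense.

## Acceptance criteria and curation statuses

A precursor is `accepted` only with a unique best-mismatch hit. Two or more
hits tied at the best count give `ambiguous_multihit`; the pipeline never
breaks such ties. Two precursors of one family (identical numeric core after
stripping species prefix, case, letter variants and locus suffixes, i.e.
`mir-29a`/`mir-29b-1` are one family) accepted over overlapping loci are
both demoted to `family_collision`. These flagged rows are the programmatic
stand-in for manual curation: the status report lists every one with its
competing hits, and a curator can promote them; the pipeline itself will
not. An ordered list of genomes generalizes the fallback-assembly idea: a
query is searched in assembly *i*+1 only when assembly *i* did not accept
it.

## Mature placement and arm assignment

A source mature is placed in an accepted target precursor at the
minimum-Hamming same-length offset (ties broken toward the smaller offset
and flagged). Placement succeeds at ≤ 3 mismatches by default —
substitutions between close relatives concentrate outside mature regions,
so observed mature divergence is small, and 3 is the largest value that
keeps a 18–24 nt match unambiguous in practice. The record carries the
*target-side* sequence, so genomic substitutions inside the mature propagate
into the transferred catalog rather than being silently reverted to the
source sequence. The hairpin arm is assigned by the center rule: mature
center in the 5′ half ⇒ `5p`, else `3p`, with a center exactly at the
midpoint assigned `5p` and flagged. No secondary-structure prediction is
involved; for the hairpin geometries in scope the center rule and the fold
agree, and the rule is deterministic.

## Expression quantification

Reads shorter than 18 nt or with mean Phred < 20 are removed; the mean is
compared on the integer score sum (`sum(q) ≥ q_min·n`), so boundary cases
like mean 19.95 are decided exactly, not by float rounding. A read and a
mature match when the shorter is within `max_mm` substitutions of an
equal-length window of the longer with at most 2 nt of overhang. The
2-nt end tolerance reflects universal 3′ isomiR length variability in small
RNA-seq; with exact-length matching a large fraction of genuine miRNA reads
would be discarded and absolute counts would be mapper-artifact dominated.
At `max_mm = 1` only best-distance assignments count (a read with an exact
match is never also credited at distance 1). A read tied between several
mature names at its best distance is credited to each name — per-name
quantitation — and the multi-credited read count is reported in the
accounting so a fractional scheme could be compared. A mature is *expressed*
at ≥ 15 reads combined across libraries (≥, "a minimum of 15"). Expression
analysis downstream (normalization, ranking, concordance) uses the
0-mismatch matrix; the 1-mismatch matrix is computed for the read-accounting
table, where it shows the expected pattern: more mapped reads, essentially
no additional expressed miRNAs.

## TMM normalization

Between-library scaling uses the trimmed mean of M-values. The reference
library is the one whose upper-quartile of library-size-scaled counts is
closest to the mean upper-quartile. For each library, genes positive in
both it and the reference contribute a log2 ratio M and an average log
abundance A; the most extreme 30% of M on each side and 5% of A on each
side are trimmed (rank-based, average ranks on ties); the surviving M are
averaged with inverse delta-method-variance weights
w⁻¹ = (N−y)/(Ny) + (N_r−y_r)/(N_r y_r); the factor is 2 to that weighted
mean, and factors are rescaled to geometric mean 1 (enforced to 1e-9).
Degenerate cases (no shared positive genes, all |M| < 1e-6, non-finite
sums) fall back to a factor of 1. Normalized values are counts per million
of the effective library size (library size × factor). Identical columns
therefore give plain CPM, and an entrywise doubling of one column is fully
absorbed by its library size. An independently coded plain-Python
implementation of the same formula serves as the test oracle at 1e-6.

## Arm profiling and novel-arm discovery

Reads are placed on precursors at their best offsets (exact matching by
default); a read tied across precursors counts for each, consistent with
the expression stage. Arm totals use the read-center rule. Reads whose
center falls within 2 nt of the hairpin midpoint while overlapping both
halves are loop-spanning: counted to their center's arm but flagged, since
no Drosha/Dicer cut-site model is in scope to adjudicate them.

Two thresholds coexist by design: an *annotated* arm counts as expressed
when its mature passes the expression call (≥ 15), while an *unannotated*
arm is called novel only strictly above 15 reads (> 15). The asymmetry
mirrors the two conventions the workflow states for each case; both are
parameters (`expressed_min`, `novel_min`), and the boundary behavior is
pinned by tests. The novel consensus is the modal (offset, length) read
form on the novel arm — ties toward the longer form, then the smaller
offset — and the consensus sequence is taken from the precursor at those
coordinates, so sequencing errors in individual reads cannot enter it.
Suffixless matures (catalog names without `-5p`/`-3p`) inherit the arm of
their placement within their parent precursor(s); disagreeing parents are
flagged and resolved by the majority-read arm.

## RT-qPCR concordance

Assays are matched to matures by target sequence: exact identity first,
else a unique same-length single-substitution match; several equally good
candidates leave the assay unmatched-ambiguous. Detection is mean Ct ≤ 32
across samples, with "Undetermined" wells entering the mean as the TLDA
sentinel Ct 40 — dropping them would bias borderline assays toward
detection; the drop policy exists as a switch for sensitivity analyses.
Duplicate assays for one mature collapse to a single call (detected if any
assay is, i.e. minimum mean Ct). The platform comparison is a set
partition: both = seq ∩ qPCR, qPCR-only = qPCR ∖ seq, seq-only(tested) =
(seq ∩ tested) ∖ qPCR, with the identity |both| + |qPCR-only| = |qPCR|
holding for all inputs.

## Synthetic data: what it emulates, and what it does not

The generator is first-class, tested code. Its defaults are the study
conditions everything downstream is exercised at: 100 precursors of
55–120 nt in a 200 kb i.i.d.-uniform genome, planted identity 0.90–1.00,
5 equal-mismatch decoy copies, 3 shared-locus family pairs, 3 libraries
totalling roughly 200k reads (per-precursor expression log-normal with
log10 mean 2.1, SD 0.8; arm dominance 0.6–0.99; 25% single-arm precursors,
half of which express the unannotated arm; ~12% between-sample log-normal
variability with Poisson counting noise), 1% per-base substitution error,
1% low-quality and 1% short junk spikes, and a Ct model
Ct = 34 − 3.32·log10(count) + N(0, 0.5²) clipped at the sentinel 40. The
uniform background makes planted loci unique with overwhelming probability
at this scale, which is what lets recovery be asserted at 100%. The Ct
intercept places the qPCR detection floor slightly below the 15-read
sequencing threshold, so the two platforms can disagree in both directions
— the qualitative structure any cross-platform comparison shows.

Deliberate biological biases: planted substitutions avoid mature regions
(at most one per mature), reflecting the much stronger selection on mature
sequences than on loops and flanks; family-pair members carry two forced
substitutions in the central third of each mature region so that their
products remain distinguishable at zero mismatches under end-jitter; reads
are 5′-anchored with 0–2 nt of 3′ jitter, matching miRNA biogenesis where
the 5′ end is precisely defined.

Not emulated: indels (by construction, matching the Hamming engine),
adapter/barcode artifacts (reads are assumed pre-trimmed), UMI structure,
position-dependent error profiles, RNA secondary structure, and real
miRNA sequence composition. Consequently, passing recovery tests shows the
pipeline's logic is correct under its own model assumptions — exact
accounting, correct flagging, threshold fidelity — not that the
substitution-only engine would recover every locus of a real genome pair,
where indel divergence and repeat families exist.

Every output is a pure function of the config seed (per-stage child
generators from a seed sequence), so identical seeds give byte-identical
FASTA/FASTQ/tables across runs and platforms.

## Problem sizes in the test suite

Oracle-equivalence suites run 200 random query/genome pairs (genomes mostly
1–8 kb with a few at 60–100 kb), 100 random fuzzy-placement cases and 50
random TMM matrices; parameter recovery runs the full default study
(error-free reads for the exactness assertions). The complete suite runs in
well under a minute on one core; the acceptance script re-runs the default
study in a few seconds.

## Known limitations

* Indel-divergent homologs are not found (see above); on real genome pairs
  the most divergent few percent of loci would need an indel-aware pass.
* The read-to-mature end-tolerance (± 2 nt) is an assumption; absolute
  counts shift with it, though threshold-based calls are robust in the
  tested regime.
* Conservation-tier counts on real catalogs depend on external pinned
  resources; the module is deterministic given those inputs but ships no
  reference data.
* Manual-curation statuses are terminal: the pipeline flags, a human
  promotes.
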