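# Methods

This note documents the models, parameter choices and numerical
conventions behind `fanzorkit`, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Fingerprint classification

The classifier decomposes the full gap-constrained pattern
`DPGx(120,160)ExxxxxxCxxCx(12,18)CxxCx(4,8)D` into its components —
RuvC1 (`D[P|Φ]G`, Φ = I,L,F,W,Y,M), the RuvC2 glutamate, and the
zinc-finger `CxxCx(12,18)CxxCx(4,8)D` — and recombines them so that
partial arrangements get informative categories instead of a bare
no-match.

Conventions that the pattern itself does not fix:

* **Spacer counting.** The 120–160 residues lie strictly between the
  RuvC1 glycine and the glutamate, exclusive of both.
* **Alternative glutamate.** `E` exactly 7 positions before the first ZF
  cysteine (E + six arbitrary residues + C).
* **Canonical glutamate window.** The canonical placement is only
  described as "~50 residues upstream of the ZF"; we use a configurable
  window of 35–65 residues before the first ZF cysteine, and an E at the
  alternative offset never counts as canonical.
* **Multiple candidates.** All (RuvC1, E, ZF) combinations are
  evaluated; the best category under
  FANZOR_LIKE > E_ALT_DPHIG > CANONICAL > AMBIGUOUS > INCOMPLETE wins,
  with the left-most combination breaking ties. AMBIGUOUS is reserved
  for sequences carrying a valid alternative-E arrangement and a valid
  canonical-E arrangement on *different* ZF motifs.
* **Unknown residues.** `X` satisfies wildcard positions but never the
  literal C/D/E/G/P/Φ positions (conservative motif calling).

The classifier is checked against an independent regex-enumeration
oracle on 10^4 random 400-aa sequences plus planted positives (100%
agreement required).

## Iterative profile search

Profile HMMs are replaced by a position-specific scoring matrix with
Laplace-style pseudocounts:

    log_odds[i][a] = log2( ((c_ia + β·q_a) / (N_i + β)) / q_a )

with β = 1 and uniform background q_a = 1/20 by default; columns with
< 50% occupancy are masked. Search is affine-gap local alignment
(Gotoh; gap open −8 bits, extend −1 bit; gap-to-gap transitions allowed;
traceback tie-break diagonal > up > left; the first best cell in
row-major order starts the traceback). The per-round inclusion threshold
is the 0.999 quantile of best-hit scores over ≥ 100 residue-shuffled
decoys, calibrated once on the seed profile and held fixed so hit sets
can only grow. Augmentation adds only the hit's aligned segment in
profile coordinates — insertions relative to the profile are dropped, so
alignment width is constant across rounds. Five rounds by default.

The search DP is validated against a memoized bounded-gap-run path
enumeration (≤ 2 gap openings) on small instances; with −8/−1 penalties
and profiles of ≤ 10 columns the optimum never needs more gap runs.

The homolog-ladder study (analysis 02 and the acceptance run) uses a
100-aa ancestral domain, five seed rows at 5% divergence, 50 database
homologs per rung at 80/60/40/30% identity embedded in 40-aa random
flanks, plus 50 decoys. These sizes were chosen so that round 1 recovers
the 40% rung only partially — the regime in which iterative augmentation
has something to add; at much longer domains the seed profile alone
saturates the ladder and the iteration is invisible.

## Transposon curation

Coordinates are 0-based half-open internally. TSD detection is
exact-match only (the longest k ∈ [2,15] whose flanking k-mers agree);
degenerate TSDs are out of scope. Empty-site verification tests both
excision choices (drop the left or the right TSD copy) for exact
reconstruction. The right-end GG convention for IS607 elements is
element-terminal: the element's first and last dinucleotides are the
crossover GGs.

TIR detection scans all equal-length segment pairs (≥ 8 nt) inside the
50-nt terminal windows, requires a mismatch fraction ≤ 0.2, and ranks
candidates by the alignment-style score *matches − mismatches* (ties:
longer repeat, then smaller offsets). Ranking by raw match count would
let chance complementarity in the adjacent core extend a perfect repeat
while staying under the mismatch cap; penalizing mismatches makes the
planted repeat the optimum. `find_element_copies` is ungapped
seed-and-extend (16-mer seeds, ≥ 90% identity) with 2-kb flank
extension, clipped at contig ends — adequate for curated desk-scale
inputs, not a BLAST replacement.

When only an insertion/empty allele pair is given,
`infer_element_interval` left-aligns the insertion at the longest common
prefix and resolves TSD vs GG-junction framing. Within repeated junction
context the framing is inherently ambiguous (several (element, TSD)
decompositions reconstruct the same empty allele); the inferred framing
is guaranteed consistent (empty-site verification passes) but may differ
from the planted one by the repeat length.

## TAM depletion

Reads are scanned for an exact anchor match (reverse complement searched
if the forward strand lacks it); the TAM is the L = 6 nucleotides
immediately 5′ of the anchor on the anchor's strand. Reads without the
anchor, without full TAM context, with N in the TAM, or with multiple
anchor hits are discarded; a multi-anchor rate > 1% aborts (bad amplicon
design). Frequencies are pseudocounted,
`f(t) = (c_t + 1) / (total + 4^L)`, and the depletion score is
`log2(f_input/f_output)` so depleted motifs score positive and the 5-bit
cutoff selects ≥ 32-fold depletion directly. Logo frequencies are
unweighted over the retained motif strings.

**Counting-noise bias at standard depth.** At 500 000 reads per sample a
64-fold-depleted TAM retains 500000/4096/64 ≈ 1.9 expected output
reads. The log-ratio of such small Poisson counts is biased (Jensen):
the mean planted score is ≈ 5.6 bits rather than the asymptotic 6, and
the score crosses the 5-bit threshold only when the output count is
≤ 2 — probability ≈ 0.69 — so roughly a quarter of genuinely 64-fold
depleted motifs are missed at this depth while precision stays at 1.0.
This is a property of the assay's depth/threshold combination, not of
the scoring: the noise-free check (expected counts plugged into the
formula) recovers log2 of the planted factor to < 0.05 bits, and deeper
depletion or deeper sequencing removes the gap. The acceptance run
reports the honest measured recall.

Normalized CFU is `cfu_double / cfu_single`; zero double-antibiotic
colonies are reported at the detection limit `1/cfu_single` and flagged.

## Co-conservation

Percent identity counts only columns where both rows are non-gap
(identical positions / shared columns × 100); rows with no shared
columns score 0 with a warning. Column trimming keeps columns with
non-gap fraction ≥ 0.9 by default. The co-conservation statistic is the
Pearson (and Spearman) correlation of (identity_A, identity_B) couples
over all unordered element pairs, plus a fixed 20×20 histogram over
[0,100]². The paired-family generator diverges both proteins of an
element from common ancestors by substitution only (sequences stay
trivially aligned); per-element clocks are drawn uniformly from 0.1–0.6
substitutions/site and mixed with coupling c (c = 1: identical draws).
The shuffle control permutes only the nuclease assignment.

## reRNA analysis

Read placement: candidate starts from any exact 12-mer shared with the
locus, accepted at ≤ 2 substitutions over the full read, unique best
placement required (ties discarded as ambiguous), forward strand.
Boundary calling: plateau = median of non-zero coverage; the called
interval is the maximal run ≥ 0.5 × plateau containing the coverage
maximum; other runs are reported as secondary. Extension past a feature
is a signed distance (positive = away from the element). The small-RNA
generator emits full-length transcript copies with Gaussian endpoint
jitter, filtered to a size-selection window (20–400 nt default) —
emulating merged read pairs of one abundant transcript. It does not
model partial degradation, strand errors, sequencing errors or rRNA
background, so boundary precision on real libraries will be set by
biology (ragged ends) rather than by the caller.

Pseudoknot checks operate on user-annotated regions (the 5 nt flanking
the guide vs the apical loop) in antiparallel register; no secondary-
structure prediction is performed. Mutation names like `U-130A` use the
negative-position convention −k = k nucleotides 5′ of the first guide
nucleotide (−1 abuts the guide); the stated reference base is verified
before substituting, and the input's RNA/DNA alphabet is preserved.

## Synthetic data and seeds

Every generator derives child streams as
`numpy.random.default_rng([master_seed, index])`, making each record
reproducible in isolation and every output byte-identical across reruns.
Planted protein families are self-checked against the classifier at
generation time (decoys must classify INCOMPLETE; positives must
classify as their planted category; 100 redraws then error), and
mutations never touch the motif residues that define the class — for
canonical-E positives the residue at the alternative offset is also
protected, so labels remain exact at any mutation rate. Transposon
generation redraws until the planted TSD is unambiguous against its
flanks and the planted TIR is the unique best-scoring repeat (inward
extensions strictly score-losing; planted mismatches ≥ 2 nt from the
repeat tips and ≥ 3 nt apart). Amino-acid background is uniform 1/20;
no indel evolution, codon model, or sequencing-error model beyond
uniform substitution is attempted — so the recovery rates measured here
are upper bounds for real, indel-rich data.

## Problem sizes

The test suite and acceptance script run the fingerprint/oracle
comparison at 10^4 random sequences, TAM depletion at the full 500 000
reads per sample (3 seeds in the acceptance script, 10 in the test),
TSD recovery at 55–100 loci, the search ladder at 250 database
sequences, and co-conservation at 30 elements × 20 seeds; elements are
300–400 nt with 100 nt flanks in bulk runs (the 2-kb flank convention is
exercised in analysis 03). These sizes keep a full run in the order of
a minute while leaving every statistic far from its decision boundary
(except the TAM recall, which is at its noise-determined value).
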