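# Methods

## The circular sequence model

A circRNA is stored as a linear DNA string (U mapped to T, uppercased,
any other character rejected) whose position 0 is the first base
downstream of the back-splice junction. All coordinates are 0-based and
taken modulo the length `L`; an interval spans the junction iff it
covers both `L-1` and `0`. All analyses run on the given strand only:
circRNAs are single-stranded, so three reading frames are searched, not
six. Genomic exon structure, when supplied (BED12), uses 0-based
half-open intervals ordered 5'→3' along the transcript.

Stepping 3 nt around the circle partitions positions into *codon
orbits*. When `3 | L` there are three orbits of period `L` (one per
frame; the frame never shifts under wraparound). When `3 ∤ L`,
`gcd(3, L) = 1`, so a single orbit visits every position once and closes
after `3L` nt; the frame shifts at each junction crossing. The orbit
structure immediately yields the two length laws: a finite ORF can reach
at most `L` nt (divisible case) or `3L` nt (non-divisible case), and the
repeat unit of a rolling-circle ("infinite") ORF is exactly `L` or `3L`.

## ORF calling

For each orbit we locate start codons (default `{ATG}`, configurable)
and stop codons (`TAA/TAG/TGA`, standard genetic code). An orbit with at
least one start and no stop yields one infinite ORF, anchored at the
smallest-position start for determinism, with every other in-orbit start
reported as an inner start. In an orbit with stops, each stop terminates
at most one maximal ORF: among in-frame starts in the arc after the
previous stop, the start farthest from the stop wins and nearer starts
become `inner_starts` (in-frame downstream AUGs, which can also drive
translation).

When the farthest start places the ORF across the junction, we
additionally emit one call from the farthest start that keeps the ORF
junction-free (when one exists). This is deliberate: it makes the set of
junction-free circular calls *identical* to the output of a conventional
linear 3-frame ORF finder with the same farthest-start rule — the parity
a user comparing against a linear tool expects — while still reporting
the full junction-spanning ORF. Without the extra call, any frame whose
first linear stop has an in-frame start upstream across the junction
would lose its linear ORF entirely.

Reported `nt_length` includes the stop codon; this makes the `3L`
maximum exactly attainable (start at the orbit successor of the unique
stop → `L` orbit codons → `3L` nt). `laps` counts junction crossings
while reading the ORF. For infinite calls, one full repeat cycle crosses
the junction exactly `repeat/L` times (1 or 3), and `spans_junction` is
always true — rolling-circle translation necessarily crosses the
junction regardless of where the anchor sits. The default minimum ORF
length is 75 nt (a conventional ORF-finder default), configurable.
Identical peptides arising in different orbits are reported separately;
IRES assignment is positional.

## IRES prediction

Fragments of 174 nt are taken every 20 nt around the circle (154-nt
overlap; windows wrap across the junction by default so that
junction-spanning IRESs remain detectable). Fragmentation exists because
kmer features computed over a whole long sequence dilute a contained
IRES's signal. Each fragment is featurized as global kmer frequencies
for k = 1..4 (340 features, fixed order: ascending k, lexicographic
within k), each count divided by the fragment length. A positive
fragment call means the fragment *contains* an IRES, not that the
fragment is one.

The classifier is a gradient-boosted decision-tree ensemble (xgboost,
`binary:logistic`, single-thread `hist` for determinism) wrapped as a
scikit-learn estimator. Hyperparameter defaults are the grid-search
optimum reported for the native IRES training set: eta 0.03, max_depth
5, scale_pos_weight 8.78, subsample 0.9, colsample_bytree 0.5,
min_child_weight 19, gamma 0, lambda 1, alpha 0. The boosting-round
count (500) and the decision threshold (0.5) are this package's
defaults, both configurable. Training follows a stratified 90/10
train/test split with ten-fold cross-validation on the training portion
(stratification is our choice; unstratified splits can starve a minority
class); the refit model is scored on the held-out 10% by accuracy,
sensitivity and specificity from the contingency table.

Each ORF is assigned the positive fragment nearest *upstream* of its
start codon, measured as the circular distance from the fragment's last
base to the ORF start; "nearest upstream" (rather than nearest in
absolute distance) reflects that an IRES recruits the ribosome 5' of the
start codon. Ties break toward the smaller fragment start, then the
higher score. With no positive fragments the ORF's IRES field is
`None`. Overlapping positive fragments are reported individually, not
merged.

## m6A motifs

All DRACH/RRACH pentamers are enumerated (D = A/G/T, R = G/A, H =
A/C/T on the DNA alphabet), testing every circle position as a motif
start and wrapping up to 4 nt past the junction. Since R ⊂ D, every
RRACH hit is a DRACH hit; hits are classified `BOTH` or `DRACH`
per occurrence. The methylated adenosine is reported at motif offset +2,
the standard convention. Known-site intersection consumes a pre-lifted
genomic table (chrom, 0-based position, strand, assembly tag), requires
matching assembly tags (mismatch is an error) and matching strand
(unless explicitly ignored), and converts in-exon positions to circle
coordinates by walking exons in transcript order. No liftover and no
methylation-likelihood scoring are attempted.

## Conservation

A cross-species pair is conserved when gene symbols match after
case-folding (human/mouse symbols usually differ only by case; no
ortholog mapping is attempted), lengths are identical, and percent
identity is strictly greater than 80. Identity comes from a global
end-to-end alignment (match +1, mismatch −1, linear gap −2; Biopython's
`PairwiseAligner`, first optimal alignment on ties) as matched columns
over alignment columns. Alignment is used even at equal lengths because
an indel pair can outscore positional matching. Both sequences are
assumed linearized at their annotated junctions; no rotational
realignment is performed, and whether the boundary is alignment-based or
positional in other tools is not asserted — this scoring scheme is this
package's own recorded choice.

## Synthetic data

The generators in `circtrans.fixtures` construct inputs with known
truth:

- **ORF fixtures** engineer one codon orbit directly. Filler material is
  chosen so no start or stop codon can occur anywhere except where
  planted: G/C-only filler in the single-orbit (`3 ∤ L`) case, glycine
  `GGN` codons in the frame-stable case (no `A` is ever followed by `T`,
  so no reading phase can contain `ATG`; off-phase stops are harmless in
  start-free orbits). Expected calls are computed from the construction
  arithmetic, independently of the ORF finder.
- **IRES training fixtures** are 174-nt uniform-random fragments;
  positives additionally carry 1 + Bernoulli(0.5) planted copies of each
  of six fixed tetramers in non-overlapping slots (~3× the background
  tetramer frequency). This emulates only the statistical shape of a
  real labelled IRES set — fixed-length fragments with a compositional
  class signal — not real IRES sequence features (no structure, no
  positional grammar), so passing pipeline tests demonstrates that the
  training/evaluation machinery recovers a planted compositional signal,
  not that the model would reach any particular accuracy on real data.
- **Conservation fixtures** mutate a fixed number of distinct positions
  (substitutions only) and re-roll patterns that a gapped alignment
  could partially repair, so the returned identity is exact under both
  gapless comparison and global alignment — which is what makes the
  80%-boundary sweep well-defined.

All generators are seed-deterministic.

## Numerical and operational choices

- xgboost runs single-threaded with `tree_method=hist` and a fixed seed;
  identical data + seed + parameters give bit-identical models, and all
  CLI outputs are byte-deterministic for a fixed seed (stable sort keys,
  4-decimal float formatting, no timestamps).
- Scores and identities are printed with 4 decimals; machine outputs use
  0-based positions, the human-readable summary 1-based.
- Problem sizes used by the test suite and acceptance checks (200 random
  circles of 90–600 nt for linear parity; 400 labelled fragments for the
  classifier; exhaustive `{A,T,G}` circles at L = 9 plus a random sample
  at L = 10 for the length-law sweep; a 75–95% identity sweep at L = 100)
  were chosen as the smallest sizes at which each property is exercised
  across all code paths, including junction wraps in every frame.

## Known limitations

- The classifier's probability calibration inherits
  `scale_pos_weight = 8.78`: trained on balanced data, scores are
  shifted upward, so the 0.5 threshold trades specificity for
  sensitivity. On imbalanced data resembling the native training set the
  weight plays its intended role. The threshold is configurable.
- Near-cognate starts, Kozak context, coding-potential scores and IRES
  secondary structure are out of scope.
- Retraining on the real native IRES set is supported operationally
  (`circtrans ires-train` on any positive/negative FASTA pair) but not
  exercised in the test suite, which uses synthetic fixtures only; the
  printed held-out metrics of a synthetic run say nothing quantitative
  about real-data performance.
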