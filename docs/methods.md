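# Methods

## The model

`mindist` treats pre-miRNA candidate screening as a nearest-neighbor problem
in a fixed feature space rather than as supervised classification. The only
labeled information used is the set of known precursors; no negative class is
postulated. The assumptions are:

* a hairpin's propensity to be recognized by the miRNA-maturation machinery
  is carried by local sequence/structure composition, summarized by triplet
  frequencies over the MFE structure;
* Euclidean proximity in the scaled principal-components space of those
  frequencies tracks sequence/structure similarity as an alignment-based
  clustering would measure it (the concordance module exists to check exactly
  this); and
* known precursors occupy a restricted region of that space, so distance to
  the nearest known precursor ranks candidates by precursor-likeness.

### Triplet encoding

Every nucleotide gets a pairing status from the dot-bracket structure:
0 = unpaired in the stem (bulges, internal loops, dangling ends), 1 = left
side of a pair, 2 = right side, 3 = inside the terminal loop (the unpaired
block enclosed by the innermost base pair). Each of the L−2 windows of three
consecutive positions increments the counter indexed by
`rank(midpoint nucleotide)·64 + prev·16 + cur·4 + next`, with nucleotide
ranks A=0, C=1, U=2, G=3 — a pure labeling convention with no effect on any
distance (tested by index-permutation invariance).

Windows lie fully inside the sequence: no padding, L−2 windows, so the
default `windows` normalization (divide by L−2) yields a vector summing to
exactly 1. A `length` variant (divide by L, sum (L−2)/L) is kept behind a
flag because both normalizations are defensible readings of the
counts-to-frequencies step; they differ by a per-hairpin scalar and the
sum-to-1 form is the default.

Structures must be single stem-loops (exactly one hairpin loop); multibranch
or multi-hairpin structures are rejected rather than heuristically resolved,
because the status alphabet has no symbol for a multiloop.

### Feature space

Dimensions whose raw values are identical across the fitting set (in
practice: all-zero, structurally impossible triplets) are dropped by exact
comparison. The rest are centered and scaled to unit variance (ddof = 1) and
rotated by PCA (numpy SVD). Default retention keeps every component with
eigenvalue > 1e-12, which makes fit+project an isometry of the scaled space —
distances, and hence everything MinDist computes, are invariant to the
rotation. Loadings signs follow the convention "largest-magnitude entry
positive", making refits bit-reproducible. The model is fitted on the union
of candidates and known precursors of the set under analysis; a
`n_components` parameter allows truncation but is off by default.

### Cutoff calibration

Each resampled split takes a fraction *f* of the known pool as reference
(at most one representative per miRNA family), the remaining knowns as
positive test examples and two disjoint equal-size random candidate subsets
as training/test negatives (training negatives are unused by MinDist itself;
the harness keeps them for symmetric comparisons with discriminative
methods). Scores are distances to the nearest reference; a prediction is
positive iff score ≤ c, boundary inclusive. The ROC is evaluated on the grid
of observed scores; the Youden-optimal cutoff c* is the smallest maximizer of
TPR − FPR (ties broken toward fewer false positives). Per-fraction average
optimal cutoffs are fitted by OLS of ln(avg c*) on *f* and evaluated at
*f* = 1 to obtain the operating cutoff. Logging the cutoff (a positive scale
quantity) is the default reading of the log-linear relation; the alternative
(cutoff linear in ln *f*) is available via `form="log-fraction"`.

The average ROC across samples uses right-continuous step interpolation on
the union grid of observed cutoffs; the average operating point is the mean
of per-sample (FPR(c*), TPR(c*)) pairs, which is generally not the optimum of
the averaged curve.

### Concordance and compactness

`proportion_correct` counts members at least as close to their own cluster
centroid as to any other centroid; ties count as correct so that singleton
clusters (member ≡ centroid) are correct, consistent with the centroid
definition. The randomization null keeps every coordinate occupied and
permutes identities only (Fisher–Yates transpositions, a uniformly random
permutation), so the spatial density of the cloud is held fixed. The
concordance test compares observed and shuffled proportions across samples
with Welch's two-sided unequal-variance t test; degenerate zero-variance
groups fall back to an exact-tie convention (p = 1 when means agree).

The compactness test reports the empirical one-sided p-value
(1 + #{null ≤ observed}) / (1 + n_null), bounded below by 1/(1 + n_null), and
additionally a normal approximation from the null mean and SD, because
resampling alone cannot certify astronomically small tails; the two are
labeled separately and the empirical value is primary.

### Genomic filters

Genomic distance is the edge-to-edge gap between intervals (0 when they
overlap or are book-ended), same chromosome only, strand ignored; all
coordinates are 0-based half-open internally (GFF3 converted on read).
The annotation filter removes candidates overlapping (≥ 1 bp) features whose
type normalizes into a configurable incompatible vocabulary (default: exon,
transposon, other non-coding RNA; `transposable_element` and common ncRNA
subtypes are dialect-mapped); introns and unannotated loci are compatible.
The proximity rule keeps candidates within 50 kb (inclusive) of a known
precursor. Genomic-cluster enumeration inside structural clusters has two
modes: precursor-anchored (members within 50 kb of each known anchor; direct
distance-to-anchor by default, single-linkage growth behind a flag) and
candidate-only (single-linkage chaining, anchors not required), with
candidate-only sets that are subsets of anchored output discarded. Cluster
reports give composition (all-known / mixed / all-candidate) and the median
over same-chromosome pairwise gaps.

## Synthetic data

The generator builds stem-loop families whose structures are known by
construction — no folding engine is involved, so every downstream test is
deterministic. A family seed hairpin has a complementary stem
(Watson–Crick, optional G·U at `gu_rate`), per-position bulge insertions at
`bulge_rate`, and a terminal loop of ≥ 3 nt. Family members are mutated
copies: substitutions arrive per position at `mutation_rate`; at paired
positions a fraction `compensatory_fraction` of substitutions co-substitutes
the partner to another Watson–Crick pair (covariation, the hallmark of
structure-conserving RNA evolution), and the remainder, when they break
complementarity beyond G·U, unpair both partners in the emitted structure so
sequence and structure stay consistent. Coordinates are laid out on one
synthetic chromosome per family with configurable inter-member gaps
(defaults 10 kb; mixed 10/60 kb layouts exercise the 50-kb rule in both
directions), unrelated background hairpins (random stem 8–30 nt, loop
3–10 nt) go on a separate chromosome, and exon/transposon/intron features are
planted over recorded candidates.

Default study conditions: 25-bp stems with 7-nt loops (≈ 70-nt hairpins, the
pre-miRNA scale), bulge rate 0.05, within-family divergence 0.02 with
compensatory fraction 0.8. What the generator does **not** emulate:
thermodynamic folding landscapes (structures are asserted, not predicted),
genome-scale base composition, overlapping candidate windows from a real
scan, and annotation dialect noise. Tests passing on these data show the
machinery is correct and that planted signal of the assumed form is
recovered; they do not certify performance on genomic candidate sets, whose
headline numbers depend on data volumes far beyond desk scale.

## Evaluation design choices

* End-to-end recovery is demonstrated on a structure-conserved family
  (compensatory fraction 1.0, divergence 0.004) of 80 members — 50 known,
  30 held out as planted trues — against 190 unrelated background hairpins,
  with cutoff calibration at fractions 5/10/20/50% and 100 resamples per
  fraction. Calibration negatives are drawn from the background candidates:
  in a genome-scale screen the precursor-like fraction of the candidate set
  is negligible, and at desk scale excluding the few planted trues from the
  calibration pool emulates that regime. With independent per-position
  mutation the within-family nearest-neighbor distance distribution acquires
  a heavy tail (a member's distance grows with its private substitution
  count), and the extrapolated cutoff — which tracks the shrinking optimal
  cutoff of ever-larger reference sets — then lands inside the family tail;
  the structure-conserved, low-divergence family is the configuration in
  which family separation genuinely dominates within-family spread.
* Resample counts (100–1000) and dataset sizes (tens of knowns, low hundreds
  of candidates) are chosen so that complete analyses run in seconds while
  the estimators operate in the same regime as the published workflow; the
  `n_samples` parameter scales to the 1000-sample groups of the original
  design unchanged.
* The unit-variance scaling makes rarely populated triplet dimensions
  influential (a dimension occupied by one hairpin contributes ~√n after
  standardization). This is inherent to the method and mostly harmless on
  large candidate sets where all feasible dimensions are well populated, but
  on small inputs distances can be dominated by private triplets; users
  analyzing small sets may prefer `n_components` truncation.

## Known limitations

* Structures are consumed, never computed; an external folding step must
  supply dot-brackets for real data (any tool emitting Vienna format works).
* The single-hairpin restriction excludes multibranch precursor candidates by
  design.
* The empirical compactness p-value cannot go below 1/(1 + n_null); the
  normal approximation extrapolates beyond that and should be read as an
  approximation, not an exact tail probability.
* The log-linear cutoff extrapolation is a modeling choice; when the
  per-fraction trend is not log-linear the extrapolated cutoff inherits the
  misfit (the reported R² flags this).
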