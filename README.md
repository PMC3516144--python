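# mindist

Minimum-distance screening of pre-miRNA hairpin candidates in a
triplet-encoded principal-components feature space.

Single-genome scans for microRNA precursors produce hundreds of thousands of
stable stem-loop candidates — far too many for sequence/structure alignment
and clustering, and far too many for experimental validation. `mindist`
implements a lightweight alternative: summarize every hairpin by a fixed-size
sequence/structure feature vector, place candidates and known precursors in a
common coordinate system, and keep the candidates that lie close to known
precursors, followed by annotation and genomic-proximity filters.

The pipeline:

1. **Triplet encoding.** Each position of a stem-loop gets a pairing status
   from its dot-bracket structure: `0` unpaired in the stem, `1`/`2`
   left/right side of a base pair, `3` terminal loop. A sliding window of
   length 3 maps each window to one of 4 × 4³ = 256 counters keyed by the
   midpoint nucleotide and the status triple; counts are normalized so the
   vector sums to 1.
2. **Feature space.** Dimensions with zero variance (structurally impossible
   triplets) are dropped, the rest are scaled to unit variance, and a PCA
   gives linearly independent coordinates. With all components retained the
   map is an isometry, so distances do not depend on the rotation.
3. **MinDist classification.** A candidate's score is its Euclidean distance
   to the nearest known precursor; it is accepted when the score is at most a
   maximum-distance cutoff *c*. The cutoff is calibrated by resampling: a
   fraction of the known pool (one representative per miRNA family) serves as
   reference, the remaining knowns and equal-size candidate samples form the
   test set, and the Youden index *J* = max(TPR − FPR) picks the optimal
   cutoff *c\** per sample. Average optimal cutoffs follow a log-linear trend
   in the training fraction, which is extrapolated to fraction 1.0 to obtain
   the operating cutoff for the full reference set.
4. **Genomic filters.** Candidates overlapping exons, transposons or other
   non-coding RNAs are removed (introns and unannotated loci are kept), and
   the survivors can be restricted to loci within 50 kb of a known precursor
   — the classic metazoan miRNA genomic-cluster arrangement — with an
   enumerator for putative genomic clusters inside structural clusters.

Concordance diagnostics (proportion of correct assignments against an
external structural clustering, identity-randomization nulls, and a
compactness test for the known precursors) quantify how well feature-space
geometry reflects sequence/structure similarity.

## Worked example

Everything below runs on synthetic data with planted ground truth: one
structure-conserved hairpin family (50 members labeled known, 30 held out as
"true" candidates) among 190 unrelated stem-loops.

```python
import mindist as md

spec = md.FamilySpec(n_families=1, members_per_family=80, stem_length=25,
                     loop_length=7, bulge_rate=0.05, mutation_rate=0.004,
                     fraction_known=50/80, compensatory_fraction=1.0, seed=1)
data = md.generate_dataset(spec, n_background=190, plant_annotations=False)

vectors, _ = md.encode_batch(data.records)          # 270 x 256 table
space = md.fit_feature_space(vectors)
coords = space.transform(vectors)

known = data.known_ids
background = [r.id for r in data.records if r.family is None]
model, per_fraction = md.calibrate_cutoff(coords, known, background,
                                          fractions=(0.05, 0.1, 0.2, 0.5),
                                          n_samples=100, seed=7)

candidates = data.candidate_ids
scores = md.min_distance(coords.loc[candidates].to_numpy(),
                         coords.loc[known].to_numpy())
selection = md.select_candidates(dict(zip(candidates, scores)),
                                 model.extrapolated_cutoff)
```

Output:

```
270 hairpins -> 60 informative triplet dimensions -> 47 principal components
fraction 0.05: mean J = 1.000, mean c* = 1.458
fraction  0.1: mean J = 1.000, mean c* = 1.429
fraction  0.2: mean J = 1.000, mean c* = 1.359
fraction  0.5: mean J = 1.000, mean c* = 1.191
log-linear fit R^2 = 0.999, extrapolated cutoff = 0.951
accepted 28/220 candidates (12.7%)
```

A mean Youden index of 1.0 says every resampled split separated held-out
knowns from background perfectly; the log-linear fit of the average optimal
cutoff against the training fraction (R² = 0.999) extrapolates to an
operating cutoff of 0.95, which accepts 28 of 220 candidates — all 28 from
the planted family (28/30 of the planted trues, no background).

The same pipeline is available from the shell:

```bash
mindist simulate --outdir data --seed 1 --n-background 50
mindist encode --in data/hairpins.vienna --out vectors.tsv
mindist fit-space --vectors vectors.tsv --out space.json
mindist project --model space.json --vectors vectors.tsv --out coords.tsv
mindist classify --coords coords.tsv --known data/known_ids.txt \
    --cutoff auto --out selection.tsv
mindist filter --candidates data/hairpins.vienna --candidates-bed data/loci.bed \
    --annotation data/annotation.gff3 --known-bed data/loci.bed --out filtered.txt
```

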