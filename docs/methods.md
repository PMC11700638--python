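# Methods

## Model and assumptions

`emobody` estimates emotion–body associations from distributional statistics
alone. The underlying assumptions are:

- **Proximity is association.** A corpus without punctuation (Akkadian has
  none) is segmented implicitly by a symmetric token window; words that
  appear within *w* tokens of each other are treated as related. Small
  windows limit false collocates that span sentence or line breaks.
- **PMI isolates statistical surprise.** The pointwise mutual information
  of a pair compares its joint frequency with what independent occurrence
  would predict; 0 means independence, negative means repulsion. Because
  marginal frequencies cancel, PMI measures association *strength* rather
  than raw frequency.
- **Low-rank structure is signal.** Truncating the SVD of the (clamped) PMI
  matrix to *k* dimensions keeps the dominant co-occurrence structure and
  discards sampling noise. Word similarity is the cosine between the
  `U_k S_k` rows. This is a second-order notion: two words are similar when
  they co-occur with the same words, not merely with each other.
- **Body maps are a readout.** Painting each body word's voxel parts with
  its cosine to a target emotion turns the vector space into an
  interpretable anatomical image; no additional inference happens there.

## Parameters

| Parameter | Default | Units | Role |
| --- | --- | --- | --- |
| `window_size` | 3 | tokens per side | co-occurrence window; does not cross document boundaries |
| `min_count` | 1 | occurrences | words below this are removed from the vocabulary before counting |
| `threshold` | 5 | bits | PMI scores ≤ −threshold are zeroed (no association) |
| `shift_type` | 0 | — | clamp semantics above; other shift variants are rejected, not guessed |
| `dimensions` (*k*) | 60 | — | truncated-SVD rank |
| grid | 141 × 101 × 348 | voxels | width × depth × height of the body volume |
| `sigma` | 2 | voxels | isotropic Gaussian smoothing |
| `kernel` | 9 | voxels | truncated kernel size (9 × 9 × 9) |
| output | 631 × 1562 | pixels | upscaled 2D map (width × height) |
| `cut_fraction` | 0.7 | — | cluster threshold as a fraction of the maximum merge height |
| `top_k` | 5 | rows | ranked body-word table length |

The embedding defaults follow the regime the method was developed for:
window 3 balances recall against cross-sentence noise in an unpunctuated
corpus, `min_count` 1 keeps every attested word at the counting stage, the
−5 clamp removes the unreliable strongly-negative tail (which otherwise
dominates the factorization), and 60 dimensions is appropriate for corpora
on the order of 10⁴–10⁶ tokens.

## Conventions pinned by this implementation

Several bookkeeping details that equivalent implementations vary on are
fixed here, with tests pinning each:

- **Counting.** Every ordered position pair (i, j), i ≠ j, |i − j| ≤ w
  contributes one directed target→context observation; the stored matrix is
  the symmetrized total (a single adjacency of distinct words gives
  C[a,b] = C[b,a] = 2). PMI is invariant to this factor since C, T and the
  marginals scale together. Self-pairs land on the diagonal; repetitive
  formulae are a real property of the target corpora. Empty (`_`) tokens
  occupy window slots but form no pairs — a broken sign still consumes
  textual distance.
- **PMI base.** Base-2 logarithms, so the two-token worked example
  ([a, b] alone in the corpus) lands exactly on 1.0 bit. Cosines are
  unaffected by the base up to the clamp.
- **Marginals.** Row (target) sums of the symmetric count matrix; with
  symmetric counting, row and column marginals coincide. A consequence
  worth knowing: every word's best PMI entry is ≥ 0 (its conditional
  allocation must meet some partner's share), so fully-empty rows arise
  from aggressive thresholds or degenerate inputs rather than from the
  default configuration; `drop_empty_rows` guards the contract regardless.
- **SVD.** Word vectors are rows of `U_k S_k` (the classical LSA scaling,
  which preserves the PMI row Gram matrix — hence all row cosines — at full
  rank). Each singular vector's sign is fixed by making its first nonzero
  loading positive, so identical inputs give bit-identical `.vec` files.
- **Extreme merging.** Where painted parts overlap, the voxel keeps the
  value of maximal absolute magnitude with its sign; exact-magnitude ties
  break toward positive and are logged (they are measure-zero on real
  cosines but must be deterministic).
- **Projection order.** Smooth in 3D first (zero-padded borders; the body
  sits interior to the grid so border effects are negligible), then take
  the signed extreme along the anterior–posterior axis per (x, z) column,
  then upscale bilinearly. A depth-average projection is available as an
  alternative reading (`projection="average"` / `--average-projection`).
  Neither smoothing nor bilinear interpolation can amplify: the 2D map's
  maximum magnitude is bounded by the largest similarity painted.
- **WPGMA.** "Weighted average" linkage: on merging clusters i and j,
  `d(k, i∪j) = (d(k,i) + d(k,j))/2`. Ties in the closest-pair choice break
  by the smallest cluster-index pair. The cut joins only merges strictly
  below `fraction × max height` (configurable to inclusive). Dendrogram
  leaf order places, at every node, the child containing the smaller
  minimum original index first. The test suite verifies the merge heights
  and cophenetic structure against an independent linkage implementation on
  random matrices.
- **Category vectors.** The mean-vector mode (arithmetic mean of member
  vectors) is the default; a per-word-average mode builds each member's map
  and averages voxelwise. Members missing from the space are skipped with a
  log entry; a category whose members all vanished raises. An exactly
  antiparallel membership yields a zero mean — reported as a degenerate
  category warning and refused downstream by the cosine.

## The synthetic data

`synthetic.PlantedSpec` generates corpora with known structure: a Zipf-like
background vocabulary (exponent 1.1 — natural corpora are heavily skewed), a
5% sprinkling of `_` tokens standing in for broken signs, and planted events
in which an emotion word is emitted and, with the category's affinity
probability, its affine body word is placed uniformly within the ±3 window.
Defaults are 80 documents × 200 tokens (≈16k tokens), a 300-word background
vocabulary and 200 events per category. The background vocabulary is
deliberately much larger than the 60 embedding dimensions so the truncation
actually compresses — the regime the method assumes; with V ≈ k the "truncated"
SVD is a rotation and nothing is denoised.

What the generator does *not* emulate: grammar, genre structure, formulaic
repetition beyond frequency skew, polysemy, or graded co-occurrence
contexts. Consequently, passing recovery tests show that the pipeline turns
within-window planted contiguity into top-ranked cosine similarity and into
correctly-located map extremes; they do not show robustness to the
philological noise of real corpora.

A known property of the method surfaces clearly on synthetic data: because
PMI cancels marginal frequency, *graded* affinity magnitudes (e.g. one
category planted on three body words at rates 1.0/0.5/0.1) are only weakly
ordered by cosine similarity — the embedding sees association profiles, not
rates. Recovery testing therefore uses designs whose ground truth is
profile-shaped: one-to-one plantings for ranking, and groups sharing planted
body words for cluster separation.

## Numerical choices and degenerate inputs

- Gaussian smoothing truncates at `(kernel // 2) / sigma` standard
  deviations so the discrete kernel is exactly `kernel³`; even or <3 kernel
  sizes are rejected.
- Bilinear upscaling maps corner pixels to corner voxels (`linspace` over
  the source index range); the skin silhouette is upscaled the same way and
  thresholded at 0.5.
- The voxel inside-test is parity ray casting along +y at voxel centers;
  ray positions carry distinct tiny x/z offsets so rays generically miss
  triangle edges and vertices (no double counting on shared edges).
  Triangles degenerate in the (x, z) projection — walls parallel to the ray
  — are skipped; their crossings are carried by the adjacent faces.
- Non-watertight meshes get one hole-filling repair attempt; failure raises
  an error naming the part. Meshes outside the grid yield an empty mask and
  a warning.
- OBJ atlases are registered by fitting the skin mesh's bounding box into
  the grid with uniform scale, centered, with a 2-voxel margin; the skin
  mesh is mandatory.
- Zero-norm vectors are refused by `cosine_similarity` and by
  `distance_matrix` (naming the offending id).
- `.vec` files round-trip exactly: values are written with `repr`, i.e.
  shortest-exact float formatting.

## The primitive atlas

Twenty part masks (head, skull, liver, heart, stomach, paired kidneys, five
vertebrae, paired arms/hands/legs/feet) are placed as analytic solids at
anatomically plausible positions on the standard grid, joined by IS-A and
PART-OF edges (e.g. *kidney_left* IS-A *kidney*; *vertebra_i* PART-OF
*spine*; *hand_left* PART-OF *arm_left*) under group nodes, with a synonym
override table (e.g. *backbone* → *spine*). Left/right pairs are exact
mirror images about the mid-sagittal plane; every part lies inside the skin
envelope; each mask's voxel count matches its analytic volume to within a
few percent. The construction is deterministic. It is a geometric stand-in
for real anatomical mesh libraries: adequate for testing part resolution,
painting, overlap merging and projection; not anatomically realistic.

## Limitations

- Association, not activation: co-occurrence cannot distinguish "my legs
  felt weak" from "my legs felt strong"; maps should not be read as
  activation/deactivation topographies.
- Female anatomy and diffuse "interior of the torso" terms are excluded
  from mapping (the body lexicon carries explicit exclusion reasons:
  whole-body systems, unsupported anatomy, ambiguous general terms); the
  atlas interface accepts user meshes so such terms can be added later.
- Boolean multi-category flags are loaded and exposed but all downstream
  analysis keys on the primary category only.
- Results at corpus scale (10⁶ tokens, full anatomical hierarchies)
  require external data; the desk-scale suite validates the machinery, the
  conventions and the planted-signal behaviour, not corpus-level findings.
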