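# emobody

**Bodily maps of emotion semantics from lemmatized text corpora.**

`emobody` implements a pipeline for quantifying how words for emotions and
words for body parts co-occur in a lemmatized historical corpus, and for
projecting those associations onto a human body template — the textual
analogue of the "bodily sensation maps" used in affective neuroscience. It
was designed for Akkadian (Neo-Assyrian) corpora in Oracc's
`lemma[guideword]EPOS` token notation, but any corpus expressible in that
dialect works. It is aimed at computational historians, Assyriologists and
affective-neuroscience researchers who want a reproducible, data-driven view
of embodied emotion language.

## The method

1. **Co-occurrence.** For every pair of non-empty tokens within *w* = 3
   positions of each other (windows never cross document boundaries; broken
   `_` tokens occupy slots but form no pairs) a symmetric count matrix *C*
   is accumulated.
2. **Pointwise mutual information.**
   `PMI(a,b) = log₂[ (C_ab/T) / ((R_a/T)(R_b/T)) ]`
   with row marginals *R* and total *T*; scores ≤ −5 (the negative
   threshold, including −∞ for never-co-occurring pairs) are treated as no
   association and zeroed. Words whose whole row is zeroed get empty vectors
   and are discarded.
3. **Truncated SVD.** The clamped PMI matrix is factorized and each word
   is represented by its row of `U_k S_k` (*k* = 60), which preserves row
   cosines at full rank and denoises below it.
4. **Body maps.** For an emotion word — or the mean vector of one of the 18
   emotion categories — the cosine similarity to every included body word is
   computed. Each body word's atlas parts (resolved through IS-A / PART-OF
   hierarchies, e.g. *backbone* → spine → the vertebrae) are painted with
   that value in a 141 × 101 × 348 voxel grid; overlaps keep the value of
   largest magnitude, sign preserved. The map is smoothed with a 9×9×9
   Gaussian kernel (σ = 2 voxels), reduced front-to-back by the signed
   extreme, upscaled to 631 × 1562 and masked by the skin outline
   (positive → red, negative → blue, zero → black).
5. **Clustering.** Category-mean vectors are clustered with weighted
   average linkage (WPGMA) on cosine distance `d = 1 − cos`; the tree is cut
   at 70% of the maximum merge height; member words are clustered the same
   way within each category.

A synthetic-corpus generator plants known emotion–body affinities inside the
co-occurrence window, and a primitive-solid body atlas (spheres, ellipsoids,
boxes, cylinders at anatomically plausible positions, plus a skin envelope)
stands in for external mesh libraries, so the whole pipeline runs and is
testable offline. Real OBJ meshes and user lexicon CSVs plug into the same
interfaces.

## Worked example

```sh
python examples/02_embeddings_from_planted_corpus.py
```

```
corpus: 80 docs, 16000 tokens
embedding space: 315 words, k=60
category 3a (planted on liver): liver=+0.686, heart=+0.158, head=+0.146
category 2 (planted on heart): heart=+0.683, head=+0.124, liver=+0.102
category 4 (planted on head): head=+0.696, heart=+0.214, liver=+0.148
```

Each line ranks the body words by cosine similarity to a category's mean
vector. The corpus planted category 3a next to *liver*, 2 next to *heart*
and 4 next to *head* (affinity 1, 200 events each); the pipeline recovers
every planted pairing as the clearly positive top-ranked body word, while
unplanted pairs sit near zero. `examples/03_body_maps.py` renders the
corresponding 631 × 1562 body-map PNG and `examples/04_clustering.py` shows
two planted category groups merging at cosine distance ≈ 0.26–0.28 within
groups and splitting into exactly two clusters at the 70% cut.

The same steps are available as a thin CLI:

```sh
emobody simulate --seed 42 --out run/
emobody embed   --corpus run/corpus --out run/vecs.vec
emobody map     --vec run/vecs.vec --emotions run/emotions.csv \
                --body run/body.csv --atlas synthetic --out run/maps/
emobody cluster --vec run/vecs.vec --emotions run/emotions.csv --out run/clust/
```

Every artifact directory contains a `provenance.json` with the resolved
configuration and input hashes; identical inputs reproduce identical
artifacts.

## Layout

| Path | Contents |
| --- | --- |
| `src/emobody/corpus.py` | token/corpus dialect, metadata filtering |
| `src/emobody/embeddings.py` | counts → PMI → truncated SVD → `.vec` |
| `src/emobody/lexicon.py` | emotion/body lexicons, 18-category scheme |
| `src/emobody/atlas.py` | voxel atlas, parity ray casting, hierarchy matching |
| `src/emobody/mapping.py` | similarity tables, painting, projection, PNG |
| `src/emobody/clustering.py` | WPGMA, threshold cut, leaf order, Newick |
| `src/emobody/synthetic.py` | planted-corpus generator |
| `src/emobody/cli.py` | `emobody` command-line wrapper |
| `examples/` | narrative scripts, one per capability |
| `docs/methods.md` | model, parameters, design choices, limitations |
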