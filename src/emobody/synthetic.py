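"""Synthetic corpora, lexicons and planted emotion–body affinities.

The generator emulates the statistical structure the analysis assumes: a
background stream of Zipf-distributed filler tokens (natural corpora are
heavily skewed toward a few frequent words), a sprinkling of ``_`` empty
tokens standing in for broken or unlemmatizable signs, and *planted events*
in which an emotion word from a category is emitted and, with the category's
affinity probability, its affine body word is placed uniformly within the
co-occurrence window.  Affinities are the ground truth against which the
recovered emotion–body rankings are scored.

Everything is driven by a mandatory seed: the same spec yields byte-identical
corpora; distinct seeds yield distinct corpora.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .corpus import Corpus, Document, parse_token
from .lexicon import (
    CATEGORY_IDS,
    BodyEntry,
    EmotionEntry,
    LexiconError,
)

logger = logging.getLogger(__name__)


def body_word_key(part: str) -> str:
    """Token key of the synthetic body word planted on an atlas part."""
    return f"{part}[{part}]N"


def emotion_word_key(category: str, index: int) -> str:
    return f"emo-{category}-{index}[emotion-{category}-{index}]V"


@dataclass
class PlantedSpec:
    """Ground-truth description of a synthetic corpus.

    ``affinity[c, b]`` is the probability that a token of category
    ``categories[c]`` is accompanied, within ±``window`` tokens, by body word
    ``body_parts[b]``.  Body words are named after primitive-atlas parts so
    the generated lexicons resolve directly against
    :func:`emobody.atlas.make_primitive_atlas`.
    """

    categories: dict[str, tuple[str, ...]]  # category id -> emotion word keys
    body_parts: tuple[str, ...]  # primitive-atlas part names
    affinity: np.ndarray  # (n_categories, n_body) in [0, 1]
    seed: int
    events_per_category: int = 200
    background_vocab: int = 300
    n_docs: int = 80
    doc_length: int = 200
    window: int = 3
    empty_fraction: float = 0.05
    zipf_exponent: float = 1.1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.affinity = np.asarray(self.affinity, dtype=np.float64)
        if self.affinity.shape != (len(self.categories), len(self.body_parts)):
            raise ValueError(
                f"affinity shape {self.affinity.shape} does not match "
                f"({len(self.categories)}, {len(self.body_parts)})"
            )
        if np.any(self.affinity < 0) or np.any(self.affinity > 1):
            raise ValueError("affinities must lie in [0, 1]")
        if not 0 <= self.empty_fraction < 1:
            raise ValueError("empty_fraction must lie in [0, 1)")

    @property
    def category_ids(self) -> list[str]:
        return list(self.categories)

    def to_json(self) -> str:
        d = asdict(self)
        d["affinity"] = self.affinity.tolist()
        d["categories"] = {k: list(v) for k, v in self.categories.items()}
        d["body_parts"] = list(self.body_parts)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PlantedSpec":
        d = json.loads(text)
        d["categories"] = {k: tuple(v) for k, v in d["categories"].items()}
        d["body_parts"] = tuple(d["body_parts"])
        d["affinity"] = np.asarray(d["affinity"], dtype=np.float64)
        return cls(**d)


def default_spec(
    seed: int,
    category_ids: Sequence[str] = ("3a", "2", "4"),
    parts: Sequence[str] = ("liver", "heart", "head"),
    words_per_category: int = 4,
    affinity: np.ndarray | None = None,
    **overrides,
) -> PlantedSpec:
    """One-to-one planting: category i pairs with part i at affinity 1."""
    if affinity is None:
        affinity = np.eye(len(category_ids), len(parts))
    categories = {
        cid: tuple(emotion_word_key(cid, j) for j in range(words_per_category))
        for cid in category_ids
    }
    return PlantedSpec(
        categories=categories,
        body_parts=tuple(parts),
        affinity=affinity,
        seed=seed,
        **overrides,
    )


def separated_groups_spec(seed: int) -> PlantedSpec:
    """Two well-separated category groups sharing body words within groups.

    Categories 3a/3c are both planted on liver *and* heart, categories 2/4 on
    head *and* stomach, all at affinity 1.  Sharing two body words gives the
    within-group category means a strong common component, so stage-1
    clustering should split the four categories into exactly two clusters.
    """
    affinity = np.array(
        [
            [1.0, 1.0, 0.0, 0.0],
            [1.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 1.0],
            [0.0, 0.0, 1.0, 1.0],
        ]
    )
    return default_spec(
        seed=seed,
        category_ids=("3a", "3c", "2", "4"),
        parts=("liver", "heart", "head", "stomach"),
        affinity=affinity,
    )


def generate_corpus(spec: PlantedSpec) -> Corpus:
    """Generate the planted corpus (deterministic under the spec's seed)."""
    rng = np.random.default_rng(spec.seed)
    bg_words = [f"bg{i}[background-{i}]N" for i in range(spec.background_vocab)]
    ranks = np.arange(1, spec.background_vocab + 1, dtype=np.float64)
    probs = ranks**-spec.zipf_exponent
    probs /= probs.sum()

    docs_keys: list[list[str]] = []
    planted: list[set[int]] = []
    for di in range(spec.n_docs):
        idx = rng.choice(spec.background_vocab, size=spec.doc_length, p=probs)
        keys = [bg_words[i] for i in idx]
        empties = rng.random(spec.doc_length) < spec.empty_fraction
        for pos in np.flatnonzero(empties):
            keys[pos] = "_"
        docs_keys.append(keys)
        planted.append(set())

    cat_ids = spec.category_ids
    for ci, cid in enumerate(cat_ids):
        members = spec.categories[cid]
        for _event in range(spec.events_per_category):
            doc = int(rng.integers(spec.n_docs))
            pos = None
            for _try in range(20):
                cand = int(rng.integers(spec.doc_length))
                if cand not in planted[doc]:
                    pos = cand
                    break
            if pos is None:
                logger.info("no free slot for an event in doc %d; skipped", doc)
                continue
            docs_keys[doc][pos] = members[int(rng.integers(len(members)))]
            planted[doc].add(pos)
            for bi, part in enumerate(spec.body_parts):
                if rng.random() >= spec.affinity[ci, bi]:
                    continue
                offsets = [
                    pos + o
                    for o in range(-spec.window, spec.window + 1)
                    if o != 0
                    and 0 <= pos + o < spec.doc_length
                    and (pos + o) not in planted[doc]
                ]
                if not offsets:
                    logger.info("window placement impossible; body token skipped")
                    continue
                target = offsets[int(rng.integers(len(offsets)))]
                docs_keys[doc][target] = body_word_key(part)
                planted[doc].add(target)

    documents = [
        Document(
            id=f"doc{di:03d}",
            language="Akkadian",
            period="Neo-Assyrian",
            tokens=[parse_token(k) for k in keys],
        )
        for di, keys in enumerate(docs_keys)
    ]
    return Corpus(documents=documents)


def generate_lexicons(spec: PlantedSpec) -> tuple[list[EmotionEntry], list[BodyEntry]]:
    """Emotion/body lexicon tables consistent with the planted spec.

    Category keys already in the 18-id scheme are used as-is; other labels are
    mapped, in order, onto the scheme (more than 18 categories is an error).
    Body words are named after primitive-atlas parts, so every included entry
    resolves through the synthetic atlas hierarchy.
    """
    keys = spec.category_ids
    if len(keys) > len(CATEGORY_IDS):
        raise LexiconError(
            f"{len(keys)} categories exceed the {len(CATEGORY_IDS)}-category scheme"
        )
    if all(k in CATEGORY_IDS for k in keys):
        mapping = {k: k for k in keys}
    else:
        mapping = {k: CATEGORY_IDS[i] for i, k in enumerate(keys)}
    emotions = [
        EmotionEntry(word=w, primary_category=mapping[cid])
        for cid in keys
        for w in spec.categories[cid]
    ]
    bodies = [
        BodyEntry(word=body_word_key(p), gloss=p, atlas_parts=(p,))
        for p in spec.body_parts
    ]
    bodies.append(
        BodyEntry(word="skin[skin]N", gloss="skin", atlas_parts=("skin",), mask_only=True)
    )
    return emotions, bodies


def expected_affinity_ranking(spec: PlantedSpec) -> dict[str, list[str] | None]:
    """Oracle ranking of body words per category by planted affinity.

    Rows whose affinities are all equal carry no ranking information and are
    reported as ``None`` (declared tied); otherwise body word keys are sorted
    by descending affinity with lexicographic tie-breaking.
    """
    out: dict[str, list[str] | None] = {}
    for ci, cid in enumerate(spec.category_ids):
        row = spec.affinity[ci]
        if np.allclose(row, row[0]):
            out[cid] = None
            continue
        keys = [body_word_key(p) for p in spec.body_parts]
        out[cid] = [k for _a, k in sorted(zip(-row, keys), key=lambda t: (t[0], t[1]))]
    return out
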