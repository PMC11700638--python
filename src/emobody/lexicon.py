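"""Emotion and body lexicons: the 18-category scheme, entry validation and
category-mean vectors.

The emotion scheme follows the 13 cross-culturally studied emotion fields,
three of which are split into sub-categories (1a–c sadness/distress/suffering,
3a–c happiness/schadenfreude/pleasure, 6a–b love/desire), giving 18 categories
in total.  Each lexicon entry carries a *primary* category — which drives all
visualization and clustering — plus Boolean flags for every category the word
can express (a word like ulṣu[pleasure]N is flagged for both Pleasure and
Sexual arousal).  The flags are loaded and exposed but deliberately unused
downstream.

Body entries map an Akkadian word to named atlas parts; words referring to
whole-body systems (veins), to anatomy absent from the atlas, or too ambiguous
to place (libbu, the general "inside of the torso") are kept in the table but
flagged excluded with a reason.  The skin entry is mask-only: it outlines the
body in rendered maps and is never painted with a similarity value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import parse_token
from .embeddings import EmbeddingSpace

logger = logging.getLogger(__name__)

#: (id, label, parent field) for the 18 emotion categories.
CATEGORY_TABLE: list[tuple[str, str, int]] = [
    ("1a", "Sadness", 1),
    ("1b", "Distress", 1),
    ("1c", "Suffering", 1),
    ("2", "Anger", 2),
    ("3a", "Happiness", 3),
    ("3b", "Schadenfreude", 3),
    ("3c", "Pleasure", 3),
    ("4", "Fear", 4),
    ("5", "Contempt", 5),
    ("6a", "Love", 6),
    ("6b", "Desire", 6),
    ("7", "Disgust", 7),
    ("8", "Sympathy", 8),
    ("9", "Envy", 9),
    ("10", "Pride", 10),
    ("11", "Surprise", 11),
    ("12", "Shame", 12),
    ("13", "Sexual arousal", 13),
]

EXCLUSION_REASONS = {
    "whole-body-system",
    "female-anatomy-unsupported",
    "ambiguous-general-term",
    "none",
}

_TRUTHY = {"yes", "y", "true", "1"}
_FALSY = {"no", "n", "false", "0", ""}


class LexiconError(ValueError):
    """Invalid lexicon content (unknown category, duplicates, bad flags)."""


class CategoryUnavailableError(LexiconError):
    """No member of the requested category has a vector in the space."""


@dataclass(frozen=True)
class EmotionCategory:
    id: str
    label: str
    parent_field: int


CATEGORIES: dict[str, EmotionCategory] = {
    cid: EmotionCategory(cid, label, parent) for cid, label, parent in CATEGORY_TABLE
}
CATEGORY_IDS: list[str] = [cid for cid, _, _ in CATEGORY_TABLE]


@dataclass
class EmotionEntry:
    word: str
    primary_category: str
    flags: dict[str, bool] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        parse_token(self.word)  # word key must be a valid token
        if self.primary_category not in CATEGORIES:
            raise LexiconError(f"unknown emotion category: {self.primary_category!r}")
        if not self.flags:
            self.flags = {self.primary_category: True}
        if not self.flags.get(self.primary_category, False):
            raise LexiconError(
                f"{self.word}: primary category {self.primary_category} flag not set"
            )


@dataclass
class BodyEntry:
    word: str
    gloss: str
    atlas_parts: tuple[str, ...] = ()
    excluded: bool = False
    exclusion_reason: str = "none"
    mask_only: bool = False

    def __post_init__(self) -> None:
        parse_token(self.word)
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise LexiconError(f"unknown exclusion reason: {self.exclusion_reason!r}")
        if self.excluded and self.exclusion_reason == "none":
            raise LexiconError(f"{self.word}: excluded entries need a reason")
        if not self.excluded and not self.mask_only and not self.atlas_parts:
            raise LexiconError(f"{self.word}: included entries need >=1 atlas part")


def _parse_bool(value: str, context: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise LexiconError(f"{context}: cannot parse Boolean value {value!r}")


def load_emotion_lexicon(source: IO[str] | str | Path | pd.DataFrame) -> list[EmotionEntry]:
    """Load the emotion lexicon CSV (columns: word, primary_category, one
    Boolean column per category id, optional notes)."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(
        source, dtype=str, keep_default_na=False
    )
    if df.empty and "word" not in df.columns:
        return []
    flag_cols = [c for c in df.columns if c in CATEGORIES]
    entries: list[EmotionEntry] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        word = row["word"].strip()
        if word in seen:
            raise LexiconError(f"duplicate emotion word: {word!r}")
        seen.add(word)
        flags = {
            c: _parse_bool(row[c], f"{word} column {c}") for c in flag_cols
        }
        entries.append(
            EmotionEntry(
                word=word,
                primary_category=row["primary_category"].strip(),
                flags=flags,
                notes=str(row.get("notes", "")).strip(),
            )
        )
    return entries


def load_body_lexicon(source: IO[str] | str | Path | pd.DataFrame) -> list[BodyEntry]:
    """Load the body lexicon CSV (columns: word, gloss, atlas_parts
    semicolon-joined, excluded, reason).  The skin entry is flagged
    mask-only."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(
        source, dtype=str, keep_default_na=False
    )
    if df.empty and "word" not in df.columns:
        return []
    entries: list[BodyEntry] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        word = row["word"].strip()
        if word in seen:
            raise LexiconError(f"duplicate body word: {word!r}")
        seen.add(word)
        parts = tuple(p.strip() for p in row["atlas_parts"].split(";") if p.strip())
        gloss = row["gloss"].strip()
        mask_only = gloss.lower() == "skin" or "skin" in parts
        entries.append(
            BodyEntry(
                word=word,
                gloss=gloss,
                atlas_parts=parts,
                excluded=_parse_bool(row.get("excluded", "no"), word),
                exclusion_reason=(row.get("reason", "none").strip() or "none"),
                mask_only=mask_only,
            )
        )
    return entries


def write_emotion_lexicon(entries: Sequence[EmotionEntry], sink: IO[str] | str | Path) -> None:
    rows = []
    for e in entries:
        row = {"word": e.word, "primary_category": e.primary_category}
        for cid in CATEGORY_IDS:
            row[cid] = "Yes" if e.flags.get(cid, False) else "No"
        row["notes"] = e.notes
        rows.append(row)
    pd.DataFrame(rows).to_csv(sink, index=False)


def write_body_lexicon(entries: Sequence[BodyEntry], sink: IO[str] | str | Path) -> None:
    rows = [
        {
            "word": e.word,
            "gloss": e.gloss,
            "atlas_parts": ";".join(e.atlas_parts),
            "excluded": "yes" if e.excluded else "no",
            "reason": e.exclusion_reason,
        }
        for e in entries
    ]
    pd.DataFrame(rows).to_csv(sink, index=False)


def category_members(
    lexicon: Iterable[EmotionEntry], category_id: str
) -> list[EmotionEntry]:
    if category_id not in CATEGORIES:
        raise LexiconError(f"unknown emotion category: {category_id!r}")
    return [e for e in lexicon if e.primary_category == category_id]


def category_vector(
    space: EmbeddingSpace,
    category_id: str,
    lexicon: Iterable[EmotionEntry],
    mode: str = "mean_vector",
):
    """Mean vector of a category's member words (or the member set itself).

    ``mean_vector`` returns the arithmetic mean of the member vectors — the
    default route for category body maps.  ``mean_of_maps`` instead returns
    the in-space member words so the caller can average per-word body maps
    (the two give similar maps on well-behaved data).  Members without a
    vector are skipped with a log entry; an all-absent category raises
    :class:`CategoryUnavailableError`.  A numerically zero mean (antiparallel
    members) is returned with a degenerate-category warning; the cosine
    computation downstream will refuse it.
    """
    members = category_members(lexicon, category_id)
    present = [e.word for e in members if e.word in space]
    skipped = [e.word for e in members if e.word not in space]
    if skipped:
        logger.info("category %s: %d members missing from space: %s",
                    category_id, len(skipped), skipped)
    if not present:
        raise CategoryUnavailableError(
            f"no member of category {category_id} has a vector in the space"
        )
    if mode == "mean_of_maps":
        return present
    if mode != "mean_vector":
        raise ValueError(f"unknown mode: {mode!r}")
    mean = np.mean([space.vector(w) for w in present], axis=0)
    if np.linalg.norm(mean) <= 1e-12 * max(1.0, float(np.abs(space.matrix).max())):
        warnings.warn(
            f"category {category_id} mean vector is numerically zero "
            "(degenerate category)",
            stacklevel=2,
        )
    return mean


def summarize_counts(
    lexicon: Sequence[EmotionEntry], space: EmbeddingSpace | None = None
) -> pd.DataFrame:
    """Per-category member counts before/after embedding-space exclusion.

    ``count_before`` is the number of lexicon words whose primary category is
    the row's category; ``count_after`` the subset that has a vector in
    ``space`` (equal to ``count_before`` when no space is given).  A ``total``
    row closes the table.
    """
    rows = []
    for cid in CATEGORY_IDS:
        members = [e for e in lexicon if e.primary_category == cid]
        after = (
            sum(1 for e in members if e.word in space) if space is not None else len(members)
        )
        rows.append({"category": cid, "label": CATEGORIES[cid].label,
                     "count_before": len(members), "count_after": after})
    df = pd.DataFrame(rows).set_index("category")
    total = pd.DataFrame(
        [{"label": "total",
          "count_before": int(df["count_before"].sum()),
          "count_after": int(df["count_after"].sum())}],
        index=pd.Index(["total"], name="category"),
    )
    return pd.concat([df, total])


def _data_path(name: str) -> Path:
    return Path(resources.files("emobody").joinpath("data", name))  # type: ignore[arg-type]


def load_reference_category_counts() -> pd.DataFrame:
    """Bundled transcription of the published per-category word counts
    (before and after exclusion), indexed by category id."""
    df = pd.read_csv(_data_path("category_counts.csv"), dtype={"category": str})
    return df.set_index("category")


def load_example_emotion_lexicon() -> list[EmotionEntry]:
    """Miniature illustrative emotion lexicon bundled with the package."""
    return load_emotion_lexicon(_data_path("example_emotion_lexicon.csv"))


def load_example_body_lexicon() -> list[BodyEntry]:
    """Miniature illustrative body lexicon bundled with the package."""
    return load_body_lexicon(_data_path("example_body_lexicon.csv"))
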