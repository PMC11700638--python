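"""Emotion↔body similarity tables and signed body-map rendering.

For a target emotion (a single word vector or a category mean) the cosine
similarity to every included body word yields a ranked table.  Each body
word's atlas parts are painted with its similarity value in the 3D voxel
grid; where parts overlap, the value of maximal absolute magnitude wins with
its sign preserved (exact-magnitude ties break toward positive and are
logged).  The 3D map is smoothed with a truncated Gaussian (σ = 2 voxels,
9×9×9 kernel, zero-padded borders), reduced to 2D by taking the signed
extreme along the anterior–posterior axis (an average projection is available
as an alternative reading), bilinearly upscaled to 631 × 1562 pixels and
masked by the skin outline.  Rendering maps positive similarity to red,
negative to blue and zero to black on the body silhouette.
"""

from __future__ import annotations

import json
import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage

from .atlas import BodyAtlas, match_parts
from .embeddings import EmbeddingSpace, cosine_similarity
from .lexicon import BodyEntry

logger = logging.getLogger(__name__)

#: default output resolution, (width, height) in pixels
OUT_DIMS: tuple[int, int] = (631, 1562)

#: diacritic fallback replacements applied when an output encoding cannot
#: carry the dotted/breve characters
DIACRITIC_FALLBACK = {
    "ṭ": "t.", "Ṭ": "T.",
    "ṣ": "s.", "Ṣ": "S.",
    "ḫ": "h_", "Ḫ": "H_",
}


class DegenerateCategoryError(ValueError):
    """The emotion vector has zero norm (degenerate category mean)."""


class MappingError(ValueError):
    """A similarity table references parts missing from the atlas."""


@dataclass(frozen=True)
class SimilarityRow:
    word: str
    part_ids: tuple[str, ...]
    similarity: float


@dataclass
class SimilarityTable:
    """Body words ranked by cosine similarity to one emotion (descending;
    exact ties ordered lexicographically by word key)."""

    emotion_id: str
    rows: list[SimilarityRow]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class BodyMap3D:
    values: np.ndarray  # signed reals on the atlas grid
    provenance: dict = field(default_factory=dict)


@dataclass
class BodyMap2D:
    values: np.ndarray  # (height, width) signed reals
    mask: np.ndarray  # (height, width) bool skin silhouette
    provenance: dict = field(default_factory=dict)

    @property
    def dims(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        return (self.values.shape[1], self.values.shape[0])


def body_similarities(
    space: EmbeddingSpace,
    emotion_vector: np.ndarray,
    body_lexicon: Iterable[BodyEntry],
    atlas: BodyAtlas | None = None,
    emotion_id: str = "emotion",
) -> SimilarityTable:
    """One cosine per included, in-space body word, sorted descending.

    Excluded and mask-only (skin) entries are skipped; entries without a
    vector are logged.  When an atlas is given, each row carries the resolved
    mask-bearing part ids; otherwise the raw atlas part names.
    """
    emotion_vector = np.asarray(emotion_vector, dtype=np.float64)
    if np.linalg.norm(emotion_vector) == 0.0:
        raise DegenerateCategoryError(
            f"{emotion_id}: emotion vector has zero norm"
        )
    rows: list[SimilarityRow] = []
    for entry in body_lexicon:
        if entry.excluded or entry.mask_only:
            continue
        if entry.word not in space:
            logger.info("body word %s has no vector; skipped", entry.word)
            continue
        sim = cosine_similarity(emotion_vector, space.vector(entry.word))
        part_ids = (
            tuple(match_parts(entry, atlas)) if atlas is not None else tuple(entry.atlas_parts)
        )
        rows.append(SimilarityRow(word=entry.word, part_ids=part_ids, similarity=sim))
    if not rows:
        raise MappingError(f"{emotion_id}: no included body word present in the space")
    rows.sort(key=lambda r: (-r.similarity, r.word))
    return SimilarityTable(emotion_id=emotion_id, rows=rows)


def top_k(table: SimilarityTable, k: int = 5) -> list[SimilarityRow]:
    """First k rows of the ranked table (fewer if the table is shorter)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return table.rows[:k]


def paint_map(table: SimilarityTable, atlas: BodyAtlas) -> BodyMap3D:
    """Paint each body word's parts with its similarity; merge overlaps by
    signed extreme (maximal |value| wins, exact ties break toward positive)."""
    values = np.zeros(atlas.grid.dims, dtype=np.float64)
    tie_count = 0
    for row in table:
        for pid in row.part_ids:
            if pid not in atlas.masks:
                raise MappingError(
                    f"{table.emotion_id}: part id {pid!r} missing from atlas"
                )
        v = row.similarity
        if v == 0.0:
            continue
        region = np.zeros(atlas.grid.dims, dtype=bool)
        for pid in row.part_ids:
            region |= atlas.masks[pid].mask
        cur = values[region]
        replace = np.abs(v) > np.abs(cur)
        ties = (np.abs(v) == np.abs(cur)) & (cur != v)
        tie_count += int(np.count_nonzero(ties & (v > cur)))
        cur[replace | (ties & (v > cur))] = v
        values[region] = cur
    if tie_count:
        logger.info(
            "%s: %d exact-magnitude overlap ties broken toward positive",
            table.emotion_id, tie_count,
        )
    return BodyMap3D(values=values, provenance={"emotion_id": table.emotion_id})


def merge_maps(a: BodyMap3D, b: BodyMap3D) -> BodyMap3D:
    """Signed-extreme merge of two 3D maps (same rule as overlap painting)."""
    take_b = (np.abs(b.values) > np.abs(a.values)) | (
        (np.abs(b.values) == np.abs(a.values)) & (b.values > a.values)
    )
    return BodyMap3D(values=np.where(take_b, b.values, a.values),
                     provenance=dict(a.provenance))


def mean_maps(maps: Sequence[BodyMap3D]) -> BodyMap3D:
    """Voxelwise mean of per-word maps (the per-word-average category mode)."""
    if not maps:
        raise ValueError("cannot average zero maps")
    return BodyMap3D(
        values=np.mean([m.values for m in maps], axis=0),
        provenance=dict(maps[0].provenance),
    )


def _signed_extreme(values: np.ndarray, axis: int) -> np.ndarray:
    """Per-fiber value of maximal |magnitude|; exact ties pick the positive."""
    mx = values.max(axis=axis)
    mn = values.min(axis=axis)
    return np.where(np.abs(mx) >= np.abs(mn), mx, mn)


def _resize_bilinear(img: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    rows = np.linspace(0.0, img.shape[0] - 1.0, out_shape[0])
    cols = np.linspace(0.0, img.shape[1] - 1.0, out_shape[1])
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(img, [rr, cc], order=1, mode="nearest")


def smooth3d(values: np.ndarray, sigma: float = 2.0, kernel: int = 9) -> np.ndarray:
    """Truncated isotropic Gaussian smoothing with zero-padded borders."""
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("kernel size must be odd and >= 3")
    truncate = (kernel // 2) / float(sigma)
    return ndimage.gaussian_filter(values, sigma=sigma, truncate=truncate, mode="constant")


def project_2d(
    map3d: BodyMap3D,
    atlas: BodyAtlas,
    sigma: float = 2.0,
    kernel: int = 9,
    out_dims: tuple[int, int] = OUT_DIMS,
    projection: str = "extreme",
) -> BodyMap2D:
    """Smooth in 3D, project along the chest–back axis, upscale and mask.

    ``projection='extreme'`` takes the signed extreme along the depth axis
    (the default); ``'average'`` takes the mean instead.  The result is
    bilinearly upscaled to ``out_dims`` (width, height), oriented with the
    head at the top, and the skin silhouette masks everything outside the
    body (masked-out pixels carry the background value 0).
    """
    if map3d.values.shape != atlas.grid.dims:
        raise MappingError(
            f"map shape {map3d.values.shape} does not match atlas grid {atlas.grid.dims}"
        )
    smoothed = smooth3d(map3d.values, sigma=sigma, kernel=kernel)
    if projection == "extreme":
        flat = _signed_extreme(smoothed, axis=1)  # (x, z)
    elif projection == "average":
        flat = smoothed.mean(axis=1)
    else:
        raise ValueError(f"unknown projection mode: {projection!r}")
    image = flat.T[::-1, :]  # rows = height (head up), cols = width
    width, height = out_dims
    up = _resize_bilinear(image, (height, width))

    skin_flat = atlas.skin.mask.any(axis=1).astype(np.float64)
    skin_img = skin_flat.T[::-1, :]
    skin_up = _resize_bilinear(skin_img, (height, width)) >= 0.5
    values = np.where(skin_up, up, 0.0)
    prov = dict(map3d.provenance)
    prov.update({"sigma": sigma, "kernel": kernel, "projection": projection,
                 "out_dims": list(out_dims)})
    return BodyMap2D(values=values, mask=skin_up, provenance=prov)


def transliterate(text: str) -> str:
    """ASCII-safe fallback: ṭ→t., ṣ→s., ḫ→h_, then strip other diacritics."""
    for src, dst in DIACRITIC_FALLBACK.items():
        text = text.replace(src, dst)
    decomposed = unicodedata.normalize("NFKD", text)
    return decomposed.encode("ascii", "ignore").decode("ascii")


def _colorize(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Diverging colormap anchored at 0 = black: positive → red, negative →
    blue, symmetric range ±max|value|; background is white."""
    vmax = float(np.abs(values[mask]).max()) if mask.any() else 0.0
    rgb = np.full(values.shape + (3,), 255, dtype=np.uint8)
    body = np.zeros(values.shape + (3,), dtype=np.float64)
    if vmax > 0:
        scaled = values / vmax
        body[..., 0] = np.clip(scaled, 0.0, 1.0) * 255.0  # red for positive
        body[..., 2] = np.clip(-scaled, 0.0, 1.0) * 255.0  # blue for negative
    rgb[mask] = body[mask].round().astype(np.uint8)
    return rgb


def render(map2d: BodyMap2D, sink: IO[bytes] | str | Path, title: str | None = None) -> None:
    """Write the 2D map as a PNG.  Labels fall back to the ASCII-safe
    transliteration when they cannot be encoded for drawing."""
    rgb = _colorize(map2d.values, map2d.mask)
    img = Image.fromarray(rgb, mode="RGB")
    if title:
        try:
            title.encode("latin-1")
        except UnicodeEncodeError:
            title = transliterate(title)
        draw = ImageDraw.Draw(img)
        draw.text((10, 10), title, fill=(32, 32, 32))
    img.save(sink, format="PNG")


def export_similarity_csv(table: SimilarityTable, sink: IO[str] | str | Path) -> None:
    """CSV export: emotion, body_word, part_ids (semicolon-joined), cosine."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            export_similarity_csv(table, fh)
        return
    sink.write("emotion,body_word,part_ids,cosine\n")
    for row in table:
        sink.write(
            f"{table.emotion_id},{row.word},{';'.join(row.part_ids)},{row.similarity!r}\n"
        )


def export_map3d(map3d: BodyMap3D, path_prefix: str | Path) -> tuple[Path, Path]:
    """Raw export: float64 little-endian flat binary + JSON header."""
    prefix = Path(path_prefix)
    raw_path = prefix.with_suffix(".raw")
    hdr_path = prefix.with_suffix(".json")
    data = np.ascontiguousarray(map3d.values, dtype="<f8")
    raw_path.write_bytes(data.tobytes())
    hdr_path.write_text(json.dumps({
        "dims": list(map3d.values.shape),
        "dtype": "<f8",
        "order": "C",
        "provenance": map3d.provenance,
    }, indent=2))
    return raw_path, hdr_path
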