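"""Similarity tables, map painting, projection and rendering."""

import io

import numpy as np
import pytest
from PIL import Image

from emobody.embeddings import EmbeddingSpace
from emobody.lexicon import BodyEntry
from emobody.mapping import (
    OUT_DIMS,
    BodyMap3D,
    DegenerateCategoryError,
    MappingError,
    SimilarityRow,
    SimilarityTable,
    body_similarities,
    merge_maps,
    paint_map,
    project_2d,
    render,
    smooth3d,
    top_k,
    transliterate,
)


def _space(vecs):
    return EmbeddingSpace(words=list(vecs), matrix=np.array(list(vecs.values()), dtype=float))


def _entries(parts_by_word):
    return [BodyEntry(w, w.split("[")[0], tuple(parts)) for w, parts in parts_by_word.items()]


class TestBodySimilarities:
    def test_identical_vector_ranks_first_with_similarity_one(self):
        space = _space({"liver[liver]N": [1.0, 0.0], "head[head]N": [0.0, 1.0]})
        lex = _entries({"liver[liver]N": ["liver"], "head[head]N": ["head"]})
        table = body_similarities(space, [1.0, 0.0], lex)
        assert table.rows[0].word == "liver[liver]N"
        assert table.rows[0].similarity == pytest.approx(1.0)

    def test_orthogonal_emotion_gives_all_zero_similarities(self):
        space = _space({"a[x]N": [1.0, 0.0], "b[y]N": [-1.0, 0.0]})
        lex = _entries({"a[x]N": ["liver"], "b[y]N": ["head"]})
        table = body_similarities(space, [0.0, 1.0], lex)
        assert all(r.similarity == 0.0 for r in table.rows)

    def test_zero_emotion_vector_rejected(self):
        space = _space({"a[x]N": [1.0, 0.0]})
        with pytest.raises(DegenerateCategoryError):
            body_similarities(space, [0.0, 0.0], _entries({"a[x]N": ["liver"]}))

    def test_excluded_and_skin_entries_skipped(self):
        space = _space({"a[x]N": [1.0], "v[v]N": [1.0], "s[s]N": [1.0]})
        lex = [
            BodyEntry("a[x]N", "arm", ("arm",)),
            BodyEntry("v[v]N", "vein", (), excluded=True,
                      exclusion_reason="whole-body-system"),
            BodyEntry("s[s]N", "skin", ("skin",), mask_only=True),
        ]
        table = body_similarities(space, [1.0], lex)
        assert [r.word for r in table.rows] == ["a[x]N"]

    def test_ties_ordered_lexicographically(self):
        space = _space({"b[y]N": [1.0, 0.0], "a[x]N": [1.0, 0.0]})
        lex = _entries({"b[y]N": ["head"], "a[x]N": ["liver"]})
        table = body_similarities(space, [1.0, 0.0], lex)
        assert [r.word for r in table.rows] == ["a[x]N", "b[y]N"]


class TestTopK:
    def _table(self, n):
        rows = [SimilarityRow(f"w{i}[g]N", (), 1.0 - i / 10) for i in range(n)]
        return SimilarityTable("e", rows)

    def test_first_k_rows_in_descending_order(self):
        rows = top_k(self._table(10), 5)
        assert len(rows) == 5
        sims = [r.similarity for r in rows]
        assert sims == sorted(sims, reverse=True)

    def test_k_larger_than_table_returns_whole_table(self):
        assert len(top_k(self._table(3), 5)) == 3


class TestPaintMap:
    def test_single_part_painted_inside_only(self, primitive_atlas):
        table = SimilarityTable("e", [SimilarityRow("liver[liver]N", ("liver",), 0.5)])
        m = paint_map(table, primitive_atlas)
        liver = primitive_atlas.masks["liver"].mask
        assert np.all(m.values[liver] == 0.5)
        assert np.all(m.values[~liver] == 0.0)

    def test_overlap_takes_larger_magnitude_sign_preserved(self, primitive_atlas):
        # head and skull overlap; skull painted more negative wins there
        table = SimilarityTable("e", [
            SimilarityRow("head[head]N", ("head",), 0.3),
            SimilarityRow("skull[skull]N", ("skull",), -0.5),
        ])
        m = paint_map(table, primitive_atlas)
        skull = primitive_atlas.masks["skull"].mask
        head_only = primitive_atlas.masks["head"].mask & ~skull
        assert np.all(m.values[skull] == -0.5)
        assert np.all(m.values[head_only] == 0.3)

    def test_exact_magnitude_tie_breaks_toward_positive(self, primitive_atlas):
        table = SimilarityTable("e", [
            SimilarityRow("skull[skull]N", ("skull",), -0.5),
            SimilarityRow("head[head]N", ("head",), 0.5),
        ])
        m = paint_map(table, primitive_atlas)
        skull = primitive_atlas.masks["skull"].mask
        assert np.all(m.values[skull] == 0.5)

    def test_missing_part_id_rejected(self, primitive_atlas):
        table = SimilarityTable("e", [SimilarityRow("x[y]N", ("nonexistent",), 0.2)])
        with pytest.raises(MappingError, match="nonexistent"):
            paint_map(table, primitive_atlas)

    def test_merge_with_itself_is_identity(self, primitive_atlas):
        table = SimilarityTable("e", [
            SimilarityRow("liver[liver]N", ("liver",), 0.4),
            SimilarityRow("head[head]N", ("head",), -0.2),
        ])
        m = paint_map(table, primitive_atlas)
        again = merge_maps(m, m)
        np.testing.assert_array_equal(again.values, m.values)


class TestProjection:
    def test_output_dims_exactly_631_by_1562(self, primitive_atlas):
        m = BodyMap3D(values=np.zeros(primitive_atlas.grid.dims))
        out = project_2d(m, primitive_atlas)
        assert out.dims == OUT_DIMS == (631, 1562)
        assert out.values.shape == (1562, 631)

    def test_constant_region_projects_to_its_value(self, primitive_atlas):
        # paint the whole skin volume: smoothing a constant region leaves the
        # interior at the constant, so skin-center pixels sit near 0.7
        m = BodyMap3D(values=np.where(primitive_atlas.skin.mask, 0.7, 0.0))
        out = project_2d(m, primitive_atlas)
        # torso center in image coordinates: x=70, z=220 -> row scale 1562/348
        row = int((347 - 220) * 1562 / 348)
        col = int(70 * 631 / 141)
        assert out.values[row, col] == pytest.approx(0.7, abs=1e-3)

    def test_single_voxel_spot_peaks_at_its_column(self, primitive_atlas):
        values = np.zeros(primitive_atlas.grid.dims)
        values[70, 50, 240] = 1.0  # inside the torso -> inside the skin mask
        sm = smooth3d(values)
        # kernel mass is conserved up to truncation
        assert sm.sum() == pytest.approx(1.0, rel=0.01)
        out = project_2d(BodyMap3D(values=values), primitive_atlas)
        r, c = np.unravel_index(np.abs(out.values).argmax(), out.values.shape)
        assert abs(c - 70 * 630 / 140) < 6
        assert abs(r - (347 - 240) * 1561 / 347) < 6

    def test_projection_cannot_amplify(self, primitive_atlas):
        rng = np.random.default_rng(0)
        values = np.where(primitive_atlas.skin.mask,
                          rng.uniform(-0.8, 0.8, primitive_atlas.grid.dims), 0.0)
        out = project_2d(BodyMap3D(values=values), primitive_atlas)
        assert np.abs(out.values).max() <= np.abs(values).max() + 1e-12

    def test_signed_extreme_prefers_larger_magnitude(self, primitive_atlas):
        values = np.zeros(primitive_atlas.grid.dims)
        values[70, 30, 240] = -0.9  # anterior, strong negative
        values[70, 70, 240] = 0.4  # posterior, weaker positive
        out = project_2d(BodyMap3D(values=values), primitive_atlas)
        r = int(round((347 - 240) * 1561 / 347))
        c = int(round(70 * 630 / 140))
        assert out.values[r, c] < 0

    def test_average_projection_mode(self, primitive_atlas):
        values = np.where(primitive_atlas.skin.mask, 0.5, 0.0)
        out = project_2d(BodyMap3D(values=values), primitive_atlas, projection="average")
        assert 0.0 < out.values.max() <= 0.5

    def test_even_or_tiny_kernel_rejected(self, primitive_atlas):
        m = BodyMap3D(values=np.zeros(primitive_atlas.grid.dims))
        with pytest.raises(ValueError):
            project_2d(m, primitive_atlas, kernel=8)
        with pytest.raises(ValueError):
            project_2d(m, primitive_atlas, kernel=1)


class TestRender:
    def _map2d(self, primitive_atlas, fill=0.0):
        m = BodyMap3D(values=np.where(primitive_atlas.skin.mask, fill, 0.0))
        return project_2d(m, primitive_atlas)

    def test_all_zero_map_renders_black_silhouette(self, primitive_atlas):
        m2 = self._map2d(primitive_atlas, 0.0)
        buf = io.BytesIO()
        render(m2, buf)
        buf.seek(0)
        img = np.asarray(Image.open(buf))
        assert img.shape == (1562, 631, 3)
        assert (img[m2.mask] == 0).all()  # body is black
        assert (img[~m2.mask] == 255).all()  # background white

    def test_positive_region_renders_red_negative_blue_symmetric(self, primitive_atlas):
        values = np.zeros(primitive_atlas.grid.dims)
        values[primitive_atlas.masks["liver"].mask] = 0.6
        values[primitive_atlas.masks["heart"].mask] = -0.6
        m2 = project_2d(BodyMap3D(values=values), primitive_atlas)
        buf = io.BytesIO()
        render(m2, buf)
        buf.seek(0)
        img = np.asarray(Image.open(buf)).astype(int)
        pos = img[m2.values > 0.3]
        neg = img[m2.values < -0.3]
        assert (pos[:, 0] > pos[:, 2]).all()  # red channel dominates
        assert (neg[:, 2] > neg[:, 0]).all()  # blue channel dominates
        # symmetric values map to color pairs mirrored about black
        v = 0.5 * np.abs(m2.values).max()
        r_pos = img[np.isclose(m2.values, v, atol=1e-6)]
        r_neg = img[np.isclose(m2.values, -v, atol=1e-6)]
        if len(r_pos) and len(r_neg):
            assert set(map(tuple, r_pos[:, [0, 1, 2]])) == set(
                map(tuple, r_neg[:, [2, 1, 0]])
            )


def test_transliterate_diacritic_fallback():
    assert transliterate("ulṣu") == "uls.u"
    assert transliterate("ṭēmu") == "t.emu"
    assert transliterate("ḫadû") == "h_adu"
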