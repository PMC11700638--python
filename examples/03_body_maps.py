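"""Render an emotion's body map on the primitive voxel atlas.

Each included body word's atlas parts are painted with the word's cosine
similarity to the emotion; overlaps keep the value of largest magnitude.
The 3D map is Gaussian-smoothed (sigma 2, 9x9x9 kernel), reduced front-to-back
by the signed extreme, upscaled to 631x1562 and masked by the skin outline.
"""

from pathlib import Path

import numpy as np

from emobody import (
    body_similarities,
    build_space,
    default_spec,
    generate_corpus,
    generate_lexicons,
    make_primitive_atlas,
    paint_map,
    project_2d,
    render,
    top_k,
)
from emobody.lexicon import category_vector

spec = default_spec(seed=42)
corpus = generate_corpus(spec)
emotions, bodies = generate_lexicons(spec)
space = build_space(corpus)
atlas = make_primitive_atlas()
print(f"atlas: {len(atlas.part_ids())} part masks on grid {atlas.grid.dims}")

cid = "3a"  # the Happiness category, planted on the liver
mean = category_vector(space, cid, emotions)
table = body_similarities(space, mean, bodies, atlas=atlas, emotion_id=cid)
print(f"\ntop body words for category {cid}:")
for row in top_k(table, 3):
    print(f"  {row.word:18s} cosine={row.similarity:+.3f} parts={row.part_ids}")

map3d = paint_map(table, atlas)
map2d = project_2d(map3d, atlas)
print(f"\n2D map {map2d.dims[0]}x{map2d.dims[1]} px, "
      f"value range [{map2d.values.min():+.3f}, {map2d.values.max():+.3f}]")
peak = np.unravel_index(np.abs(map2d.values).argmax(), map2d.values.shape)
print(f"strongest pixel at row {peak[0]}, col {peak[1]} "
      "(red = positive association, blue = negative, black = none)")

out = Path("scratch") / "example_map_3a.png"
out.parent.mkdir(exist_ok=True)
render(map2d, out, title=cid)
print(f"wrote {out}")
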