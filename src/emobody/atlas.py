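"""Voxel body atlas: mesh voxelization, part-name hierarchy and a built-in
primitive atlas.

Body parts live on a fixed logical grid of 141 × 101 × 348 voxels
(width × depth × height): axis 0 runs left↔right, axis 1 anterior↔posterior
(chest–back) and axis 2 inferior↔superior.  A part is a logical occupancy
mask — a voxel is occupied iff its center lies inside the part's closed
surface.  Parts are named and connected by IS-A and PART-OF hierarchy edges
so a body word naming a compound part ("backbone") expands to all constituent
models lower in the hierarchy (the vertebrae).  The skin mask is special: it
outlines the body in rendered maps and is required in every atlas.

Atlases can be built from Wavefront OBJ triangle meshes plus a hierarchy CSV,
or generated as a deterministic primitive-solid stand-in
(:func:`make_primitive_atlas`) whose spheres, ellipsoids, boxes and cylinders
are placed at anatomically plausible positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh

from .lexicon import BodyEntry

logger = logging.getLogger(__name__)

#: width (left-right), depth (chest-back), height (feet-head) in voxels
GRID_DIMS: tuple[int, int, int] = (141, 101, 348)

RELATIONS = {"IS-A", "PART-OF"}


class AtlasError(ValueError):
    """Structural atlas problem (missing skin, duplicate ids, bad hierarchy)."""


class VoxelizationError(ValueError):
    """A mesh could not be voxelized (non-watertight after repair)."""


class UnmatchedPartError(KeyError):
    """No atlas part could be resolved for any of a body entry's names."""


@dataclass
class VoxelGrid:
    """Logical voxel grid with a grid→world affine (rows map grid indices,
    in homogeneous coordinates, to world positions of voxel centers)."""

    dims: tuple[int, int, int] = GRID_DIMS
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if any(d <= 0 for d in self.dims):
            raise AtlasError(f"grid dims must be positive: {self.dims}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-300:
            raise AtlasError("grid affine must be invertible")

    def world_coords(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates of voxel centers for (n, 3) integer indices."""
        idx = np.asarray(idx, dtype=np.float64)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class MeshModel:
    """A named triangle mesh (vertices in world coordinates)."""

    part_id: str
    name: str
    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if len(self.vertices) < 4:
            raise AtlasError(f"{self.part_id}: a closed solid needs >= 4 vertices")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=0) >= len(self.vertices):
            raise AtlasError(f"{self.part_id}: triangle index out of range")


@dataclass
class PartMask:
    """Logical occupancy of one part on the atlas grid."""

    part_id: str
    mask: np.ndarray  # bool array with VoxelGrid dims

    @property
    def volume(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class HierarchyEdge:
    child: str
    parent: str
    relation: str  # IS-A or PART-OF


class BodyAtlas:
    """Named part masks plus the IS-A / PART-OF name hierarchy and skin."""

    def __init__(
        self,
        grid: VoxelGrid,
        masks: Mapping[str, PartMask],
        names: Mapping[str, str],
        edges: Sequence[HierarchyEdge],
        skin: PartMask,
        overrides: Mapping[str, str] | None = None,
    ):
        self.grid = grid
        self.masks = dict(masks)
        self.names = dict(names)  # part id -> display name (incl. group nodes)
        self.edges = list(edges)
        self.skin = skin
        self.overrides = dict(overrides or {})
        for edge in self.edges:
            if edge.relation not in RELATIONS:
                raise AtlasError(f"unknown hierarchy relation: {edge.relation!r}")
        self._children: dict[str, list[str]] = {}
        for edge in self.edges:
            self._children.setdefault(edge.parent, []).append(edge.child)
        # every hierarchy leaf must be backed by a mask
        for pid in self.names:
            if pid not in self._children and pid not in self.masks and pid != skin.part_id:
                raise AtlasError(f"hierarchy leaf {pid!r} has no mask")

    def part_ids(self) -> list[str]:
        return sorted(self.masks)

    def descendants(self, part_id: str) -> list[str]:
        """All transitive children of a node (both relations)."""
        out: list[str] = []
        stack = list(self._children.get(part_id, []))
        seen: set[str] = set()
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            out.append(node)
            stack.extend(self._children.get(node, []))
        return sorted(out)

    def resolve_name(self, name: str) -> list[str]:
        """Node ids matching a part name: exact → case-insensitive substring
        → manual-override table (then resolved again).  Empty if no match."""
        exact = [pid for pid, nm in self.names.items() if nm == name]
        if exact:
            return sorted(exact)
        low = name.strip().lower()
        sub = [pid for pid, nm in self.names.items() if low in nm.lower()]
        if sub:
            return sorted(sub)
        if low in self.overrides:
            target = self.overrides[low]
            if target.strip().lower() != low:
                return self.resolve_name(target)
        return []


def match_parts(entry: BodyEntry, atlas: BodyAtlas) -> list[str]:
    """Resolve a body entry's atlas part names to mask-bearing part ids.

    Each name is resolved through the atlas hierarchy and expanded to every
    descendant model lower in the hierarchy; the union over the entry's names
    is returned.  Adding descendants can only grow the result (monotone).
    """
    if entry.excluded:
        raise ValueError(f"{entry.word}: excluded entries have no atlas parts")
    ids: set[str] = set()
    tried: list[str] = []
    for name in entry.atlas_parts:
        tried.append(name)
        for node in atlas.resolve_name(name):
            if node in atlas.masks and node != atlas.skin.part_id:
                ids.add(node)
            for desc in atlas.descendants(node):
                if desc in atlas.masks and desc != atlas.skin.part_id:
                    ids.add(desc)
    if not ids:
        raise UnmatchedPartError(
            f"{entry.word}: no atlas part matched any of {tried}"
        )
    return sorted(ids)


#: tie-perturbation of ray positions: rays are shifted off the integer
#: lattice by distinct tiny offsets in x and z so they generically miss
#: triangle edges and vertices (shared-edge double counting)
_RAY_EPS_X = 0.5e-6
_RAY_EPS_Z = 1.3e-6


def _parity_ray_cast(vertices: np.ndarray, faces: np.ndarray, dims) -> np.ndarray:
    """Inside-test by parity ray casting along +y at every voxel center.

    For each (x, z) lattice ray the crossing heights with all non-degenerate
    triangles are collected; a voxel center is inside iff an odd number of
    crossings lies above it.  Vertices must already be in grid coordinates.
    """
    mask = np.zeros(dims, dtype=bool)
    tris = vertices[faces]  # (m, 3, 3)
    crossings: dict[tuple[int, int], list[float]] = {}
    ys = np.arange(dims[1], dtype=np.float64)
    for tri in tris:
        ax, ay, az = tri[0]
        bx, by, bz = tri[1]
        cx, cy, cz = tri[2]
        e1x, e1z = bx - ax, bz - az
        e2x, e2z = cx - ax, cz - az
        det = e1x * e2z - e1z * e2x
        if abs(det) < 1e-12:
            continue  # degenerate in the (x, z) projection (wall parallel to +y)
        xlo = max(int(np.ceil(min(ax, bx, cx) - _RAY_EPS_X)), 0)
        xhi = min(int(np.floor(max(ax, bx, cx) - _RAY_EPS_X)), dims[0] - 1)
        zlo = max(int(np.ceil(min(az, bz, cz) - _RAY_EPS_Z)), 0)
        zhi = min(int(np.floor(max(az, bz, cz) - _RAY_EPS_Z)), dims[2] - 1)
        if xlo > xhi or zlo > zhi:
            continue
        gx, gz = np.meshgrid(np.arange(xlo, xhi + 1), np.arange(zlo, zhi + 1),
                             indexing="ij")
        rx = gx + _RAY_EPS_X - ax
        rz = gz + _RAY_EPS_Z - az
        u = (rx * e2z - rz * e2x) / det
        w = (e1x * rz - e1z * rx) / det
        hit = (u >= 0.0) & (w >= 0.0) & (u + w <= 1.0)
        if not hit.any():
            continue
        y_hit = ay + u * (by - ay) + w * (cy - ay)
        for ix, iz, yc in zip(gx[hit], gz[hit], y_hit[hit]):
            crossings.setdefault((int(ix), int(iz)), []).append(float(yc))
    for (ix, iz), yc in crossings.items():
        yc = np.sort(yc)
        n_above = len(yc) - np.searchsorted(yc, ys, side="right")
        mask[ix, :, iz] = (n_above % 2) == 1
    return mask


def voxelize(mesh: MeshModel, grid: VoxelGrid) -> PartMask:
    """Occupancy mask of a closed mesh: a voxel is set iff its center lies
    inside the surface (parity ray casting along +y with tie perturbation).

    Non-watertight meshes are repaired by simple hole filling; if that fails
    the error names the part.  A mesh entirely outside the grid yields an
    empty mask with a warning.
    """
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if not tm.is_watertight:
        trimesh.repair.fill_holes(tm)
        if not tm.is_watertight:
            raise VoxelizationError(
                f"mesh for part {mesh.part_id!r} is not watertight after repair"
            )
    inv = np.linalg.inv(grid.affine)
    gverts = np.asarray(tm.vertices) @ inv[:3, :3].T + inv[:3, 3]
    lo, hi = gverts.min(axis=0), gverts.max(axis=0)
    if np.any(hi < 0) or np.any(lo > np.array(grid.dims) - 1):
        logger.warning("mesh %s lies entirely outside the grid", mesh.part_id)
        return PartMask(part_id=mesh.part_id, mask=np.zeros(grid.dims, dtype=bool))
    mask = _parity_ray_cast(gverts, np.asarray(tm.faces), grid.dims)
    if not mask.any():
        logger.warning("mesh %s voxelized to an empty mask", mesh.part_id)
    return PartMask(part_id=mesh.part_id, mask=mask)


def _read_hierarchy(source: IO[str] | str | Path | pd.DataFrame) -> tuple[dict[str, str], list[HierarchyEdge]]:
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(
        source, dtype=str, keep_default_na=False
    )
    names: dict[str, str] = {}
    edges: list[HierarchyEdge] = []
    for _, row in df.iterrows():
        pid = row["part_id"].strip()
        names[pid] = row["name"].strip()
        parent = row.get("parent_id", "").strip()
        relation = row.get("relation", "").strip()
        if parent:
            edges.append(HierarchyEdge(child=pid, parent=parent, relation=relation))
    return names, edges


def load_override_table(source: IO[str] | str | Path | pd.DataFrame) -> dict[str, str]:
    """Manual word-name → part-name synonym table (case-insensitive keys)."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(
        source, dtype=str, keep_default_na=False
    )
    return {
        row["word_name"].strip().lower(): row["part_name"].strip()
        for _, row in df.iterrows()
    }


def default_overrides() -> dict[str, str]:
    """Best-effort synonym/constituent table bundled with the package."""
    path = Path(resources.files("emobody").joinpath("data", "atlas_overrides.csv"))  # type: ignore[arg-type]
    return load_override_table(path)


def build_atlas(
    obj_dir: str | Path,
    hierarchy: IO[str] | str | Path | pd.DataFrame,
    grid: VoxelGrid | None = None,
    overrides: Mapping[str, str] | None = None,
    skin_id: str = "skin",
) -> BodyAtlas:
    """Build an atlas from a directory of ``<part_id>.obj`` meshes.

    The union bounding box of the skin vertices is fitted to the grid with a
    uniform scale and centered (2-voxel margin); every mesh is voxelized in
    that frame.  The skin mesh is mandatory.
    """
    obj_dir = Path(obj_dir)
    paths = sorted(obj_dir.glob("*.obj"))
    if not paths:
        raise AtlasError(f"no OBJ meshes found in {obj_dir}")
    meshes: dict[str, trimesh.Trimesh] = {}
    for path in paths:
        pid = path.stem
        if pid in meshes:
            raise AtlasError(f"duplicate part id: {pid!r}")
        loaded = trimesh.load(path, force="mesh", process=False)
        meshes[pid] = loaded
    if skin_id not in meshes:
        raise AtlasError(f"missing required skin mesh {skin_id!r}.obj")
    names, edges = _read_hierarchy(hierarchy)
    for pid in meshes:
        names.setdefault(pid, pid)

    dims = np.array((grid or VoxelGrid()).dims, dtype=np.float64)
    margin = 2.0
    skin_verts = np.asarray(meshes[skin_id].vertices, dtype=np.float64)
    lo, hi = skin_verts.min(axis=0), skin_verts.max(axis=0)
    extent = np.maximum(hi - lo, 1e-12)
    scale = float(((dims - 1 - 2 * margin) / extent).min())  # world units per... grid per world
    center_world = (lo + hi) / 2.0
    center_grid = (dims - 1) / 2.0
    # grid index g maps to world: w = center_world + (g - center_grid) / scale
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) / scale
    affine[:3, 3] = center_world - center_grid / scale
    vgrid = VoxelGrid(dims=tuple(int(d) for d in dims), affine=affine)

    masks: dict[str, PartMask] = {}
    for pid, tm in meshes.items():
        model = MeshModel(part_id=pid, name=names[pid],
                          vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))
        masks[pid] = voxelize(model, vgrid)
    skin = masks.pop(skin_id)
    return BodyAtlas(
        grid=vgrid, masks=masks, names=names, edges=edges, skin=skin,
        overrides=dict(overrides) if overrides is not None else default_overrides(),
    )


# ---------------------------------------------------------------------------
# primitive atlas


def _grid_axes(dims: tuple[int, int, int]):
    return np.ogrid[0 : dims[0], 0 : dims[1], 0 : dims[2]]


def _sphere(dims, center, r):
    x, y, z = _grid_axes(dims)
    return (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= r**2


def _ellipsoid(dims, center, semi):
    x, y, z = _grid_axes(dims)
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
        <= 1.0
    )


def _box(dims, lo, hi):
    """Half-open box on integer voxel centers: lo <= v < hi per axis."""
    x, y, z = _grid_axes(dims)
    return (
        (x >= lo[0]) & (x < hi[0]) & (y >= lo[1]) & (y < hi[1]) & (z >= lo[2]) & (z < hi[2])
    )


def _vcylinder(dims, cx, cy, r, z0, z1):
    """Vertical cylinder, half-open in z."""
    x, y, z = _grid_axes(dims)
    return ((x - cx) ** 2 + (y - cy) ** 2 <= r**2) & (z >= z0) & (z < z1)


#: analytic solids of the primitive atlas: (part id, kind, parameters).
#: Mid-sagittal plane is x = 70; right-side parts are exact mirror images of
#: their left counterparts (constructed by flipping axis 0).
PRIMITIVE_SOLIDS: list[tuple[str, str, dict]] = [
    ("head", "sphere", {"center": (70, 50, 310), "r": 24}),
    ("skull", "sphere", {"center": (70, 50, 312), "r": 16}),
    ("liver", "ellipsoid", {"center": (84, 44, 240), "semi": (16, 12, 10)}),
    ("heart", "ellipsoid", {"center": (64, 46, 252), "semi": (10, 9, 11)}),
    ("stomach", "ellipsoid", {"center": (58, 52, 230), "semi": (13, 10, 9)}),
    ("kidney_left", "ellipsoid", {"center": (56, 62, 218), "semi": (7, 6, 11)}),
    ("vertebra_1", "box", {"lo": (66, 64, 158), "hi": (74, 74, 180)}),
    ("vertebra_2", "box", {"lo": (66, 64, 183), "hi": (74, 74, 205)}),
    ("vertebra_3", "box", {"lo": (66, 64, 208), "hi": (74, 74, 230)}),
    ("vertebra_4", "box", {"lo": (66, 64, 233), "hi": (74, 74, 255)}),
    ("vertebra_5", "box", {"lo": (66, 64, 258), "hi": (74, 74, 280)}),
    ("arm_left", "cylinder", {"cx": 12, "cy": 50, "r": 7, "z0": 170, "z1": 272}),
    ("hand_left", "sphere", {"center": (12, 50, 160), "r": 8}),
    ("leg_left", "cylinder", {"cx": 50, "cy": 50, "r": 10, "z0": 20, "z1": 150}),
    ("foot_left", "box", {"lo": (42, 28, 6), "hi": (58, 62, 20)}),
]

MIRRORED_PAIRS = [
    ("kidney_left", "kidney_right"),
    ("arm_left", "arm_right"),
    ("hand_left", "hand_right"),
    ("leg_left", "leg_right"),
    ("foot_left", "foot_right"),
]

PRIMITIVE_HIERARCHY: list[HierarchyEdge] = [
    HierarchyEdge("skull", "head", "PART-OF"),
    HierarchyEdge("head", "body", "PART-OF"),
    HierarchyEdge("torso", "body", "PART-OF"),
    HierarchyEdge("liver", "torso", "PART-OF"),
    HierarchyEdge("heart", "torso", "PART-OF"),
    HierarchyEdge("stomach", "torso", "PART-OF"),
    HierarchyEdge("kidney", "torso", "PART-OF"),
    HierarchyEdge("kidney_left", "kidney", "IS-A"),
    HierarchyEdge("kidney_right", "kidney", "IS-A"),
    HierarchyEdge("spine", "torso", "PART-OF"),
    HierarchyEdge("vertebra_1", "spine", "PART-OF"),
    HierarchyEdge("vertebra_2", "spine", "PART-OF"),
    HierarchyEdge("vertebra_3", "spine", "PART-OF"),
    HierarchyEdge("vertebra_4", "spine", "PART-OF"),
    HierarchyEdge("vertebra_5", "spine", "PART-OF"),
    HierarchyEdge("arm_left", "arm", "IS-A"),
    HierarchyEdge("arm_right", "arm", "IS-A"),
    HierarchyEdge("arm", "body", "PART-OF"),
    HierarchyEdge("hand_left", "arm_left", "PART-OF"),
    HierarchyEdge("hand_right", "arm_right", "PART-OF"),
    HierarchyEdge("hand_left", "hand", "IS-A"),
    HierarchyEdge("hand_right", "hand", "IS-A"),
    HierarchyEdge("leg_left", "leg", "IS-A"),
    HierarchyEdge("leg_right", "leg", "IS-A"),
    HierarchyEdge("leg", "body", "PART-OF"),
    HierarchyEdge("foot_left", "leg_left", "PART-OF"),
    HierarchyEdge("foot_right", "leg_right", "PART-OF"),
    HierarchyEdge("foot_left", "foot", "IS-A"),
    HierarchyEdge("foot_right", "foot", "IS-A"),
]

_GROUP_NODES = ["body", "torso", "kidney", "spine", "arm", "hand", "leg", "foot"]


def _primitive_mask(dims, kind: str, params: dict) -> np.ndarray:
    if kind == "sphere":
        return _sphere(dims, **params)
    if kind == "ellipsoid":
        return _ellipsoid(dims, **params)
    if kind == "box":
        return _box(dims, **params)
    if kind == "cylinder":
        return _vcylinder(dims, **params)
    raise ValueError(f"unknown primitive kind: {kind!r}")


def primitive_volume(kind: str, params: dict) -> float:
    """Analytic volume (in voxels) of one primitive solid."""
    if kind == "sphere":
        return 4.0 / 3.0 * np.pi * params["r"] ** 3
    if kind == "ellipsoid":
        a, b, c = params["semi"]
        return 4.0 / 3.0 * np.pi * a * b * c
    if kind == "box":
        lo, hi = params["lo"], params["hi"]
        return float(np.prod([h - l for l, h in zip(lo, hi)]))
    if kind == "cylinder":
        return float(np.pi * params["r"] ** 2 * (params["z1"] - params["z0"]))
    raise ValueError(f"unknown primitive kind: {kind!r}")


def _skin_mask(dims) -> np.ndarray:
    """Body-shaped filled envelope enclosing every primitive part."""
    skin = np.zeros(dims, dtype=bool)
    skin |= _sphere(dims, (70, 50, 310), 27)  # head
    x, y, z = _grid_axes(dims)
    torso = (((x - 70) / 36.0) ** 2 + ((y - 50) / 26.0) ** 2 <= 1.0) & (z >= 148) & (z < 288)
    skin |= torso
    skin |= _vcylinder(dims, 70, 50, 11, 280, 300)  # neck
    for cx in (12, 128):
        skin |= _vcylinder(dims, cx, 50, 9.5, 166, 276)  # arms
        skin |= _sphere(dims, (cx, 50, 160), 10.5)  # hands
    for cx in (50, 90):
        skin |= _vcylinder(dims, cx, 50, 12, 14, 152)  # legs
    skin |= _box(dims, (40, 26, 4), (60, 64, 22))  # feet
    skin |= _box(dims, (80, 26, 4), (100, 64, 22))
    return skin


def make_primitive_atlas(seed: int | None = None) -> BodyAtlas:
    """Deterministic primitive-solid atlas on the standard grid.

    ``seed`` is accepted for interface symmetry with the synthetic corpus
    generator but the construction is fully deterministic.  Left/right paired
    parts are exact mirror images about the mid-sagittal plane, all parts lie
    inside the skin envelope, and each mask's voxel count matches its
    analytic primitive volume closely.
    """
    dims = GRID_DIMS
    masks: dict[str, PartMask] = {}
    for pid, kind, params in PRIMITIVE_SOLIDS:
        masks[pid] = PartMask(part_id=pid, mask=_primitive_mask(dims, kind, params))
    for left, right in MIRRORED_PAIRS:
        masks[right] = PartMask(part_id=right, mask=np.flip(masks[left].mask, axis=0))
    skin = PartMask(part_id="skin", mask=_skin_mask(dims))
    names = {pid: pid for pid in masks}
    names.update({g: g for g in _GROUP_NODES})
    names["skin"] = "skin"
    return BodyAtlas(
        grid=VoxelGrid(dims=dims),
        masks=masks,
        names=names,
        edges=PRIMITIVE_HIERARCHY,
        skin=skin,
        overrides=default_overrides(),
    )
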