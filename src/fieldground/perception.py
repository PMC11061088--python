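"""Scene rendering and cued conjunction search.

A synthetic scene is rendered into feature/space perception fields — one
three-dimensional field (x, y, feature) per feature dimension, with the
two spatial dimensions shared across all of them so that the features of
one object bind through space.  Visual search is cued by concept nodes
whose Gaussian feature templates inject slice input into feature/space
attention fields; contraction over the feature axes plus inhibition
proportional to the number of cues leaves the spatial attention field
supra-threshold only where every cued feature matches.  A selective target
field then picks a single candidate location, biased away from previously
tried candidates by an inhibition-of-return (IoR) working memory field.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from fieldground.concepts import ConceptDef, ConceptInventory, SHAPE_CLASSES, shape_center
from fieldground.fields import (
    DimensionSpec,
    Field,
    FieldParams,
    detect_peaks,
    kernel_preset,
    select_by_boost,
    settle_field,
    sigmoid,
)

__all__ = [
    "SceneObject",
    "Scene",
    "SceneGrids",
    "PerceptionFields",
    "render_scene",
    "cue_attention",
    "select_target",
    "mark_ior",
    "reset_ior",
    "make_ior_field",
    "read_motion_dir",
    "calibrate_match_mass",
    "effective_blob_width",
]

BLOB_WIDTH = 2.5  # spatial blob width, scene units
BLOB_AMP = 8.0  # rendering amplitude (safely supra-threshold off-grid)
FEATURE_WIDTHS = {"hue": 20.0, "size": 1.2, "shape": 4.0, "dir": 20.0}

# conjunction calibration: each matching cued feature contributes MATCH_GAIN,
# each cue costs MATCH_COST, object presence contributes PRESENCE_GAIN; with
# h = -5 a full conjunction sits ~1 above threshold and a location missing
# one cue sits >= 1.5 below.
PRESENCE_GAIN = 6.0
MATCH_GAIN = 2.5
MATCH_COST = 2.5
GUIDANCE_GAIN = 1.0
ATT_GAIN = 3.8  # attention rate -> (subthreshold) target field drive
IOR_GAIN = 4.0  # IoR rate -> target field suppression
TARGET_BETA = 1.0  # shallow transmission into the target field keeps the
# drive graded: a strongly guided candidate outcompetes a barely
# supra-threshold one instead of both saturating at rate 1


@dataclass(frozen=True)
class SceneObject:
    id: str
    pos: tuple[float, float]
    hue: float
    size: float
    shape: str
    motion_dir: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.hue < 360.0):
            raise ValueError("hue must lie in [0, 360)")
        if self.motion_dir is not None and not (0.0 <= self.motion_dir < 360.0):
            raise ValueError("motion_dir must lie in [0, 360)")
        if self.shape not in SHAPE_CLASSES:
            raise ValueError(f"unknown shape {self.shape!r}")

    def feature_value(self, dim: str) -> float | None:
        return {
            "hue": self.hue,
            "size": self.size,
            "shape": shape_center(self.shape),
            "dir": self.motion_dir,
        }[dim]


@dataclass
class Scene:
    objects: list[SceneObject]
    bounds: tuple[DimensionSpec, DimensionSpec]

    def __post_init__(self) -> None:
        ids = [o.id for o in self.objects]
        if len(set(ids)) != len(ids):
            raise ValueError("object ids must be unique")
        for o in self.objects:
            bx, by = self.bounds
            if not (bx.lo <= o.pos[0] <= bx.hi and by.lo <= o.pos[1] <= by.hi):
                raise ValueError(f"object {o.id!r} outside scene bounds")

    def __getitem__(self, oid: str) -> SceneObject:
        for o in self.objects:
            if o.id == oid:
                return o
        raise KeyError(oid)

    def to_json(self, path: str | Path | None = None) -> str:
        bx, by = self.bounds
        data = {
            "bounds": {"x": [bx.lo, bx.hi], "y": [by.lo, by.hi]},
            "objects": [
                {
                    "id": o.id,
                    "x": o.pos[0],
                    "y": o.pos[1],
                    "hue": o.hue,
                    "size": o.size,
                    "shape": o.shape,
                    "motion_dir": o.motion_dir,
                }
                for o in self.objects
            ],
        }
        text = json.dumps(data, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path, n: int = 64) -> "Scene":
        s = str(text_or_path)
        if "\n" not in s and len(s) < 1024 and Path(s).exists():
            s = Path(s).read_text()
        data = json.loads(s)
        if "scene" in data and "objects" not in data:
            data = data["scene"]  # task bundles nest the scene
        bx = data["bounds"]["x"]
        by = data["bounds"]["y"]
        bounds = (
            DimensionSpec("x", bx[0], bx[1], n),
            DimensionSpec("y", by[0], by[1], n),
        )
        objects = [
            SceneObject(
                o["id"],
                (o["x"], o["y"]),
                o["hue"],
                o["size"],
                o["shape"],
                o.get("motion_dir"),
            )
            for o in data["objects"]
        ]
        return cls(objects, bounds)


def default_bounds(n: int = 64) -> tuple[DimensionSpec, DimensionSpec]:
    return (DimensionSpec("x", 0, 100, n), DimensionSpec("y", 0, 100, n))


@dataclass(frozen=True)
class SceneGrids:
    """Grid resolutions for the perception substrate."""

    spatial: tuple[DimensionSpec, DimensionSpec]
    features: dict[str, DimensionSpec]

    @classmethod
    def make(cls, n_spatial: int = 64, n_angle: int = 16, n_size: int = 13) -> "SceneGrids":
        shape_hi = 20.0 * len(SHAPE_CLASSES)
        return cls(
            spatial=default_bounds(n_spatial),
            features={
                "hue": DimensionSpec("hue", 0, 360, n_angle, circular=True),
                "size": DimensionSpec("size", 0, 12, n_size),
                "shape": DimensionSpec("shape", 0, shape_hi, max(8, int(shape_hi / 5) + 1)),
                "dir": DimensionSpec("dir", 0, 360, n_angle, circular=True),
            },
        )


@dataclass
class PerceptionFields:
    """One settled (x, y, feature) field per feature dimension."""

    grids: SceneGrids
    fields: dict[str, Field]

    def output(self, dim: str) -> np.ndarray:
        return self.fields[dim].output()


def effective_blob_width(dim: DimensionSpec) -> float:
    # blobs must stay resolvable on coarse grids: an object falling midway
    # between samples would otherwise render subthreshold
    return max(BLOB_WIDTH, 1.2 * dim.spacing)


def _spatial_blob(grids: SceneGrids, pos) -> np.ndarray:
    gx, gy = grids.spatial
    w = effective_blob_width(gx)
    X, Y = np.meshgrid(gx.grid, gy.grid, indexing="ij")
    return np.exp(-((X - pos[0]) ** 2 + (Y - pos[1]) ** 2) / (2 * w**2))


def _feature_profile(dim: DimensionSpec, center: float, width: float) -> np.ndarray:
    d = dim.distance(dim.grid, center)
    return np.exp(-(d**2) / (2 * width**2))


def render_scene(scene: Scene, grids: SceneGrids) -> PerceptionFields:
    """Render objects into feature/space perception fields.

    The perception fields are interaction-free; their settled state is the
    fixed point h + s, with each object contributing a Gaussian blob at
    (position, feature value).
    """
    params = FieldParams(q=0.0)
    fields: dict[str, Field] = {}
    for name, fdim in grids.features.items():
        dims = [grids.spatial[0], grids.spatial[1], fdim]
        s = np.zeros(tuple(d.n for d in dims))
        for o in scene.objects:
            value = o.feature_value(name)
            if value is None:
                continue
            blob = _spatial_blob(grids, o.pos)
            prof = _feature_profile(fdim, value, FEATURE_WIDTHS[name])
            s += BLOB_AMP * blob[:, :, None] * prof[None, None, :]
        f = Field(dims, params, kernel=None, name=f"perception_{name}")
        f.u = params.h + s  # settled fixed point of the interaction-free field
        fields[name] = f
    return PerceptionFields(grids, fields)


def _rate(u: np.ndarray, beta: float = 4.0) -> np.ndarray:
    out = sigmoid(u, beta)
    return np.where(u > 0, out, 0.0)  # zero is the transmission threshold


def calibrate_match_mass(grids: SceneGrids) -> dict[str, float]:
    """Reference contraction mass of one exactly matching object per feature.

    Shipped as the calibration utility for the conjunction inhibition: the
    soft match detectors compare observed contraction mass against half of
    this single-object reference.
    """
    ref = {}
    bx, by = grids.spatial
    center = ((bx.lo + bx.hi) / 2, (by.lo + by.hi) / 2)
    for name, fdim in grids.features.items():
        blob = _spatial_blob(grids, center)
        prof = _feature_profile(fdim, float(fdim.grid[fdim.n // 2]), FEATURE_WIDTHS[name])
        u = -5.0 + BLOB_AMP * blob[:, :, None] * prof[None, None, :]
        cue = _feature_profile(fdim, float(fdim.grid[fdim.n // 2]), FEATURE_WIDTHS[name])
        att = -5.0 + 3.0 * _rate(u) + 3.0 * cue[None, None, :]
        mass = _rate(att).sum(axis=2).max() * fdim.spacing
        ref[name] = float(mass)
    return ref


def _soft_match(mass: np.ndarray, ref_mass: float) -> np.ndarray:
    """Squash contraction mass into a near-binary match rate."""
    m0 = 0.5 * ref_mass
    return sigmoid(4.0 * (mass - m0) / m0, 1.0)


def _presence(percepts: PerceptionFields) -> np.ndarray:
    """Spatial object-presence rate from the shape perception field."""
    fdim = percepts.grids.features["shape"]
    u = percepts.fields["shape"].u
    mass = _rate(u).sum(axis=2) * fdim.spacing
    ref = calibrate_match_mass(percepts.grids)["shape"]
    # uncued presence: perception output alone carries the field over
    # threshold when boosted, so compare against the cued reference scaled
    # to the perception-only mass
    u_att = -5.0 + 6.0 * _rate(u)
    mass_att = _rate(u_att).sum(axis=2) * fdim.spacing
    return _soft_match(mass_att, ref)


def cue_attention(
    active_concepts: list[ConceptDef],
    percepts: PerceptionFields,
    guidance_bias: np.ndarray | None = None,
    settle_ms: float = 80.0,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Field:
    """Cued conjunction search: settle the 2-D spatial attention field.

    Every cued feature dimension contributes slice input overlapping the
    perception output; the contraction of each feature/space attention
    field is squashed into a match rate, and match-count inhibition
    ``-MATCH_COST * K`` ensures only full conjunctions reach threshold.
    """
    grids = percepts.grids
    for c in active_concepts:
        if c.kind not in ("property", "object"):
            raise ValueError(f"cannot cue with {c.kind} concept {c.name!r}")
    # one cue channel per templated feature value: two property cues on the
    # same feature dimension (an unsatisfiable conjunction) each count
    # toward the match inhibition
    cues: list[tuple[str, np.ndarray]] = []
    for c in active_concepts:
        for dim_name, (center, width) in c.feature_templates.items():
            prof = _feature_profile(grids.features[dim_name], center, width)
            cues.append((dim_name, prof))
    ref_mass = calibrate_match_mass(grids)
    K = len(cues)
    s = PRESENCE_GAIN * _presence(percepts) - MATCH_COST * K
    for dim_name, cue in cues:
        fdim = grids.features[dim_name]
        u_att = -5.0 + 3.0 * _rate(percepts.fields[dim_name].u) + 3.0 * cue[None, None, :]
        mass = _rate(u_att).sum(axis=2) * fdim.spacing
        s = s + MATCH_GAIN * _soft_match(mass, ref_mass[dim_name])
    if guidance_bias is not None:
        s = s + GUIDANCE_GAIN * np.asarray(guidance_bias)
    dims = list(grids.spatial)
    att = Field(dims, FieldParams(q=noise), kernel_preset("detect", dims), "spatial_attention")
    settle_field(att, s, max_ms=settle_ms, tol=1e-4, rng=rng)
    return att


def make_ior_field(grids: SceneGrids) -> Field:
    dims = list(grids.spatial)
    return Field(dims, FieldParams(q=0.0), kernel_preset("memory", dims), "ior")


def mark_ior(ior_field: Field, location, settle_ms: float = 120.0) -> Field:
    """Lay down a sustained inhibition-of-return peak at a location."""
    gx, gy = ior_field.dims
    if not (gx.lo <= location[0] <= gx.hi and gy.lo <= location[1] <= gy.hi):
        raise ValueError("IoR location outside bounds")
    X, Y = np.meshgrid(gx.grid, gy.grid, indexing="ij")
    w = effective_blob_width(gx)
    boost = 8.0 * np.exp(
        -((X - location[0]) ** 2 + (Y - location[1]) ** 2) / (2 * w**2)
    )
    settle_field(ior_field, boost, max_ms=settle_ms, tol=1e-4)
    settle_field(ior_field, 0.0, max_ms=60.0, tol=1e-4)  # peak must self-sustain
    return ior_field


def reset_ior(ior_field: Field) -> Field:
    ior_field.reset()
    return ior_field


def select_target(
    spatial_attention: Field,
    ior_field: Field | None = None,
    settle_ms: float = 150.0,
    rng: np.random.Generator | None = None,
    noise: float = 0.0,
) -> tuple[float, float] | None:
    """Winner-take-all selection of a single target location.

    All candidate drives stay below the detection threshold; a slowly
    rising homogeneous boost induces the selection decision, so the
    strongest candidate wins even against near-equal competitors.
    Candidates under an IoR peak are suppressed; returns the peak centroid
    of the selective target field, or None if nothing reaches threshold
    ("none" is a valid outcome consumed by the process control).
    """
    dims = list(spatial_attention.dims)
    s = ATT_GAIN * np.where(
        spatial_attention.u > 0, sigmoid(spatial_attention.u, TARGET_BETA), 0.0
    )
    if ior_field is not None:
        s = s - IOR_GAIN * _rate(ior_field.u)
    # perfectly symmetric candidates would annihilate each other in the
    # selective regime; a minuscule fixed gradient breaks exact ties
    # deterministically (lower-left first) without overriding any real bias
    gx, gy = dims
    X, Y = np.meshgrid(gx.grid, gy.grid, indexing="ij")
    s = s + 0.02 * ((gx.hi - X) / (gx.hi - gx.lo) + 0.5 * (gy.hi - Y) / (gy.hi - gy.lo))
    target = Field(dims, FieldParams(q=noise), kernel_preset("select", dims), "target")
    peaks = select_by_boost(target, s, rng=rng if noise > 0 else None)
    if not peaks:
        return None
    return peaks[0].location[:2]


def read_motion_dir(percepts: PerceptionFields, location) -> float | None:
    """Motion direction represented at a scene location (circular centroid)."""
    f = percepts.fields["dir"]
    gx, gy, gdir = f.dims
    ix, iy = gx.index_of(location[0]), gy.index_of(location[1])
    col = f.u[ix, iy, :]
    if col.max() <= 0:
        return None
    w = np.where(col > 0, col, 0.0)
    ang = np.deg2rad(gdir.grid)
    c = float(np.average(np.cos(ang), weights=w))
    s = float(np.average(np.sin(ang), weights=w))
    return float(math.degrees(math.atan2(s, c)) % 360.0)
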