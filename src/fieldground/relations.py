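"""Spatial and movement relation concepts as patterned connectivity.

A relation concept is a weight pattern over difference coordinates
d = target - reference.  The pattern is the product of an angular profile
around the relation's canonical axis (a Gaussian of width 45 deg with an
inhibitory surround that turns negative beyond 90 deg off-axis) and a
radial plateau that excludes a small disk around the origin, so that a
target sitting on its reference never matches.  Movement relations use the
same machinery on the difference plane rotated into the agent's motion
direction: "approach" holds when the patient lies ahead of the agent along
its motion axis.

Matching is a neural detection decision: a relation match field receives a
localized bump at the observed difference plus the template as patterned
input, and a supra-threshold peak signals the match.  The amplitudes are
calibrated so that the decision boundary sits at ``MATCH_CONE_DEG`` off
the canonical axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from fieldground.fields import (
    DimensionSpec,
    Field,
    FieldParams,
    detect_peaks,
    kernel_preset,
    settle_field,
)
from fieldground.transforms import TransformSpec, invert_to_scene, relational_dims

__all__ = [
    "RelationTemplate",
    "make_template",
    "relational_match",
    "guidance_bias",
    "MatchResult",
    "template_value",
    "SPATIAL_RELATIONS",
    "MOVEMENT_RELATIONS",
    "ANGULAR_WIDTH_DEG",
    "MATCH_CONE_DEG",
    "ORACLE_R_MIN",
]

# canonical axis (polar angle, deg) of each relation on the difference plane;
# for movement relations the plane has been rotated so the agent's motion
# direction points along +x, hence "approach" (patient ahead) is the -x
# direction of d = agent - patient.
SPATIAL_RELATIONS = {
    "left_of": 180.0,
    "right_of": 0.0,
    "above": 90.0,
    "below": 270.0,
}
MOVEMENT_RELATIONS = {"approach": 180.0}

ANGULAR_WIDTH_DEG = 45.0  # width of the angular Gaussian
MATCH_CONE_DEG = 45.0  # calibrated decision boundary off the canonical axis
R_INNER = 3.0  # template zero inside this radius
R_FULL = 6.0  # full radial strength beyond this radius
ORACLE_R_MIN = 5.0  # symbolic-geometry counterpart of the radial ramp

# angular profile value at the decision boundary: the match amplitudes are
# chosen so the neural detection threshold is crossed exactly there
_SURROUND = math.exp(-(90.0**2) / (2 * ANGULAR_WIDTH_DEG**2))
T_CRIT = (math.exp(-(MATCH_CONE_DEG**2) / (2 * ANGULAR_WIDTH_DEG**2)) - _SURROUND) / (
    1.0 - _SURROUND
)

BUMP_GAIN = 3.0  # localized difference bump (subthreshold alone)
BUMP_WIDTH = 2.5
# template gain: bump + gain * T_CRIT reaches the field threshold (|h| = 5)
TEMPLATE_GAIN = 2.0 / T_CRIT


@dataclass(frozen=True)
class RelationTemplate:
    """Named weight pattern over difference coordinates."""

    name: str
    pattern: np.ndarray
    kind: str  # "spatial" | "movement"
    dims: tuple[DimensionSpec, DimensionSpec]

    def value_at(self, d: tuple[float, float]) -> float:
        return template_value(self.name, d)


def _angular_profile(delta_deg: np.ndarray) -> np.ndarray:
    """Gaussian of width 45 deg, shifted to cross zero at 90 deg off-axis."""
    g = np.exp(-(delta_deg**2) / (2 * ANGULAR_WIDTH_DEG**2))
    return (g - _SURROUND) / (1.0 - _SURROUND)


def _radial_profile(r: np.ndarray) -> np.ndarray:
    return np.clip((r - R_INNER) / (R_FULL - R_INNER), 0.0, 1.0)


def template_value(name: str, d: tuple[float, float]) -> float:
    """Analytic template value at one difference vector."""
    axis = {**SPATIAL_RELATIONS, **MOVEMENT_RELATIONS}[name]
    dx, dy = float(d[0]), float(d[1])
    r = math.hypot(dx, dy)
    if r == 0.0:
        return 0.0
    ang = math.degrees(math.atan2(dy, dx))
    delta = abs((ang - axis + 180.0) % 360.0 - 180.0)
    return float(_angular_profile(np.array(delta)) * _radial_profile(np.array(r)))


def make_template(name: str, scene_dims) -> RelationTemplate:
    """Sample a named relation pattern on the relational grid."""
    if name in SPATIAL_RELATIONS:
        axis, kind = SPATIAL_RELATIONS[name], "spatial"
    elif name in MOVEMENT_RELATIONS:
        axis, kind = MOVEMENT_RELATIONS[name], "movement"
    else:
        raise KeyError(f"unknown relation {name!r}")
    rdims = relational_dims(list(scene_dims))
    DX, DY = np.meshgrid(rdims[0].grid, rdims[1].grid, indexing="ij")
    r = np.hypot(DX, DY)
    ang = np.degrees(np.arctan2(DY, DX))
    delta = np.abs((ang - axis + 180.0) % 360.0 - 180.0)
    pattern = _angular_profile(delta) * _radial_profile(r)
    pattern[r == 0] = 0.0
    return RelationTemplate(name, pattern, kind, (rdims[0], rdims[1]))


@dataclass(frozen=True)
class MatchResult:
    match: bool
    score: float
    difference: tuple[float, float]


def _rotate_vec(d: tuple[float, float], direction: float) -> tuple[float, float]:
    th = -math.radians(direction)
    c, s = math.cos(th), math.sin(th)
    return (c * d[0] - s * d[1], s * d[0] + c * d[1])


def relational_match(
    target_loc,
    reference_loc,
    template: RelationTemplate,
    motion_dir: float | None = None,
    settle_ms: float = 60.0,
) -> MatchResult:
    """Settle the relation match field and report whether a peak formed.

    The field receives a localized bump at the observed difference
    (rotated into the motion frame for movement relations) plus the
    template as patterned input; only where both align does activation
    reach threshold.
    """
    if template.kind == "movement":
        if motion_dir is None:
            raise ValueError("movement relations require motion_dir")
        d = _rotate_vec(
            (target_loc[0] - reference_loc[0], target_loc[1] - reference_loc[1]),
            motion_dir,
        )
    else:
        d = (target_loc[0] - reference_loc[0], target_loc[1] - reference_loc[1])
    dims = template.dims
    DX, DY = np.meshgrid(dims[0].grid, dims[1].grid, indexing="ij")
    bump = np.exp(-((DX - d[0]) ** 2 + (DY - d[1]) ** 2) / (2 * BUMP_WIDTH**2))
    s = BUMP_GAIN * bump + TEMPLATE_GAIN * template.pattern
    f = Field(dims, FieldParams(q=0.0), kernel_preset("detect", dims), "relation_match")
    settle_field(f, s, max_ms=settle_ms, tol=1e-4)
    peaks = detect_peaks(f)
    score = float((bump * template.pattern).sum()) * dims[0].spacing * dims[1].spacing
    return MatchResult(bool(peaks), score, d)


def guidance_bias(
    template: RelationTemplate,
    reference_loc,
    scene_dims,
) -> np.ndarray:
    """Scene-frame attention bias: the template centered on the reference.

    Delegates to the inverse coordinate transform with a point reference,
    so the bias at a location x equals the template at x - reference.
    """
    spec = TransformSpec(in_dims=tuple(scene_dims))
    for dim, v in zip(scene_dims, reference_loc):
        if not (dim.lo <= v <= dim.hi):
            raise ValueError("reference location outside scene bounds")
    ref = np.zeros(tuple(d.n for d in scene_dims))
    ix = scene_dims[0].index_of(reference_loc[0])
    iy = scene_dims[1].index_of(reference_loc[1])
    ref[ix, iy] = 1.0
    bias, ok = invert_to_scene(template.pattern, ref, spec)
    return bias
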