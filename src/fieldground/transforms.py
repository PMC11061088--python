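"""Steerable neural maps: reference-centering, its inverse, and rotation.

The relational representation of "where is the target relative to the
reference" is a map over difference coordinates d = target - reference.
Neurally this is computed in a gain field — a joint representation of
target and reference position in which sub-threshold ridges from both maps
overlap, and a projection along the diagonal reads out the difference.
Because the full joint field over two 2-D maps is quartic in the grid size,
the default implementation computes the identical input-output contract
algebraically by cross-correlation; the literal gain field remains
available at low resolution and is verified against the fast path in the
test suite.

Convention: x increases rightward, y increases upward; "left of" means the
target has smaller x than the reference.  Differences that would fall
outside the relational grid are clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

from fieldground.fields import DimensionSpec, sigmoid

__all__ = [
    "TransformSpec",
    "relational_dims",
    "center_on_reference",
    "invert_to_scene",
    "rotate_relational",
]

MODES = ("center_on_reference", "invert_to_scene", "rotate")
IMPLEMENTATIONS = ("algebraic", "explicit_gain_field")


def relational_dims(scene_dims: Sequence[DimensionSpec]) -> list[DimensionSpec]:
    """Difference-coordinate dimensions covering all reachable differences.

    Each spatial dimension of extent E maps to a relational dimension over
    [-E, +E] at the same grid spacing (2n - 1 samples).
    """
    out = []
    for d in scene_dims:
        extent = d.hi - d.lo
        out.append(
            DimensionSpec(f"d{d.name}", -extent, extent, 2 * d.n - 1, circular=False)
        )
    return out


@dataclass(frozen=True)
class TransformSpec:
    """Configuration of one steerable-map transform."""

    in_dims: tuple[DimensionSpec, ...]
    mode: str = "center_on_reference"
    implementation: str = "algebraic"
    gain_field_h: float = -5.0
    gain_field_beta: float = 4.0
    ridge_gain: float = 3.5

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown transform mode {self.mode!r}")
        if self.implementation not in IMPLEMENTATIONS:
            raise ValueError(f"unknown implementation {self.implementation!r}")

    @property
    def out_dims(self) -> list[DimensionSpec]:
        return relational_dims(list(self.in_dims))


def _normalized_reference(reference_map: np.ndarray, eps: float = 1e-9):
    ref = np.asarray(reference_map, dtype=float)
    mass = float(ref.sum())
    if mass <= eps:
        return None
    return ref / mass


def center_on_reference(
    target_map: np.ndarray,
    reference_map: np.ndarray,
    spec: TransformSpec,
) -> tuple[np.ndarray, bool]:
    """Represent the target map in reference-centered (difference) coordinates.

    Returns ``(relational_map, ok)``; with no supra-threshold mass in the
    reference the transform is flagged and the output is zero.  For a single
    reference peak at r and a target peak at t the output peaks at t - r.
    """
    t = np.asarray(target_map, dtype=float)
    shape = tuple(d.n for d in spec.in_dims)
    if t.shape != shape or np.shape(reference_map) != shape:
        raise ValueError("target and reference maps must share the scene grid")
    out_shape = tuple(2 * n - 1 for n in shape)
    ref = _normalized_reference(reference_map)
    if ref is None:
        return np.zeros(out_shape), False
    if spec.implementation == "explicit_gain_field":
        return _gain_field_center(t, ref, spec), True
    # rel[d] = sum_r t[r + d] * ref[r]; full cross-correlation
    rel = signal.fftconvolve(t, ref[tuple(slice(None, None, -1) for _ in shape)], mode="full")
    rel = np.maximum(rel, 0.0)
    return rel, True


def _gain_field_center(t: np.ndarray, ref: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Literal joint (gain) field with diagonal read-out projection."""
    nx, ny = t.shape
    # joint activation over (target position, reference position): ridges
    # from both maps overlap; supra-threshold output is read out
    ref_amp = ref / max(float(ref.max()), 1e-12)  # ridge height ~1 per peak
    u = (
        spec.gain_field_h
        + spec.ridge_gain * t[:, :, None, None]
        + spec.ridge_gain * ref_amp[None, None, :, :]
    )
    g = sigmoid(u, spec.gain_field_beta)
    g = np.where(u > 0, g, 0.0)
    out = np.zeros((2 * nx - 1, 2 * ny - 1))
    # diagonal projection: accumulate g at difference (tx - rx, ty - ry)
    tx, ty, rx, ry = np.nonzero(g > 0)
    np.add.at(out, (tx - rx + nx - 1, ty - ry + ny - 1), g[tx, ty, rx, ry])
    return out


def invert_to_scene(
    relational_template: np.ndarray,
    reference_map: np.ndarray,
    spec: TransformSpec,
) -> tuple[np.ndarray, bool]:
    """Shift a relational template so its origin sits on the reference.

    The exact adjoint of :func:`center_on_reference`:
    ``<center(t, r), T> == <t, invert(T, r)>`` for all maps.  Template mass
    falling outside the scene (reference near a border) is clipped.
    """
    shape = tuple(d.n for d in spec.in_dims)
    T = np.asarray(relational_template, dtype=float)
    if T.shape != tuple(2 * n - 1 for n in shape):
        raise ValueError("template must live on the relational grid")
    if np.shape(reference_map) != shape:
        raise ValueError("reference map must live on the scene grid")
    ref = _normalized_reference(reference_map)
    if ref is None:
        return np.zeros(shape), False
    # bias[x] = sum_r ref[r] * T[x - r]  -> convolution, cropped to scene
    full = signal.fftconvolve(ref, T, mode="full")
    # full has shape 3n-2; scene window starts at offset n-1
    window = tuple(slice(n - 1, 2 * n - 1) for n in shape)
    return full[window], True


def rotate_relational(relational_map: np.ndarray, direction: float) -> np.ndarray:
    """Rotate the difference plane by ``-direction`` about the origin.

    Aligns the target's motion direction with the canonical +x axis:
    a peak at polar angle ``direction`` maps onto the +x axis.  Bilinear
    interpolation; ``rotate(m, 0)`` is the identity.
    """
    m = np.asarray(relational_map, dtype=float)
    if not (0.0 <= direction < 360.0):
        direction = float(direction) % 360.0
    if direction == 0.0:
        return m.copy()
    th = np.deg2rad(direction)
    c, s = np.cos(th), np.sin(th)
    # output(d') = input(R d') with R = rotation by +direction in (x, y)
    R = np.array([[c, -s], [s, c]])
    center = (np.array(m.shape, dtype=float) - 1.0) / 2.0
    offset = center - R @ center
    return ndimage.affine_transform(m, R, offset=offset, order=1, mode="constant", cval=0.0)
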