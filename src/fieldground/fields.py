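"""Dynamic neural fields and nodes.

The representational substrate of the package: activation variables that
evolve in continuous time under

    tau * du/dt = -u + h + s + interaction + noise

where the interaction term is a lateral kernel that excites locally and
inhibits globally.  Supra-threshold peaks (u > 0) are the elementary units
of representation; detection, reverse detection, selection and sustained
activation (working memory) are all regimes of the same dynamics, set by
the kernel parameters.

Activation is sampled on regular grids over named dimensions.  Continuous
dimensions (visual space, hue, motion direction) carry the Gaussian lateral
kernel; discrete dimensions (concept axes, the object-index axis) carry
pure self-excitation per sample, which is the zero-width limit of the same
kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "DimensionSpec",
    "IndexDimension",
    "KernelParams",
    "FieldParams",
    "NodeParams",
    "Field",
    "Node",
    "Peak",
    "sigmoid",
    "make_kernel",
    "field_step",
    "node_step",
    "detect_peaks",
    "run_until_settled",
    "kernel_preset",
    "settle_field",
    "EventLog",
]


# --------------------------------------------------------------------------
# dimensions


@dataclass(frozen=True)
class DimensionSpec:
    """A sampled continuous dimension (space in scene units, angles in deg).

    Circular dimensions identify ``lo`` with ``hi``; the sample at ``hi`` is
    therefore not stored.
    """

    name: str
    lo: float
    hi: float
    n: int
    circular: bool = False

    def __post_init__(self) -> None:
        if self.n < 8:
            raise ValueError(f"dimension {self.name!r}: need n >= 8, got {self.n}")
        if not self.hi > self.lo:
            raise ValueError(f"dimension {self.name!r}: need hi > lo")

    @property
    def spacing(self) -> float:
        if self.circular:
            return (self.hi - self.lo) / self.n
        return (self.hi - self.lo) / (self.n - 1)

    @property
    def grid(self) -> np.ndarray:
        if self.circular:
            return self.lo + self.spacing * np.arange(self.n)
        return np.linspace(self.lo, self.hi, self.n)

    def index_of(self, value: float) -> int:
        """Nearest sample index for a physical coordinate."""
        if self.circular:
            span = self.hi - self.lo
            return int(round((value - self.lo) % span / self.spacing)) % self.n
        return int(np.clip(round((value - self.lo) / self.spacing), 0, self.n - 1))

    def distance(self, a, b):
        """Signed sample distance ``a - b`` respecting circularity."""
        d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
        if self.circular:
            span = self.hi - self.lo
            d = (d + span / 2.0) % span - span / 2.0
        return d


@dataclass(frozen=True)
class IndexDimension:
    """A discrete axis: object/relation/action indices or a concept axis.

    No lateral kernel acts along it; each sample is its own category.
    """

    name: str
    n: int
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("index dimension needs n >= 1")
        if self.labels is not None and len(self.labels) != self.n:
            raise ValueError("labels must match n")

    @property
    def spacing(self) -> float:
        return 1.0

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.n, dtype=float)

    circular = False

    def index_of(self, value) -> int:
        if isinstance(value, str):
            if self.labels is None:
                raise KeyError(value)
            return self.labels.index(value)
        return int(value)


Dim = DimensionSpec | IndexDimension


# --------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class KernelParams:
    """Lateral interaction: local Gaussian excitation, global inhibition.

    w(x - x') = w_exc * exp(-(x - x')^2 / (2 sigma^2)) - w_inhib
    """

    w_exc: float
    w_inhib: float
    sigma: float

    def __post_init__(self) -> None:
        if self.w_exc < 0 or self.w_inhib < 0:
            raise ValueError("kernel weights must be non-negative")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class FieldParams:
    tau: float = 10.0  # ms
    h: float = -5.0  # resting level, < 0
    beta: float = 4.0  # sigmoid steepness
    q: float = 0.1  # noise strength

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if not self.h < 0:
            raise ValueError("resting level h must be negative")
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if self.q < 0:
            raise ValueError("noise strength q must be non-negative")


@dataclass(frozen=True)
class NodeParams(FieldParams):
    w_se: float = 0.0  # self-excitation
    w_comp: float = 0.0  # inhibition from competitor output

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.w_se < 0 or self.w_comp < 0:
            raise ValueError("node interaction weights must be non-negative")


# --------------------------------------------------------------------------
# elementary functions


def sigmoid(u, beta: float):
    """Threshold function sigma(u) = 1 / (1 + exp(-beta u))."""
    if not beta > 0:
        raise ValueError("beta must be positive")
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite activation")
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-beta * u[pos]))
    eu = np.exp(beta * u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out if out.ndim else float(out)


def make_kernel(kp: KernelParams, dim: DimensionSpec) -> np.ndarray:
    """Sample the lateral kernel over all pairwise distances of ``dim``.

    Returns the kernel evaluated at the signed distances of every sample to
    the sample at index 0 (wrap-around minimal distance on circular dims),
    so ``out[i] = w(grid[i] - grid[0])``.
    """
    d = dim.distance(dim.grid, dim.grid[0])
    return kp.w_exc * np.exp(-(d**2) / (2.0 * kp.sigma**2)) - kp.w_inhib


# --------------------------------------------------------------------------
# fields


class Field:
    """A dynamic neural field sampled over one to four named dimensions.

    ``kernel=None`` means interaction-free dynamics (pure relaxation to
    ``h + s``).  The lateral kernel smooths along continuous dimensions
    only; along discrete dimensions the excitation is per-sample
    self-excitation.  Global inhibition is applied as a scalar
    ``-w_inhib * integral of output`` over the whole field, which is
    equivalent to carrying the constant term inside the kernel array.
    """

    def __init__(
        self,
        dims: Sequence[Dim],
        params: FieldParams | None = None,
        kernel: KernelParams | None = None,
        name: str = "field",
        u: np.ndarray | None = None,
    ):
        self.dims = list(dims)
        self.params = params or FieldParams()
        self.kernel = kernel
        self.name = name
        shape = tuple(d.n for d in self.dims)
        if u is None:
            u = np.full(shape, self.params.h, dtype=float)
        else:
            u = np.asarray(u, dtype=float)
            if u.shape != shape:
                raise ValueError(f"u shape {u.shape} does not match dims {shape}")
        if not np.all(np.isfinite(u)):
            raise ValueError("non-finite activation")
        self.u = u

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(d.n for d in self.dims)

    @property
    def dim_names(self) -> list[str]:
        return [d.name for d in self.dims]

    def dim(self, name: str) -> Dim:
        for d in self.dims:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def cell_volume(self) -> float:
        """Product of grid spacings (physical volume element)."""
        return float(np.prod([d.spacing for d in self.dims]))

    def output(self) -> np.ndarray:
        return sigmoid(self.u, self.params.beta)

    def interaction(self) -> np.ndarray:
        """Lateral interaction input: kernel correlated with the output."""
        if self.kernel is None:
            return np.zeros(self.shape)
        g = self.output()
        exc = g
        amp = self.kernel.w_exc
        for ax, d in enumerate(self.dims):
            if isinstance(d, IndexDimension):
                continue  # delta kernel along discrete axes
            exc = ndimage.gaussian_filter1d(
                exc,
                sigma=self.kernel.sigma / d.spacing,
                axis=ax,
                mode="wrap" if d.circular else "constant",
                cval=0.0,
            )
            amp *= math.sqrt(2.0 * math.pi) * self.kernel.sigma
        inhib = self.kernel.w_inhib * float(g.sum()) * self.cell_volume
        return amp * exc - inhib

    def reset(self) -> None:
        self.u[...] = self.params.h

    def step(self, s, dt: float, rng: np.random.Generator | None = None) -> float:
        """One explicit Euler step; returns the max |du| of the step."""
        p = self.params
        if dt > p.tau / 5.0 + 1e-12:
            raise ValueError(f"dt={dt} too large for tau={p.tau} (need dt <= tau/5)")
        s = np.broadcast_to(np.asarray(s, dtype=float), self.shape)
        du = (dt / p.tau) * (-self.u + p.h + s + self.interaction())
        if p.q > 0 and rng is not None:
            du = du + p.q * math.sqrt(dt) * rng.standard_normal(self.shape)
        self.u = self.u + du
        return float(np.max(np.abs(du)))

    def copy(self) -> "Field":
        f = Field(self.dims, self.params, self.kernel, self.name, self.u.copy())
        return f


def field_step(f: Field, s, dt: float, rng: np.random.Generator | None = None) -> Field:
    """Functional form of :meth:`Field.step`: returns the updated field."""
    g = f.copy()
    g.step(s, dt, rng)
    return g


# --------------------------------------------------------------------------
# nodes


class Node:
    """A zero-dimensional activation variable for categorical content.

    Self-excitation ``w_se`` makes the node bistable between an on-state
    (output near 1) and an off-state; ``w_comp`` weights inhibition summed
    over competitor outputs.
    """

    def __init__(
        self,
        params: NodeParams | None = None,
        name: str = "node",
        competitors: Sequence[str] = (),
        u: float | None = None,
    ):
        self.params = params or NodeParams()
        self.name = name
        self.competitors = list(competitors)
        self.u = float(self.params.h if u is None else u)
        if not math.isfinite(self.u):
            raise ValueError("non-finite activation")

    def output(self) -> float:
        return float(sigmoid(self.u, self.params.beta))

    @property
    def on(self) -> bool:
        return self.u > 0

    def reset(self) -> None:
        self.u = self.params.h

    def step(
        self,
        s: float,
        competitor_outputs: Iterable[float] = (),
        dt: float = 1.0,
        rng: np.random.Generator | None = None,
    ) -> float:
        p = self.params
        if dt > p.tau / 5.0 + 1e-12:
            raise ValueError(f"dt={dt} too large for tau={p.tau}")
        comp = p.w_comp * float(sum(competitor_outputs))
        du = (dt / p.tau) * (-self.u + p.h + s + p.w_se * self.output() - comp)
        if p.q > 0 and rng is not None:
            du += p.q * math.sqrt(dt) * float(rng.standard_normal())
        self.u += du
        return abs(du)

    def copy(self) -> "Node":
        return Node(self.params, self.name, self.competitors, self.u)


def node_step(
    n: Node,
    s: float,
    competitor_outputs: Iterable[float] = (),
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
) -> Node:
    m = n.copy()
    m.step(s, competitor_outputs, dt, rng)
    return m


# --------------------------------------------------------------------------
# peaks


@dataclass(frozen=True)
class Peak:
    """One connected supra-threshold region of a field."""

    location: tuple[float, ...]  # activation-weighted centroid, physical units
    mass: float  # integral of supra-threshold activation
    indices: tuple[np.ndarray, ...] = dc_field(repr=False, default=())

    def __iter__(self):
        return iter(self.location)


def _label_with_wrap(mask: np.ndarray, dims: Sequence[Dim]) -> tuple[np.ndarray, int]:
    """Connected components; discrete axes do not connect, circular axes wrap."""
    structure = np.zeros((3,) * mask.ndim, dtype=bool)
    center = (1,) * mask.ndim
    structure[center] = True
    for ax, d in enumerate(dims):
        if isinstance(d, IndexDimension):
            continue
        lo = list(center)
        hi = list(center)
        lo[ax] = 0
        hi[ax] = 2
        structure[tuple(lo)] = True
        structure[tuple(hi)] = True
    # full connectivity across continuous axes (diagonals included)
    cont = [ax for ax, d in enumerate(dims) if not isinstance(d, IndexDimension)]
    if len(cont) > 1:
        idx = np.indices(structure.shape)
        sel = np.ones(structure.shape, dtype=bool)
        for ax in range(mask.ndim):
            if ax not in cont:
                sel &= idx[ax] == 1
        structure |= sel
    labels, n = ndimage.label(mask, structure=structure)
    # merge labels split across circular boundaries
    for ax, d in enumerate(dims):
        if not (isinstance(d, DimensionSpec) and d.circular) or d.n < 2:
            continue
        first = np.take(labels, 0, axis=ax)
        last = np.take(labels, d.n - 1, axis=ax)
        pairs = set(zip(first.ravel().tolist(), last.ravel().tolist()))
        mapping = {}
        for a, b in pairs:
            if a and b and a != b:
                ra, rb = mapping.get(a, a), mapping.get(b, b)
                if ra != rb:
                    keep, drop = min(ra, rb), max(ra, rb)
                    labels[labels == drop] = keep
                    for k, v in list(mapping.items()):
                        if v == drop:
                            mapping[k] = keep
                    mapping[drop] = keep
    uniq = np.unique(labels)
    uniq = uniq[uniq > 0]
    relabel = {int(v): i + 1 for i, v in enumerate(uniq)}
    out = np.zeros_like(labels)
    for v, i in relabel.items():
        out[labels == v] = i
    return out, len(uniq)


def detect_peaks(f: Field, threshold: float = 0.0, min_mass: float = 0.0) -> list[Peak]:
    """Connected supra-threshold regions with activation-weighted centroids.

    Circular dimensions use the circular mean; zero is the transmission
    threshold by convention.  ``min_mass`` discards micro-regions whose
    integrated supra-threshold activation is below the given value — during
    a selection instability competing sites may cross threshold transiently
    before the competition resolves, and such transition states are not
    self-stabilized peaks.
    """
    mask = f.u > threshold
    if not mask.any():
        return []
    labels, n = _label_with_wrap(mask, f.dims)
    peaks = []
    for i in range(1, n + 1):
        idx = np.nonzero(labels == i)
        w = f.u[idx] - threshold
        wsum = float(w.sum())
        loc = []
        for ax, d in enumerate(f.dims):
            coords = d.grid[idx[ax]]
            if isinstance(d, DimensionSpec) and d.circular:
                span = d.hi - d.lo
                ang = (coords - d.lo) * (2 * np.pi / span)
                c = float(np.average(np.cos(ang), weights=w))
                s = float(np.average(np.sin(ang), weights=w))
                loc.append(d.lo + (math.atan2(s, c) % (2 * np.pi)) * span / (2 * np.pi))
            else:
                loc.append(float(np.average(coords, weights=w)))
        peaks.append(Peak(tuple(loc), wsum * f.cell_volume, idx))
    peaks.sort(key=lambda p: -p.mass)
    return [p for p in peaks if p.mass >= min_mass]


# --------------------------------------------------------------------------
# kernel presets

# Presets are stated in resolution-free terms: `boost` is the interaction
# input at the centre of a broad fully-on region (w_exc times the kernel
# integral), `inhib` is the global inhibition produced by one standard peak
# of unit output over a region of linear size `sigma` per dimension.
_PRESETS: dict[str, dict[str, float]] = {
    # bistable detection: peaks need input to persist, clear hysteresis
    # margin; inhibition weak enough that half a dozen peaks coexist
    "detect": {"boost": 8.0, "inhib": 0.125},
    # winner-take-all: one peak suppresses all others
    "select": {"boost": 8.0, "inhib": 3.75},
    # working memory: peaks survive removal of their inducing input;
    # weak global inhibition leaves room for several simultaneous memories
    "memory": {"boost": 20.0, "inhib": 0.25},
}


def kernel_preset(name: str, dims: Sequence[Dim], sigma: float = 2.5) -> KernelParams:
    """Kernel parameters for a named dynamic regime on the given grid.

    The same named regime produces the same peak behavior independent of
    grid resolution and dimensionality, because the physical amplitudes are
    derived from the kernel integral over the continuous dimensions.
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown kernel preset {name!r}")
    p = _PRESETS[name]
    k = sum(1 for d in dims if isinstance(d, DimensionSpec))
    if k == 0:
        # all-discrete field: pure self-excitation, inhibition per sample
        return KernelParams(w_exc=p["boost"], w_inhib=p["inhib"], sigma=sigma)
    integral = (math.sqrt(2.0 * math.pi) * sigma) ** k
    peak_mass = (2.0 * sigma) ** k  # output mass of one standard peak
    return KernelParams(
        w_exc=p["boost"] / integral,
        w_inhib=p["inhib"] / peak_mass,
        sigma=sigma,
    )


# --------------------------------------------------------------------------
# simulation loops


class EventLog:
    """Ordered record of instability events with simulated timestamps."""

    def __init__(self) -> None:
        self.events: list[dict] = []

    def add(self, t_ms: float, event_type: str, component: str, **info) -> None:
        e = {"t_ms": float(t_ms), "event": event_type, "component": component}
        e.update(info)
        self.events.append(e)

    def of_type(self, *event_types: str) -> list[dict]:
        return [e for e in self.events if e["event"] in event_types]

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


def settle_field(
    f: Field,
    s,
    dt: float = 1.0,
    max_ms: float = 200.0,
    tol: float = 1e-3,
    rng: np.random.Generator | None = None,
    min_ms: float = 20.0,
) -> bool:
    """Step a single field under fixed input until activation stops moving.

    Returns True if the settle criterion (max |du|/ms < tol) was reached
    before ``max_ms``.
    """
    t = 0.0
    while t < max_ms:
        delta = f.step(s, dt, rng)
        t += dt
        if t >= min_ms and delta / dt < tol:
            return True
    return False


def select_by_boost(
    f: Field,
    s,
    ramp_per_ms: float = 0.05,
    boost_cap: float = 4.5,
    hold_ms: float = 120.0,
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
    min_mass: float = 0.5,
) -> list[Peak]:
    """Selection decision induced by a slowly rising homogeneous boost.

    All localized inputs stay below the detection threshold on their own; a
    homogeneous resting-level boost rises until the strongest candidate
    goes through the detection instability, whose global inhibition then
    locks out every other candidate.  The ramp stops at the first peak (or
    at ``boost_cap``) and the field settles for ``hold_ms``.  This yields a
    unique winner even for near-degenerate inputs, because crossings are
    serialized by the ramp rather than simultaneous.
    """
    s = np.broadcast_to(np.asarray(s, dtype=float), f.shape)
    boost = 0.0
    found_at = None
    t = 0.0
    max_ms = boost_cap / ramp_per_ms + 2 * hold_ms
    while t < max_ms:
        f.step(s + boost, dt, rng)
        t += dt
        if found_at is None:
            boost = min(boost + ramp_per_ms * dt, boost_cap)
            if detect_peaks(f, min_mass=min_mass):
                found_at = t
            elif boost >= boost_cap and t > boost_cap / ramp_per_ms + hold_ms:
                return []
        elif t - found_at >= hold_ms:
            break
    return detect_peaks(f, min_mass=min_mass)


def run_until_settled(
    system,
    max_ms: float,
    settle_criterion: float = 1e-3,
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
    input_fn: Callable[[float], dict] | None = None,
    min_ms: float = 10.0,
):
    """Step a coupled system until activation stops changing or timeout.

    ``system`` needs ``step(dt, rng, external=...) -> max |du|`` and an
    ``events`` :class:`EventLog` (see :class:`fieldground.coupling.Network`).
    Returns ``(trajectory, settled)`` where trajectory is the list of
    per-step max changes; timeout is reported in the flag, not raised.
    """
    if not max_ms > 0:
        raise ValueError("max_ms must be positive")
    traj = []
    t = 0.0
    settled = False
    while t < max_ms:
        external = input_fn(t) if input_fn else None
        delta = system.step(dt, rng=rng, external=external)
        t += dt
        traj.append(delta)
        if t >= min_ms and delta / dt < settle_criterion:
            settled = True
            break
    return traj, settled
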