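"""Projections between fields and nodes, and the network container.

Five coupling kinds wire an architecture together while preserving the
meaning of dimensions:

* ``one_to_one`` — same dimensions, activation mapped sample-for-sample;
* ``contract``  — dimensionality reduction by integrating over dropped
  dimensions (grid-spacing weighted so the result is resolution-free);
* ``expand``    — dimensionality increase: input constant along the new
  dimensions ("ridge" or "slice" input);
* ``patterned`` — a node's output times a stored template over the target
  grid (negative weights give the inhibitory counterpart);
* ``boost``     — a node's output as a homogeneous resting-level shift.

Projections always transmit sigmoided output, never raw activation: zero
is the transmission threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np

from fieldground.fields import Dim, EventLog, Field, Node, detect_peaks

__all__ = ["Projection", "apply_projection", "gather_inputs", "Network"]

KINDS = ("one_to_one", "contract", "expand", "patterned", "boost")


@dataclass
class Projection:
    """A directed coupling from one component's output to another's input."""

    source: str
    target: str
    kind: str
    weight: float = 1.0
    # maps source dim name -> target dim name for dims that survive;
    # source dims absent from the map are summed out (contract), target
    # dims absent from the values are tiled (expand).
    dim_map: Mapping[str, str] = dc_field(default_factory=dict)
    template: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown projection kind {self.kind!r}")
        if not np.isfinite(self.weight):
            raise ValueError("projection weight must be finite")
        if self.kind == "patterned" and self.template is None:
            raise ValueError("patterned projection needs a template")


def _as_rate(source, source_output):
    if source_output is not None:
        return np.asarray(source_output, dtype=float)
    return source.output()


def apply_projection(
    p: Projection,
    source_output,
    source_dims: Sequence[Dim] | None = None,
    target_dims: Sequence[Dim] | None = None,
) -> np.ndarray:
    """Map a source output (rate) array onto the target's input grid."""
    out = np.asarray(source_output, dtype=float)
    if p.kind == "boost":
        rate = float(np.asarray(out).sum()) if out.ndim else float(out)
        base = p.weight * rate
        if target_dims is None:
            return np.asarray(base)
        return np.full(tuple(d.n for d in target_dims), base)
    if p.kind == "patterned":
        rate = float(np.asarray(out).sum()) if out.ndim else float(out)
        return p.weight * rate * p.template
    if p.kind == "one_to_one":
        return p.weight * out
    if source_dims is None:
        raise ValueError(f"{p.kind} projection needs source dims")
    names = [d.name for d in source_dims]
    if out.shape != tuple(d.n for d in source_dims):
        raise ValueError("source output shape does not match source dims")
    for n in p.dim_map:
        if n not in names:
            raise KeyError(f"dim {n!r} not in source dims {names}")
    if p.kind == "contract":
        dropped = [i for i, n in enumerate(names) if n not in p.dim_map]
        vol = float(np.prod([source_dims[i].spacing for i in dropped])) if dropped else 1.0
        res = out.sum(axis=tuple(dropped)) * vol if dropped else out.copy()
        kept = [n for n in names if n in p.dim_map]
        if target_dims is not None:
            order = [kept.index(s) for s, t in _target_order(p, target_dims, kept)]
            res = np.transpose(res, order) if order else res
        return p.weight * res
    if p.kind == "expand":
        if target_dims is None:
            raise ValueError("expand projection needs target dims")
        mapped = {p.dim_map[n]: i for i, n in enumerate(names) if n in p.dim_map}
        # reorder source axes to the order their targets appear in
        src_order = [mapped[d.name] for d in target_dims if d.name in mapped]
        arr = np.transpose(out, src_order)
        shape = tuple(
            d.n if d.name in mapped else 1 for d in target_dims
        )
        arr = arr.reshape(shape)
        return p.weight * np.broadcast_to(
            arr, tuple(d.n for d in target_dims)
        ).copy()
    raise AssertionError(p.kind)


def _target_order(p: Projection, target_dims: Sequence[Dim], kept: list[str]):
    pairs = []
    for d in target_dims:
        for s, t in p.dim_map.items():
            if t == d.name and s in kept:
                pairs.append((s, t))
    return pairs


def gather_inputs(
    target,
    projections: Sequence[Projection],
    state: Mapping[str, "Field | Node"],
    external=None,
) -> np.ndarray:
    """Sum all projection inputs converging on ``target`` plus external input.

    Linear in every source output; an empty projection list yields zeros.
    """
    if isinstance(target, str):
        target = state[target]
    t_dims = target.dims if isinstance(target, Field) else None
    shape = target.shape if isinstance(target, Field) else ()
    total = np.zeros(shape)
    for p in projections:
        if p.target != getattr(target, "name", None):
            raise ValueError(f"projection targets {p.target!r}, not the given target")
        src = state[p.source]
        s_dims = src.dims if isinstance(src, Field) else None
        contrib = apply_projection(p, src.output(), s_dims, t_dims)
        total = total + contrib
    if external is not None:
        total = total + np.asarray(external, dtype=float)
    return total


class Network:
    """A set of named fields and nodes wired by projections.

    ``step`` advances every component synchronously by one Euler step and
    records instability events (peak created/destroyed, node on/off) in the
    event log.  Recurrent wiring is allowed; there is no cycle check —
    recurrence is the point.
    """

    def __init__(self) -> None:
        self.components: dict[str, Field | Node] = {}
        self.projections: list[Projection] = []
        self.events = EventLog()
        self.t_ms = 0.0
        self._peak_counts: dict[str, int] = {}
        self._node_states: dict[str, bool] = {}

    def add(self, component: Field | Node) -> "Network":
        if component.name in self.components:
            raise ValueError(f"duplicate component name {component.name!r}")
        self.components[component.name] = component
        if isinstance(component, Field):
            self._peak_counts[component.name] = 0
        else:
            self._node_states[component.name] = component.on
        return self

    def connect(self, projection: Projection) -> "Network":
        for end in (projection.source, projection.target):
            if end not in self.components:
                raise KeyError(f"unknown component {end!r}")
        self.projections.append(projection)
        return self

    def incoming(self, name: str) -> list[Projection]:
        return [p for p in self.projections if p.target == name]

    def step(self, dt: float = 1.0, rng=None, external: Mapping[str, np.ndarray] | None = None) -> float:
        external = external or {}
        inputs = {}
        outputs = {n: c.output() for n, c in self.components.items()}
        for name, comp in self.components.items():
            projs = self.incoming(name)
            if isinstance(comp, Field):
                t_dims = comp.dims
                total = np.zeros(comp.shape)
            else:
                t_dims = None
                total = np.zeros(())
            for p in projs:
                src = self.components[p.source]
                s_dims = src.dims if isinstance(src, Field) else None
                total = total + apply_projection(p, outputs[p.source], s_dims, t_dims)
            if name in external:
                total = total + np.asarray(external[name], dtype=float)
            inputs[name] = total
        max_delta = 0.0
        for name, comp in self.components.items():
            if isinstance(comp, Field):
                delta = comp.step(inputs[name], dt, rng)
            else:
                comp_out = [
                    outputs[c] for c in comp.competitors if c in outputs
                ]
                delta = comp.step(float(inputs[name]), comp_out, dt, rng)
            max_delta = max(max_delta, delta)
        self.t_ms += dt
        self._log_transitions()
        return max_delta

    def _log_transitions(self) -> None:
        for name, comp in self.components.items():
            if isinstance(comp, Field):
                n = len(detect_peaks(comp))
                prev = self._peak_counts[name]
                if n > prev:
                    self.events.add(self.t_ms, "peak_created", name, count=n)
                elif n < prev:
                    self.events.add(self.t_ms, "peak_destroyed", name, count=n)
                self._peak_counts[name] = n
            else:
                on = comp.on
                if on != self._node_states[name]:
                    self.events.add(self.t_ms, "node_on" if on else "node_off", name)
                self._node_states[name] = on
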