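"""Autonomous sequencing of the grounding processes.

Four processes ground each object description referenced by a phrase:
*select target candidate* (attend one scene location that matches the
object's concepts), *check relations* (verify each relation bound to the
object, one at a time), *commit* (store the verified location in the
index-map working memory), and *proceed to next target*.  Each process is
a motif of two bistable nodes: an intention node that drives the process,
and a condition-of-satisfaction (CoS) node that receives pre-activation
from the intention plus input reflecting the outcome.  When the outcome
arrives, the CoS node switches on, inhibits the intention through a
reverse detection instability, and then — its pre-activation gone — resets
itself.  Precondition gating serializes the processes; failure of a
relation check re-enters candidate selection with an inhibition-of-return
mark on the rejected location.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from fieldground.concepts import ConceptInventory, default_inventory
from fieldground.fields import (
    EventLog,
    Field,
    FieldParams,
    Node,
    NodeParams,
    detect_peaks,
    kernel_preset,
    settle_field,
)
from fieldground.perception import (
    Scene,
    SceneGrids,
    cue_attention,
    make_ior_field,
    mark_ior,
    read_motion_dir,
    render_scene,
    select_target,
)
from fieldground.relations import guidance_bias, make_template, relational_match
from fieldground.structure import (
    CSFields,
    ConceptualStructure,
    GroundingResult,
    actions_for_agent,
    encode_cs,
    produce_next,
    readout_action,
    readout_object,
    readout_relation,
    relations_for_target,
)

__all__ = [
    "ProcessMotif",
    "step_motif",
    "IndexMap",
    "commit",
    "read_index",
    "dependency_bias",
    "ground",
    "GroundConfig",
]

PROCESS_NAMES = (
    "select_target_candidate",
    "check_relations",
    "commit",
    "proceed_to_next_target",
)

_INTENTION = NodeParams(h=-2.0, q=0.0, w_se=6.0)
_COS = NodeParams(h=-4.0, q=0.0, w_se=3.0)
PRECONDITION_BOOST = 4.0
COS_PREACTIVATION = 2.5
COS_OUTCOME_GAIN = 3.0
COS_INHIBITION = 8.0
# CoS "on" criterion: output above 0.9 for 5 consecutive ms (debounce)
ON_LEVEL = 0.9
ON_HOLD_MS = 5.0


class ProcessMotif:
    """Intention / condition-of-satisfaction node pair for one process."""

    def __init__(self, name: str, noise_q: float = 0.0):
        if name not in PROCESS_NAMES:
            raise ValueError(f"unknown process {name!r}")
        self.name = name
        qi = NodeParams(h=_INTENTION.h, q=noise_q, w_se=_INTENTION.w_se)
        qc = NodeParams(h=_COS.h, q=noise_q, w_se=_COS.w_se)
        self.intention = Node(qi, f"{name}.intention")
        self.cos = Node(qc, f"{name}.cos")
        self.precondition = False  # gate opened by the preceding process
        self._on_run_ms = 0.0

    def step(self, outcome_input: float, dt: float = 1.0, rng=None) -> None:
        step_motif(self, PRECONDITION_BOOST if self.precondition else 0.0, outcome_input, dt, rng)

    def cos_confirmed(self, dt: float) -> bool:
        if self.cos.output() > ON_LEVEL:
            self._on_run_ms += dt
        else:
            self._on_run_ms = 0.0
        return self._on_run_ms >= ON_HOLD_MS

    def reset_debounce(self) -> None:
        self._on_run_ms = 0.0


def step_motif(
    m: ProcessMotif,
    predicted_input: float,
    outcome_input: float,
    dt: float = 1.0,
    rng=None,
) -> ProcessMotif:
    """One Euler step of the intention/CoS motif.

    The CoS node needs both the intention's pre-activation and the outcome
    input to switch on; its activity inhibits the intention, whose decay
    removes the pre-activation and thereby resets the CoS node too.
    """
    cos_out = m.cos.output()
    int_out = m.intention.output()
    m.intention.step(predicted_input - COS_INHIBITION * cos_out, dt=dt, rng=rng)
    m.cos.step(COS_PREACTIVATION * int_out + COS_OUTCOME_GAIN * outcome_input, dt=dt, rng=rng)
    return m


# --------------------------------------------------------------------------
# index map working memory


class IndexMap:
    """3-D working memory over (x, y, object index), one 2-D slice per index.

    A sustained peak at (x, y, o) represents that the object with index o
    was found at (x, y).  Committing to an occupied slice is an error: the
    map is immutable within one grounding run.
    """

    def __init__(self, grids: SceneGrids, index_depth: int = 4):
        self.grids = grids
        self.index_depth = index_depth
        self.slices: dict[int, Field] = {}

    def _slice(self, object_index: int) -> Field:
        if not (1 <= object_index <= self.index_depth):
            raise ValueError(f"object index {object_index} outside 1..{self.index_depth}")
        if object_index not in self.slices:
            dims = list(self.grids.spatial)
            self.slices[object_index] = Field(
                dims, FieldParams(q=0.0), kernel_preset("memory", dims),
                name=f"index_map_{object_index}",
            )
        return self.slices[object_index]

    def committed_indices(self) -> set[int]:
        return {i for i in self.slices if detect_peaks(self.slices[i], min_mass=0.5)}


def commit(index_map: IndexMap, location, object_index: int, settle_ms: float = 120.0) -> IndexMap:
    """Imprint a sustained peak at (location, object_index).

    Raises if the index slice already holds a peak; other slices are
    untouched.
    """
    f = index_map._slice(object_index)
    if detect_peaks(f, min_mass=0.5):
        raise ValueError(f"index {object_index} already committed")
    gx, gy = f.dims
    from fieldground.perception import effective_blob_width

    X, Y = np.meshgrid(gx.grid, gy.grid, indexing="ij")
    w = effective_blob_width(gx)
    boost = 8.0 * np.exp(
        -((X - location[0]) ** 2 + (Y - location[1]) ** 2) / (2 * w**2)
    )
    settle_field(f, boost, max_ms=settle_ms, tol=1e-4)
    settle_field(f, 0.0, max_ms=60.0, tol=1e-4)
    if not detect_peaks(f, min_mass=0.5):
        raise RuntimeError("commit failed to form a sustained peak")
    return index_map


def read_index(index_map: IndexMap, object_index: int):
    """Peak centroid of one index slice, or None if uncommitted.

    None signals an unresolved dependency to the process control.
    """
    if object_index not in index_map.slices:
        return None
    peaks = detect_peaks(index_map.slices[object_index], min_mass=0.5)
    if not peaks:
        return None
    return peaks[0].location[:2]


def dependency_bias(cs_fields: CSFields, index_map: IndexMap) -> dict[int, float]:
    """Suppression per object index: 1.5 per ungrounded prerequisite.

    Prerequisites are the reference objects of relations in which the
    index fills the target role, plus the patient of any action in which
    it is the agent — both must be in the index map before the object
    itself can be verified.
    """
    committed = index_map.committed_indices()
    bias: dict[int, float] = {}
    for idx in cs_fields.declared_object_indices():
        count = 0
        for r in relations_for_target(cs_fields, idx):
            ref = readout_relation(cs_fields, r)["reference_index"]
            if ref is not None and ref not in committed and ref != idx:
                count += 1
        for a in actions_for_agent(cs_fields, idx):
            patient = readout_action(cs_fields, a)["patient_index"]
            if patient is not None and patient not in committed and patient != idx:
                count += 1
        bias[idx] = 1.5 * count
    return bias


# --------------------------------------------------------------------------
# the grounding loop


@dataclass
class GroundConfig:
    n_spatial: int = 64
    noise: float = 0.0  # q for the dynamic fields of the loop
    seed: int = 0
    process_timeout_ms: float = 2000.0
    global_timeout_ms: float = 60000.0

    def as_dict(self) -> dict:
        return {
            "n_spatial": self.n_spatial,
            "noise": self.noise,
            "seed": self.seed,
            "process_timeout_ms": self.process_timeout_ms,
            "global_timeout_ms": self.global_timeout_ms,
        }


class _Clock:
    def __init__(self) -> None:
        self.t = 0.0

    def advance(self, ms: float) -> None:
        self.t += ms


class _Sequencer:
    """Steps the four process motifs and logs their instabilities."""

    def __init__(self, clock: _Clock, events: EventLog, noise_q: float, rng, timeout_ms: float):
        self.motifs = {n: ProcessMotif(n, noise_q) for n in PROCESS_NAMES}
        self.clock = clock
        self.events = events
        self.rng = rng
        self.timeout_ms = timeout_ms
        self._states: dict[str, tuple[bool, bool]] = {
            n: (False, False) for n in PROCESS_NAMES
        }

    def _log_transitions(self) -> None:
        for name, m in self.motifs.items():
            was_int, was_cos = self._states[name]
            if m.intention.on != was_int:
                self.events.add(
                    self.clock.t, "intention_on" if m.intention.on else "intention_off", name
                )
            if m.cos.on != was_cos:
                self.events.add(self.clock.t, "cos_on" if m.cos.on else "cos_off", name)
            self._states[name] = (m.intention.on, m.cos.on)

    def run_process(self, name: str, operation, outcome_fn) -> str:
        """Open the precondition, run the operation, drive the CoS cycle.

        ``operation`` performs the process's work once the intention is on
        (advancing the clock by its settle durations); ``outcome_fn`` maps
        the operation's result to the CoS outcome input, or None when the
        process failed to reach its outcome — the intention is then
        dismantled by transient inhibition instead of by its CoS (the
        rejection path).  Returns "done", "aborted" or "timeout".
        """
        m = self.motifs[name]
        m.precondition = True
        m.reset_debounce()
        deadline = self.clock.t + self.timeout_ms
        # intention rises under the precondition boost
        while not m.intention.on:
            if self.clock.t > deadline:
                return "timeout"
            m.step(0.0, 1.0, self.rng)
            self.clock.advance(1.0)
            self._log_transitions()
        result = operation()
        self._result = result
        outcome = outcome_fn(result)
        if outcome is None:
            # no outcome will arrive; transient inhibition takes the
            # intention through the reverse detection instability
            m.precondition = False
            while m.intention.on or m.cos.on:
                if self.clock.t > deadline:
                    return "timeout"
                step_motif(m, -6.0, 0.0, 1.0, self.rng)
                self.clock.advance(1.0)
                self._log_transitions()
            return "aborted"
        confirmed = False
        # outcome drives the CoS; its inhibition dismantles the intention,
        # which in turn resets the CoS — strict on/off ordering
        while True:
            if self.clock.t > deadline:
                return "timeout"
            m.step(outcome, 1.0, self.rng)
            self.clock.advance(1.0)
            self._log_transitions()
            if not confirmed and m.cos_confirmed(1.0):
                confirmed = True
            if confirmed and not m.intention.on:
                m.precondition = False
                outcome = 0.0  # the architecture moves on; outcome decays
            if confirmed and not m.intention.on and not m.cos.on:
                return "done"

    @property
    def result(self):
        return self._result


def ground(
    cs: ConceptualStructure,
    scene: Scene,
    config: GroundConfig | None = None,
    inventory: ConceptInventory | None = None,
    snapshots: list | None = None,
) -> GroundingResult:
    """Ground every object index of a conceptual structure in a scene.

    Runs the full architecture: render the scene, encode the structure,
    then let the four-process sequence select, verify, and commit one
    object after the other until all indices are in the index map and all
    relations and actions are verified.  Candidate rejection re-enters
    selection with inhibition of return; exhausting all candidates for an
    index marks the run failed.
    """
    config = config or GroundConfig()
    inv = inventory or default_inventory()
    cs.validate(inv)
    rng = np.random.default_rng(config.seed)
    grids = SceneGrids.make(n_spatial=config.n_spatial)
    scene = Scene(scene.objects, grids.spatial)  # re-grid to config resolution
    percepts = render_scene(scene, grids)
    cs_fields = encode_cs(cs, inv)
    index_map = IndexMap(grids, cs.index_depth)
    clock = _Clock()
    events = EventLog()
    seq = _Sequencer(clock, events, config.noise, rng, config.process_timeout_ms)
    templates = {
        name: make_template(name, grids.spatial)
        for name in ("left_of", "right_of", "above", "below", "approach")
    }
    locations: dict[int, tuple[float, float]] = {}
    verified: dict[str, bool] = {}
    object_ior: set[int] = set()

    def result(status: str, failed_index: int | None = None) -> GroundingResult:
        return GroundingResult(
            locations=locations,
            verified=verified,
            events=list(events),
            status=status,
            failed_index=failed_index,
            provenance=config.as_dict(),
        )

    all_indices = cs_fields.declared_object_indices()
    while index_map.committed_indices() != all_indices:
        if clock.t > config.global_timeout_ms:
            return result("timeout")
        # ---- object production: pick the next index to ground
        candidates = all_indices - index_map.committed_indices()
        bias = dependency_bias(cs_fields, index_map)
        idx = produce_next(candidates, object_ior, bias, cs.index_depth)
        clock.advance(120.0)
        if idx is None:
            # every remaining candidate is either inhibited or carries
            # unresolved dependencies; force the least-dependent choice
            idx = produce_next(candidates, set(), None, cs.index_depth)
            clock.advance(120.0)
            if idx is None:
                return result("failed")
        events.add(clock.t, "object_selected", "object_production", index=idx)
        concepts = readout_object(cs_fields, idx)
        cue_defs = [inv[c] for c in sorted(concepts["object_concepts"] | concepts["property_concepts"])]
        rel_idxs = relations_for_target(cs_fields, idx)
        act_idxs = actions_for_agent(cs_fields, idx)
        ior_field = make_ior_field(grids)
        committed_this_index = False
        while not committed_this_index:
            if clock.t > config.global_timeout_ms:
                return result("timeout")
            # ---- process 1: select a target candidate
            def select_op():
                # stacked guidance biases are averaged so that guidance can
                # order matching candidates but never lift a conjunction
                # failure over threshold
                biases = []
                for r in sorted(rel_idxs):
                    ro = readout_relation(cs_fields, r)
                    ref_loc = read_index(index_map, ro["reference_index"])
                    if ref_loc is None:
                        continue
                    biases.append(
                        guidance_bias(templates[ro["relation_concept"]], ref_loc, grids.spatial)
                    )
                guidance = sum(biases) / len(biases) if biases else None
                att = cue_attention(
                    cue_defs, percepts, guidance, noise=config.noise, rng=rng
                )
                clock.advance(80.0)
                if snapshots is not None:
                    snapshots.append((clock.t, "spatial_attention", att.u.copy()))
                loc = select_target(att, ior_field, rng=rng, noise=config.noise)
                clock.advance(150.0)
                return loc

            status = seq.run_process(
                "select_target_candidate", select_op,
                lambda loc: 1.0 if loc is not None else None,
            )
            if status == "timeout":
                return result("timeout")
            loc = seq.result
            if loc is None:
                # candidate exhaustion: no location left for this index
                events.add(clock.t, "index_failed", "object_production", index=idx)
                return result("failed", failed_index=idx)
            events.add(clock.t, "candidate_selected", "target", index=idx,
                       location=[round(loc[0], 2), round(loc[1], 2)])

            # ---- process 2: check relations (and actions) one at a time
            def check_op():
                all_match = True
                rel_ior: set[int] = set()
                while True:
                    r = produce_next(rel_idxs, rel_ior, None, cs.index_depth)
                    clock.advance(120.0)
                    if r is None:
                        break  # no production peak left: the CoS condition
                    events.add(clock.t, "relation_selected", "relation_production", index=r)
                    ro = readout_relation(cs_fields, r)
                    ref_loc = read_index(index_map, ro["reference_index"])
                    if ref_loc is None:
                        all_match = False
                        rel_ior.add(r)
                        continue
                    m = relational_match(loc, ref_loc, templates[ro["relation_concept"]])
                    clock.advance(60.0)
                    verified[f"relation_{r}"] = m.match
                    events.add(clock.t, "relation_checked", "relation_match",
                               index=r, match=m.match)
                    if not m.match:
                        all_match = False
                        break
                    rel_ior.add(r)  # matched: production peak destabilized
                if all_match:
                    for a in sorted(act_idxs):
                        ao = readout_action(cs_fields, a)
                        patient_loc = read_index(index_map, ao["patient_index"])
                        if patient_loc is None:
                            continue  # patient not grounded yet; checked later
                        motion = read_motion_dir(percepts, loc)
                        if motion is None:
                            verified[f"action_{a}"] = False
                            all_match = False
                            continue
                        m = relational_match(
                            loc, patient_loc, templates[ao["action_concept"]], motion_dir=motion
                        )
                        clock.advance(60.0)
                        verified[f"action_{a}"] = m.match
                        events.add(clock.t, "action_checked", "relation_match",
                                   index=a, match=m.match)
                        if not m.match:
                            all_match = False
                return all_match

            status = seq.run_process(
                "check_relations", check_op, lambda matched: 1.0 if matched else None
            )
            if status == "timeout":
                return result("timeout")
            if not seq.result:
                # a relation failed: inhibit this candidate and reselect
                mark_ior(ior_field, loc)
                clock.advance(180.0)
                events.add(clock.t, "candidate_rejected", "ior", index=idx,
                           location=[round(loc[0], 2), round(loc[1], 2)])
                continue

            # ---- process 3: commit the verified location to the index map
            def commit_op():
                commit(index_map, loc, idx)
                clock.advance(180.0)
                return read_index(index_map, idx)

            status = seq.run_process("commit", commit_op, lambda stored: 1.0 if stored else None)
            if status != "done":
                return result("timeout")
            locations[idx] = tuple(seq.result)
            events.add(clock.t, "commit", "index_map", index=idx,
                       location=[round(seq.result[0], 2), round(seq.result[1], 2)])
            if snapshots is not None:
                snapshots.append(
                    (clock.t, f"index_map_{idx}", index_map.slices[idx].u.copy())
                )
            committed_this_index = True

            # ---- process 4: proceed to the next target
            def proceed_op():
                return True  # transient inhibition destabilizes the
                # object production peak; the next cycle reselects

            status = seq.run_process("proceed_to_next_target", proceed_op, lambda _: 1.0)
            if status != "done":
                return result("timeout")

    # every index committed; the run succeeds iff every checked relation
    # and action verified
    return result("grounded" if all(verified.values()) else "failed")
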