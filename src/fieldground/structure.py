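"""Index-bound conceptual structure: the working memory of a phrase.

A phrase like "the blue ball approaches the big tree, which is to the left
of the lake and to the right of the house" is held as a set of discrete
working-memory fields.  Concepts come in a small number of copies spanned
by an *index* dimension (four by default); binding "ball" and "blue" to
object index 1 means sustained peaks at (ball, 1) and (blue, 1) in the
object-concept and property-concept fields.  Roles in relations and
actions are encoded purely through index pairs: a peak at (object 2,
relation 1) in the target-role field says that object 2 is the target of
relation 1.  The same index being activated wherever the same referent is
mentioned is what solves both the problem of 2 (two trees, two indices)
and the massive binding problem (one lake index filling a reference role
in one relation and the target role in another).

Reading the structure out again is a neural ridge mechanism: a selective
production field picks one index, and ridge input along that index column
lets readout fields form peaks only on the concepts bound to it.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from fieldground.concepts import ConceptInventory, default_inventory
from fieldground.fields import (
    Field,
    FieldParams,
    IndexDimension,
    detect_peaks,
    kernel_preset,
    select_by_boost,
    settle_field,
)

__all__ = [
    "INDEX_DEPTH",
    "ConceptualStructure",
    "CSFields",
    "build_cs",
    "parse_phrase",
    "encode_cs",
    "decode_cs",
    "produce_next",
    "readout_object",
    "readout_relation",
    "readout_action",
    "relations_for_target",
    "actions_for_agent",
    "GroundingResult",
]

INDEX_DEPTH = 4


@dataclass(frozen=True)
class RelationEntry:
    relation_concept: str
    target_index: int
    reference_index: int


@dataclass(frozen=True)
class ActionEntry:
    action_concept: str
    agent_index: int
    patient_index: int


@dataclass
class ConceptualStructure:
    """Symbolic content of a phrase: indexed objects, relations, actions."""

    objects: dict[int, dict[str, set]] = dc_field(default_factory=dict)
    relations: dict[int, RelationEntry] = dc_field(default_factory=dict)
    actions: dict[int, ActionEntry] = dc_field(default_factory=dict)
    index_depth: int = INDEX_DEPTH

    def validate(self, inventory: ConceptInventory | None = None) -> None:
        for store, what in ((self.objects, "object"), (self.relations, "relation"), (self.actions, "action")):
            for i in store:
                if not (1 <= i <= self.index_depth):
                    raise ValueError(f"{what} index {i} outside 1..{self.index_depth}")
        for i, r in self.relations.items():
            for j in (r.target_index, r.reference_index):
                if j not in self.objects:
                    raise ValueError(f"relation {i} references undeclared object {j}")
        for i, a in self.actions.items():
            for j in (a.agent_index, a.patient_index):
                if j not in self.objects:
                    raise ValueError(f"action {i} references undeclared object {j}")
        if inventory is not None:
            for o in self.objects.values():
                for c in o["object_concepts"] | o["property_concepts"]:
                    inventory[c]
            for r in self.relations.values():
                inventory[r.relation_concept]
            for a in self.actions.values():
                inventory[a.action_concept]

    def add_object(self, index: int, object_concepts=(), property_concepts=()) -> None:
        self.objects[index] = {
            "object_concepts": set(object_concepts),
            "property_concepts": set(property_concepts),
        }

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ConceptualStructure)
            and self.objects == other.objects
            and self.relations == other.relations
            and self.actions == other.actions
        )

    def to_json(self, path: str | Path | None = None) -> str:
        data = {
            "objects": {
                str(i): {
                    "object_concepts": sorted(o["object_concepts"]),
                    "property_concepts": sorted(o["property_concepts"]),
                }
                for i, o in self.objects.items()
            },
            "relations": {
                str(i): {
                    "relation_concept": r.relation_concept,
                    "target_index": r.target_index,
                    "reference_index": r.reference_index,
                }
                for i, r in self.relations.items()
            },
            "actions": {
                str(i): {
                    "action_concept": a.action_concept,
                    "agent_index": a.agent_index,
                    "patient_index": a.patient_index,
                }
                for i, a in self.actions.items()
            },
            "index_depth": self.index_depth,
        }
        text = json.dumps(data, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ConceptualStructure":
        s = str(text_or_path)
        if "\n" not in s and len(s) < 1024 and Path(s).exists():
            s = Path(s).read_text()
        data = json.loads(s)
        cs = cls(index_depth=data.get("index_depth", INDEX_DEPTH))
        for i, o in data.get("objects", {}).items():
            cs.add_object(int(i), o.get("object_concepts", ()), o.get("property_concepts", ()))
        for i, r in data.get("relations", {}).items():
            cs.relations[int(i)] = RelationEntry(
                r["relation_concept"], r["target_index"], r["reference_index"]
            )
        for i, a in data.get("actions", {}).items():
            cs.actions[int(i)] = ActionEntry(
                a["action_concept"], a["agent_index"], a["patient_index"]
            )
        cs.validate()
        return cs


@dataclass
class GroundingResult:
    """Outcome of grounding a conceptual structure in a scene."""

    locations: dict[int, tuple[float, float]]
    verified: dict[str, bool]
    events: list[dict]
    status: str  # grounded | failed | timeout
    failed_index: int | None = None
    provenance: dict | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        data = {
            "status": self.status,
            "locations": {str(i): list(v) for i, v in self.locations.items()},
            "verified": self.verified,
            "failed_index": self.failed_index,
            "events": self.events,
            "provenance": self.provenance,
        }
        text = json.dumps(data, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


# --------------------------------------------------------------------------
# phrase DSL

_RELATION_PHRASES = {
    "to the left of": "left_of",
    "to the right of": "right_of",
    "left of": "left_of",
    "right of": "right_of",
    "above": "above",
    "below": "below",
}
_VERBS = {"approaches": "approach"}


class PhraseError(ValueError):
    pass


def _tokenize(phrase: str) -> list[str]:
    text = phrase.lower().strip().rstrip(".")
    text = re.sub(r",", " , ", text)
    toks = text.split()
    # collapse multiword relation phrases into single tokens
    out = []
    i = 0
    while i < len(toks):
        for length in (4, 2):
            cand = " ".join(toks[i : i + length])
            if cand in _RELATION_PHRASES:
                out.append(cand)
                i += length
                break
        else:
            out.append(toks[i])
            i += 1
    return out


class _Parser:
    """Recursive-descent parser for the restricted phrase grammar.

    Covers: determiner + optional property + noun, relative clauses
    ("which is ..."), bare postmodifiers ("the tree to the left of ..."),
    "and"-conjoined relations, and simple subject-verb-object sentences.
    """

    def __init__(self, tokens: list[str], inventory: ConceptInventory, index_depth: int):
        self.toks = tokens
        self.pos = 0
        self.inv = inventory
        self.cs = ConceptualStructure(index_depth=index_depth)
        self.next_object = 1
        self.next_relation = 1
        self.next_action = 1
        self._mentions: dict[tuple, int] = {}

    def peek(self, k=0):
        return self.toks[self.pos + k] if self.pos + k < len(self.toks) else None

    def eat(self, expected=None):
        tok = self.peek()
        if tok is None or (expected is not None and tok != expected):
            raise PhraseError(f"expected {expected!r}, got {tok!r} at position {self.pos}")
        self.pos += 1
        return tok

    def parse(self) -> ConceptualStructure:
        agent = self.parse_np(allow_bare_rel=True)
        if self.peek() in _VERBS:
            verb = _VERBS[self.eat()]
            patient = self.parse_np(allow_bare_rel=True)
            if self.next_action > self.cs.index_depth:
                raise PhraseError("too many actions for the index depth")
            self.cs.actions[self.next_action] = ActionEntry(verb, agent, patient)
            self.next_action += 1
        if self.peek() is not None:
            raise PhraseError(f"trailing tokens from {self.peek()!r}")
        self.cs.validate(self.inv)
        return self.cs

    def parse_np(self, allow_bare_rel: bool) -> int:
        self.eat("the")
        props = []
        while self.peek() in self.inv.concepts and self.inv[self.peek()].kind == "property":
            props.append(self.eat())
        noun = self.eat()
        if noun not in self.inv.concepts or self.inv[noun].kind != "object":
            raise PhraseError(f"unknown object concept {noun!r}")
        key = (tuple(sorted(props)), noun)
        if key in self._mentions:
            idx = self._mentions[key]  # repeated mention reuses the index
        else:
            if self.next_object > self.cs.index_depth:
                raise PhraseError(
                    f"phrase needs more than {self.cs.index_depth} object indices"
                )
            idx = self.next_object
            self.next_object += 1
            self.cs.add_object(idx, {noun}, set(props))
            self._mentions[key] = idx
        self._parse_rel_mods(idx, allow_bare_rel)
        return idx

    def _parse_rel_mods(self, idx: int, allow_bare_rel: bool) -> None:
        took = 0
        while True:
            save = self.pos
            comma = False
            if self.peek() == ",":
                self.eat()
                comma = True
            marked = False
            if self.peek() == "which" and self.peek(1) == "is":
                self.eat(), self.eat()
                marked = True
            conj = False
            if not marked and self.peek() == "and":
                # "and" continues this noun's clause only once it has one
                if took == 0:
                    self.pos = save
                    return
                self.eat()
                if self.peek() == "is":
                    self.eat()
                conj = True
            if self.peek() in _RELATION_PHRASES and (
                marked or conj or (allow_bare_rel and not comma and took == 0)
            ):
                rel = _RELATION_PHRASES[self.eat()]
                ref_idx = self.parse_np(allow_bare_rel=False)
                if self.next_relation > self.cs.index_depth:
                    raise PhraseError("too many relations for the index depth")
                self.cs.relations[self.next_relation] = RelationEntry(rel, idx, ref_idx)
                self.next_relation += 1
                took += 1
            else:
                self.pos = save
                return


def parse_phrase(
    phrase: str,
    inventory: ConceptInventory | None = None,
    index_depth: int = INDEX_DEPTH,
) -> ConceptualStructure:
    """Compile a restricted-DSL phrase into a conceptual structure.

    Indices are recruited deterministically in order of first mention;
    mentioning the same description again reuses its index.
    """
    inv = inventory or default_inventory()
    return _Parser(_tokenize(phrase), inv, index_depth).parse()


def build_cs(
    phrase_or_json: str,
    inventory: ConceptInventory | None = None,
    index_depth: int = INDEX_DEPTH,
) -> ConceptualStructure:
    """Accept either a phrase in the restricted DSL or a CS JSON document."""
    text = str(phrase_or_json).strip()
    if text.startswith("{") or (len(text) < 1024 and "\n" not in text and Path(text).exists()):
        cs = ConceptualStructure.from_json(text)
        cs.validate(inventory or default_inventory())
        return cs
    return parse_phrase(text, inventory, index_depth)


# --------------------------------------------------------------------------
# neural working-memory representation

_FIELD_SPECS = {
    # name -> (row axis content, column axis content)
    "object_concept": ("object", "object_index"),
    "property_concept": ("property", "object_index"),
    "relation_concept": ("spatial_relation", "relation_index"),
    "action_concept": ("action", "action_index"),
    "target_role": ("object_index", "relation_index"),
    "reference_role": ("object_index", "relation_index"),
    "agent_role": ("object_index", "action_index"),
    "patient_role": ("object_index", "action_index"),
}

_BIND_GAIN = 8.0  # transient binding input
_SUB_GAIN = 2.5  # sub-threshold memory input into readout fields
_RIDGE_GAIN = 3.0  # production-index ridge input


class CSFields:
    """Discrete working-memory fields holding one conceptual structure.

    Every field is a 2-D grid of bistable sites (self-excitatory memory
    regime); a binding is a sustained peak at (entry, index).
    """

    def __init__(self, inventory: ConceptInventory | None = None, index_depth: int = INDEX_DEPTH):
        self.inventory = inventory or default_inventory()
        self.index_depth = index_depth
        self.fields: dict[str, Field] = {}
        for name, (rows, cols) in _FIELD_SPECS.items():
            rdim = self._axis(rows)
            cdim = self._axis(cols)
            self.fields[name] = Field(
                [rdim, cdim],
                FieldParams(q=0.0),
                kernel_preset("memory", [rdim, cdim]),
                name=name,
            )

    def _axis(self, content: str) -> IndexDimension:
        if content.endswith("_index"):
            return IndexDimension(content, self.index_depth)
        if content == "spatial_relation":
            labels = tuple(
                c.name for c in self.inventory.of_kind("spatial_relation", "movement_relation")
            )
        else:
            labels = tuple(c.name for c in self.inventory.of_kind(content))
        return IndexDimension(content, len(labels), labels)

    def bind(self, field_name: str, row, index: int, settle_ms: float = 80.0) -> None:
        f = self.fields[field_name]
        s = np.zeros(f.shape)
        # index-valued rows are 1-based, labelled concept rows positional
        i = f.dims[0].index_of(row) if f.dims[0].labels else int(row) - 1
        s[i, index - 1] = _BIND_GAIN
        settle_field(f, s, max_ms=settle_ms, tol=1e-4)
        settle_field(f, 0.0, max_ms=40.0, tol=1e-4)  # must self-sustain

    def bindings(self, field_name: str) -> set[tuple[str | int, int]]:
        f = self.fields[field_name]
        out = set()
        for i, j in zip(*np.nonzero(f.u > 0)):
            dim = f.dims[0]
            row = dim.labels[i] if dim.labels else int(i) + 1
            out.add((row, int(j) + 1))
        return out

    def declared_object_indices(self) -> set[int]:
        return {j for _, j in self.bindings("object_concept")} | {
            j for _, j in self.bindings("property_concept")
        }


def encode_cs(cs: ConceptualStructure, inventory: ConceptInventory | None = None) -> CSFields:
    """Imprint a conceptual structure as sustained working-memory peaks."""
    cs.validate(inventory)
    fields = CSFields(inventory, cs.index_depth)
    for idx, o in cs.objects.items():
        for c in o["object_concepts"]:
            fields.bind("object_concept", c, idx)
        for c in o["property_concepts"]:
            fields.bind("property_concept", c, idx)
    for idx, r in cs.relations.items():
        fields.bind("relation_concept", r.relation_concept, idx)
        fields.bind("target_role", r.target_index, idx)
        fields.bind("reference_role", r.reference_index, idx)
    for idx, a in cs.actions.items():
        fields.bind("action_concept", a.action_concept, idx)
        fields.bind("agent_role", a.agent_index, idx)
        fields.bind("patient_role", a.patient_index, idx)
    return fields


def decode_cs(fields: CSFields) -> ConceptualStructure:
    """Read the sustained peak pattern back into symbolic form."""
    cs = ConceptualStructure(index_depth=fields.index_depth)
    for c, idx in fields.bindings("object_concept"):
        cs.objects.setdefault(idx, {"object_concepts": set(), "property_concepts": set()})[
            "object_concepts"
        ].add(c)
    for c, idx in fields.bindings("property_concept"):
        cs.objects.setdefault(idx, {"object_concepts": set(), "property_concepts": set()})[
            "property_concepts"
        ].add(c)
    rel_concepts = dict_by_index(fields.bindings("relation_concept"))
    rel_targets = dict_by_index(fields.bindings("target_role"))
    rel_refs = dict_by_index(fields.bindings("reference_role"))
    for idx, concept in rel_concepts.items():
        cs.relations[idx] = RelationEntry(concept, rel_targets[idx], rel_refs[idx])
    act_concepts = dict_by_index(fields.bindings("action_concept"))
    act_agents = dict_by_index(fields.bindings("agent_role"))
    act_patients = dict_by_index(fields.bindings("patient_role"))
    for idx, concept in act_concepts.items():
        cs.actions[idx] = ActionEntry(concept, act_agents[idx], act_patients[idx])
    return cs


def dict_by_index(bindings: set[tuple]) -> dict[int, object]:
    out = {}
    for row, idx in bindings:
        if idx in out:
            raise ValueError(f"two bindings at index {idx}")
        out[idx] = row
    return out


# --------------------------------------------------------------------------
# production (serialization) machinery


def produce_next(
    candidates: set[int],
    ior: set[int],
    dependency_bias: dict[int, float] | None = None,
    index_depth: int = INDEX_DEPTH,
    settle_ms: float = 120.0,
) -> int | None:
    """Selective competition over the index axis; one winner or none.

    Candidate drives are subthreshold; a rising homogeneous boost lets the
    least-suppressed index cross the detection instability first, and its
    inhibition locks out the rest.  Candidates under inhibition of return
    never reach threshold; the dependency bias delays entries whose
    prerequisites are not yet grounded.  Exact ties resolve
    lowest-index-first through a minuscule fixed gradient.
    """
    dim = IndexDimension("index", index_depth)
    f = Field([dim], FieldParams(q=0.0), kernel_preset("select", [dim]), "production")
    s = np.full(index_depth, -4.0)
    for i in candidates:
        s[i - 1] = 2.0 - 0.05 * (i - 1)
    for i in ior:
        s[i - 1] -= 4.0
    if dependency_bias:
        for i, b in dependency_bias.items():
            if i - 1 < index_depth:
                s[i - 1] -= b
    peaks = select_by_boost(f, s, boost_cap=4.2, hold_ms=60.0, min_mass=0.0)
    if not peaks:
        return None
    winner = max(peaks, key=lambda p: f.u[int(p.location[0])])
    return int(winner.location[0]) + 1


def _ridge_readout(fields: CSFields, field_name: str, index: int, axis: int = 1) -> set:
    """Peaks where memory input overlaps the ridge at the selected index."""
    mem = fields.fields[field_name]
    rate = np.where(mem.u > 0, 1.0, 0.0)
    ridge = np.zeros(mem.shape)
    if axis == 1:
        ridge[:, index - 1] = 1.0
    else:
        ridge[index - 1, :] = 1.0
    u = -5.0 + _SUB_GAIN * rate + _RIDGE_GAIN * ridge
    out = set()
    for i, j in zip(*np.nonzero(u > 0)):
        dim0 = mem.dims[0]
        row = dim0.labels[i] if dim0.labels else int(i) + 1
        out.add((row, int(j) + 1))
    return out


def readout_object(fields: CSFields, index: int) -> dict[str, set]:
    """Concepts bound to one object index (ridge-overlap readout)."""
    return {
        "object_concepts": {c for c, _ in _ridge_readout(fields, "object_concept", index)},
        "property_concepts": {c for c, _ in _ridge_readout(fields, "property_concept", index)},
    }


def relations_for_target(fields: CSFields, object_index: int) -> set[int]:
    """Relation indices having the object in their target role."""
    return {j for _, j in _ridge_readout(fields, "target_role", object_index, axis=0)}


def actions_for_agent(fields: CSFields, object_index: int) -> set[int]:
    return {j for _, j in _ridge_readout(fields, "agent_role", object_index, axis=0)}


def readout_relation(fields: CSFields, relation_index: int) -> dict:
    """Relation concept and reference index bound to one relation index."""
    concepts = {c for c, _ in _ridge_readout(fields, "relation_concept", relation_index)}
    refs = {r for r, _ in _ridge_readout(fields, "reference_role", relation_index)}
    return {
        "relation_concept": next(iter(concepts)) if concepts else None,
        "reference_index": next(iter(refs)) if refs else None,
    }


def readout_action(fields: CSFields, action_index: int) -> dict:
    concepts = {c for c, _ in _ridge_readout(fields, "action_concept", action_index)}
    agents = {a for a, _ in _ridge_readout(fields, "agent_role", action_index)}
    patients = {p for p, _ in _ridge_readout(fields, "patient_role", action_index)}
    return {
        "action_concept": next(iter(concepts)) if concepts else None,
        "agent_index": next(iter(agents)) if agents else None,
        "patient_index": next(iter(patients)) if patients else None,
    }
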