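"""Synthetic task generator: scenes and phrases with known ground truth.

Every other module is testable without any external data: this module
builds the five-object demonstration scene (house, big tree, lake, a small
distractor tree, and a blue ball heading for the big tree), samples random
solvable grounding tasks, and provides the brute-force symbolic oracle
that enumerates all assignments of object indices to scene objects.  The
oracle shares the calibration constants of the relation templates (the
45-degree match cone) but is implemented purely with difference-vector
geometry, independent of all field code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from fieldground.concepts import ConceptInventory, default_inventory
from fieldground.perception import BLOB_WIDTH, Scene, SceneObject, default_bounds
from fieldground.relations import MATCH_CONE_DEG, ORACLE_R_MIN, SPATIAL_RELATIONS
from fieldground.structure import ActionEntry, ConceptualStructure, RelationEntry

__all__ = ["TaskSpec", "make_demo_scene", "make_random_task", "symbolic_oracle"]

MIN_OBJECT_DISTANCE = 3.0 * BLOB_WIDTH  # prevents peak merging
# generated relations keep this margin from the decision cone so the
# neural and symbolic criteria cannot disagree on borderline geometry
CONE_MARGIN_DEG = 10.0

_HUES = {"red": 0.0, "green": 120.0, "blue": 240.0}
_SIZES = {"big": 9.0, "small": 2.5}


@dataclass
class TaskSpec:
    scene: Scene
    cs: ConceptualStructure
    ground_truth: dict[int, str]  # object index -> scene object id
    solvable: bool
    seed: int


# --------------------------------------------------------------------------
# symbolic oracle


def _feature_ok(obj: SceneObject, cs_entry: dict, inventory: ConceptInventory) -> bool:
    for cname in cs_entry["object_concepts"] | cs_entry["property_concepts"]:
        for dim, (center, width) in inventory[cname].feature_templates.items():
            v = obj.feature_value(dim)
            if v is None:
                return False
            d = abs((v - center + 180.0) % 360.0 - 180.0) if dim in ("hue", "dir") else abs(v - center)
            if d > 2.0 * width:  # nearest-prototype criterion
                return False
    return True


def _relation_ok(target: SceneObject, reference: SceneObject, relation: str) -> bool:
    dx = target.pos[0] - reference.pos[0]
    dy = target.pos[1] - reference.pos[1]
    r = math.hypot(dx, dy)
    if r < ORACLE_R_MIN:
        return False
    axis = SPATIAL_RELATIONS[relation]
    ang = math.degrees(math.atan2(dy, dx))
    return abs((ang - axis + 180.0) % 360.0 - 180.0) <= MATCH_CONE_DEG


def _action_ok(agent: SceneObject, patient: SceneObject, action: str) -> bool:
    if action != "approach" or agent.motion_dir is None:
        return False
    bearing = math.degrees(
        math.atan2(patient.pos[1] - agent.pos[1], patient.pos[0] - agent.pos[0])
    )
    off = abs((agent.motion_dir - bearing + 180.0) % 360.0 - 180.0)
    r = math.hypot(patient.pos[0] - agent.pos[0], patient.pos[1] - agent.pos[1])
    return off <= MATCH_CONE_DEG and r >= ORACLE_R_MIN


def symbolic_oracle(
    scene: Scene,
    cs: ConceptualStructure,
    inventory: ConceptInventory | None = None,
) -> list[dict[int, str]]:
    """All injective index-to-object assignments satisfying the structure.

    Brute-force enumeration over object tuples; features are checked by
    nearest prototype, spatial relations and actions by difference-vector
    geometry with the same angular criterion the relation templates are
    calibrated to.
    """
    inv = inventory or default_inventory()
    indices = sorted(cs.objects)
    feasible = {
        i: [o.id for o in scene.objects if _feature_ok(o, cs.objects[i], inv)]
        for i in indices
    }
    results: list[dict[int, str]] = []

    def extend(k: int, partial: dict[int, str]) -> None:
        if k == len(indices):
            results.append(dict(partial))
            return
        idx = indices[k]
        for oid in feasible[idx]:
            if oid in partial.values():
                continue
            partial[idx] = oid
            if _consistent(partial):
                extend(k + 1, partial)
            del partial[idx]

    def _consistent(partial: dict[int, str]) -> bool:
        for r in cs.relations.values():
            if r.target_index in partial and r.reference_index in partial:
                if not _relation_ok(
                    scene[partial[r.target_index]],
                    scene[partial[r.reference_index]],
                    r.relation_concept,
                ):
                    return False
        for a in cs.actions.values():
            if a.agent_index in partial and a.patient_index in partial:
                if not _action_ok(
                    scene[partial[a.agent_index]],
                    scene[partial[a.patient_index]],
                    a.action_concept,
                ):
                    return False
        return True

    extend(0, {})
    return results


# --------------------------------------------------------------------------
# fixture scenes


def make_demo_scene(n: int = 64) -> Scene:
    """The five-object demonstration scene.

    House, big tree and lake sit left to right; a small distractor tree on
    the far right fails the "left of the lake" relation; a blue ball moves
    straight at the big tree.
    """
    bounds = default_bounds(n)
    big_tree = (50.0, 60.0)
    ball = (25.0, 25.0)
    bearing = math.degrees(math.atan2(big_tree[1] - ball[1], big_tree[0] - ball[0])) % 360.0
    objects = [
        SceneObject("house", (20.0, 62.0), 30.0, 7.0, "house"),
        SceneObject("big_tree", big_tree, 120.0, 9.0, "tree"),
        SceneObject("lake", (80.0, 58.0), 200.0, 8.0, "lake"),
        SceneObject("small_tree", (90.0, 30.0), 120.0, 2.5, "tree"),
        SceneObject("ball", ball, 240.0, 2.5, "ball", motion_dir=bearing),
    ]
    return Scene(objects, bounds)


# --------------------------------------------------------------------------
# random tasks


def _sample_positions(rng: np.random.Generator, k: int, lo=10.0, hi=90.0, tries=200):
    locs: list[np.ndarray] = []
    for _ in range(tries):
        p = rng.uniform(lo, hi, 2)
        if all(np.hypot(*(p - q)) >= MIN_OBJECT_DISTANCE for q in locs):
            locs.append(p)
            if len(locs) == k:
                return locs
    raise RuntimeError("could not place objects")


def _action_margin_ok(agent: SceneObject, patient: SceneObject) -> bool:
    """Heading clearly inside the approach cone (quantization-proof)."""
    if agent.motion_dir is None:
        return False
    bearing = math.degrees(
        math.atan2(patient.pos[1] - agent.pos[1], patient.pos[0] - agent.pos[0])
    )
    off = abs((agent.motion_dir - bearing + 180.0) % 360.0 - 180.0)
    r = math.hypot(patient.pos[0] - agent.pos[0], patient.pos[1] - agent.pos[1])
    return off <= MATCH_CONE_DEG - CONE_MARGIN_DEG and r >= ORACLE_R_MIN + 4.0


def _relation_margin_ok(target: SceneObject, reference: SceneObject, relation: str) -> bool:
    """Clearly inside or clearly outside the cone — never borderline."""
    dx = target.pos[0] - reference.pos[0]
    dy = target.pos[1] - reference.pos[1]
    r = math.hypot(dx, dy)
    if r < ORACLE_R_MIN + 4.0:
        return False
    axis = SPATIAL_RELATIONS[relation]
    off = abs((math.degrees(math.atan2(dy, dx)) - axis + 180.0) % 360.0 - 180.0)
    return abs(off - MATCH_CONE_DEG) > CONE_MARGIN_DEG


def _size_class(o: SceneObject) -> str:
    return "big" if o.size > 6.0 else "small"


def _unique_description(o: SceneObject, objs, inventory) -> tuple[set, set] | None:
    """A feature description matching exactly this object, if one exists.

    Reference objects must be identifiable from their description alone:
    the grounding process commits them before the target and cannot
    backtrack a commit.
    """
    for props in (set(), {_size_class(o)}):
        entry = {"object_concepts": {o.shape}, "property_concepts": props}
        hits = [x for x in objs if _feature_ok(x, entry, inventory)]
        if hits == [o]:
            return {o.shape}, props
    return None


def make_random_task(
    seed: int,
    n_objects: int = 5,
    n_relations: int = 2,
    n_actions: int = 1,
    inventory: ConceptInventory | None = None,
    max_tries: int = 400,
) -> TaskSpec:
    """Rejection-sample a scene/phrase pair with a unique satisfying assignment.

    Deterministic per seed.  The phrase describes one target object through
    its concepts plus up to ``n_relations`` relations to reference objects
    and up to ``n_actions`` movement actions.  Reference and patient
    descriptions are required to be individually unambiguous (they are
    grounded first and commits are immutable); the target may share its
    description with distractors, in which case the relations single it
    out.  Sampling retries until the symbolic oracle finds exactly one
    assignment and every relation sits well clear of the angular decision
    cone.
    """
    if not (1 <= n_objects <= 6 and 0 <= n_relations <= 2 and 0 <= n_actions <= 1):
        raise ValueError("task bounds: n_objects<=6, n_relations<=2, n_actions<=1")
    inv = inventory or default_inventory()
    rng = np.random.default_rng(seed)
    shapes = ["ball", "tree", "lake", "house", "cube", "star"]
    for attempt in range(max_tries):
        locs = _sample_positions(rng, n_objects)
        objs = []
        for i, p in enumerate(locs):
            motion = float(rng.uniform(0, 360)) if rng.random() < 0.5 else None
            objs.append(
                SceneObject(
                    f"o{i}",
                    (float(p[0]), float(p[1])),
                    float(rng.choice(list(_HUES.values()))),
                    float(rng.choice(list(_SIZES.values()))),
                    str(rng.choice(shapes)),
                    motion_dir=motion,
                )
            )
        scene = Scene(objs, default_bounds())
        cs = ConceptualStructure()
        target_obj = objs[int(rng.integers(n_objects))]
        props = set()
        if rng.random() < 0.5:
            props.add(_size_class(target_obj))
        cs.add_object(1, {target_obj.shape}, props)
        next_idx = 2
        used = {target_obj.id}
        n_rel_wanted = int(rng.integers(0, n_relations + 1))
        for _ in range(n_rel_wanted):
            if next_idx > cs.index_depth:
                break
            free = [o for o in objs if o.id not in used]
            rng.shuffle(free)
            placed = False
            for ref_obj in free:
                desc = _unique_description(ref_obj, objs, inv)
                if desc is None:
                    continue
                rels = list(SPATIAL_RELATIONS)
                rng.shuffle(rels)
                for rel in rels:
                    if _relation_ok(target_obj, ref_obj, rel) and _relation_margin_ok(
                        target_obj, ref_obj, rel
                    ):
                        cs.add_object(next_idx, desc[0], desc[1])
                        cs.relations[len(cs.relations) + 1] = RelationEntry(rel, 1, next_idx)
                        used.add(ref_obj.id)
                        next_idx += 1
                        placed = True
                        break
                if placed:
                    break
        if n_actions and target_obj.motion_dir is not None and next_idx <= cs.index_depth:
            free = [o for o in objs if o.id not in used]
            patients = [
                o
                for o in free
                if _action_ok(target_obj, o, "approach")
                and _action_margin_ok(target_obj, o)
                and _unique_description(o, objs, inv) is not None
            ]
            if patients:
                patient = patients[0]
                desc = _unique_description(patient, objs, inv)
                cs.add_object(next_idx, desc[0], desc[1])
                cs.actions[1] = ActionEntry("approach", 1, next_idx)
                used.add(patient.id)
                next_idx += 1
        cs.validate(inv)
        assignments = symbolic_oracle(scene, cs, inv)
        if len(assignments) != 1:
            continue
        return TaskSpec(scene, cs, assignments[0], True, seed)
    raise RuntimeError(f"task generation failed after {max_tries} tries (seed {seed})")
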