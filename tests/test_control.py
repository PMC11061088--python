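"""Tests for process motifs, the index map, and the grounding loop."""

import numpy as np
import pytest

from fieldground.control import (
    GroundConfig,
    IndexMap,
    ProcessMotif,
    commit,
    dependency_bias,
    ground,
    read_index,
)
from fieldground.perception import Scene, SceneGrids, SceneObject
from fieldground.structure import encode_cs, parse_phrase
from fieldground.synth import make_demo_scene, make_random_task

FULL_SENTENCE = (
    "the blue ball approaches the big tree, which is to the left of the lake "
    "and to the right of the house"
)

CFG = GroundConfig(n_spatial=32)


@pytest.fixture(scope="module")
def grids():
    return SceneGrids.make(n_spatial=32)


class TestProcessMotif:
    def run_motif(self, outcome_fn, ms=400):
        m = ProcessMotif("commit")
        m.precondition = True
        log = []
        state = (False, False)
        for t in range(ms):
            m.step(outcome_fn(t, m), 1.0)
            if m.cos.on:
                # the completed process no longer satisfies its own
                # precondition; the sequence moves on
                m.precondition = False
            now = (m.intention.on, m.cos.on)
            if now != state:
                for which, was, isnow in (("intention", state[0], now[0]), ("cos", state[1], now[1])):
                    if was != isnow:
                        log.append((t, f"{which}_{'on' if isnow else 'off'}"))
                state = now
        return m, log

    def test_no_outcome_cos_stays_off(self):
        m, log = self.run_motif(lambda t, m: 0.0, ms=600)
        assert m.intention.on
        assert not m.cos.on
        assert all(e != "cos_on" for _, e in log)

    def test_outcome_triggers_full_reset_cycle_in_order(self):
        # outcome present once the intention is active; the outcome input
        # decays as soon as the intention has been dismantled
        def outcome(t, m):
            return 1.0 if m.intention.on else 0.0

        m, log = self.run_motif(outcome, ms=400)
        names = [e for _, e in log]
        assert names == ["intention_on", "cos_on", "intention_off", "cos_off"]
        ts = dict((e, t) for t, e in log)
        assert ts["cos_on"] < ts["intention_off"] < ts["cos_off"]
        assert ts["cos_off"] - ts["cos_on"] < 100  # within 100 ms simulated

    def test_outcome_without_intention_ignored(self):
        m = ProcessMotif("commit")  # precondition closed: intention off
        for _ in range(400):
            m.step(1.0, 1.0)
        assert not m.cos.on  # pre-activation is required


class TestIndexMap:
    def test_commit_read_inverse(self, grids):
        im = IndexMap(grids)
        commit(im, (30, 60), 3)
        loc = read_index(im, 3)
        step = grids.spatial[0].spacing
        assert abs(loc[0] - 30) <= step and abs(loc[1] - 60) <= step

    def test_two_commits_persist_1000ms(self, grids):
        im = IndexMap(grids)
        commit(im, (30, 60), 3)
        commit(im, (70, 20), 4)
        for f in im.slices.values():
            for _ in range(1000):
                f.step(0.0, 1.0)
        assert read_index(im, 3) == pytest.approx((30, 60), abs=2 * grids.spatial[0].spacing)
        assert read_index(im, 4) == pytest.approx((70, 20), abs=2 * grids.spatial[0].spacing)

    def test_recommit_rejected_map_unchanged(self, grids):
        im = IndexMap(grids)
        commit(im, (30, 60), 3)
        before = im.slices[3].u.copy()
        with pytest.raises(ValueError):
            commit(im, (80, 80), 3)
        assert np.array_equal(im.slices[3].u, before)

    def test_uncommitted_index_reads_none(self, grids):
        im = IndexMap(grids)
        assert read_index(im, 2) is None

    def test_no_cross_talk_between_slices(self, grids):
        im = IndexMap(grids)
        commit(im, (20, 20), 3)
        commit(im, (80, 80), 4)
        assert read_index(im, 4) == pytest.approx((80, 80), abs=3)
        assert read_index(im, 3) == pytest.approx((20, 20), abs=3)


class TestDependencyBias:
    def test_full_sentence_initial_bias(self, grids):
        cs = parse_phrase(FULL_SENTENCE)
        fields = encode_cs(cs)
        im = IndexMap(grids)
        bias = dependency_bias(fields, im)
        # object 2 is suppressed by two unresolved references, the agent
        # (object 1) by its ungrounded patient; 3 and 4 are free
        assert bias[2] > bias[3] == bias[4] == 0.0
        assert 0.0 < bias[1] < bias[2]

    def test_bias_clears_after_commits(self, grids):
        cs = parse_phrase(FULL_SENTENCE)
        fields = encode_cs(cs)
        im = IndexMap(grids)
        commit(im, (80, 58), 3)
        commit(im, (20, 62), 4)
        assert dependency_bias(fields, im)[2] == 0.0

    def test_no_relations_all_zero(self, grids):
        fields = encode_cs(parse_phrase("the lake"))
        assert all(v == 0.0 for v in dependency_bias(fields, IndexMap(grids)).values())


class TestGround:
    def test_single_object_phrase(self):
        scene = Scene(
            [
                SceneObject("lake1", (60, 40), 200.0, 8.0, "lake"),
                SceneObject("ball1", (20, 70), 240.0, 2.5, "ball"),
            ],
            SceneGrids.make(32).spatial,
        )
        res = ground(parse_phrase("the lake"), scene, CFG)
        assert res.status == "grounded"
        commits = [e for e in res.events if e["event"] == "commit"]
        assert len(commits) == 1
        assert res.locations[1] == pytest.approx((60, 40), abs=4)

    def test_three_process_grounding_rejects_distractor(self):
        scene = make_demo_scene()
        cs = parse_phrase(
            "the big tree which is to the left of the lake and to the right of the house"
        )
        res = ground(cs, scene, CFG)
        assert res.status == "grounded"
        commits = [e for e in res.events if e["event"] == "commit"]
        assert len(commits) == 3
        # the committed tree is the relationally correct one, not the
        # small distractor on the far right
        assert res.locations[1] == pytest.approx(scene["big_tree"].pos, abs=4)

    def test_unsatisfiable_phrase_flags_failure(self):
        scene = Scene(
            [SceneObject("b", (50, 50), 240.0, 2.5, "ball")],
            SceneGrids.make(32).spatial,
        )
        res = ground(parse_phrase("the red ball"), scene, CFG)
        assert res.status == "failed"
        assert res.failed_index == 1

    def test_strict_process_seriality(self):
        res = ground(parse_phrase(FULL_SENTENCE), make_demo_scene(), CFG)
        assert res.status == "grounded"
        open_intentions = set()
        for e in res.events:
            if e["event"] == "intention_on":
                open_intentions.add(e["component"])
                assert len(open_intentions) == 1  # exactly one process active
            elif e["event"] == "intention_off":
                open_intentions.discard(e["component"])

    def test_reset_soundness(self):
        # after each CoS, intention and CoS are both off before the next
        # precondition opens
        res = ground(parse_phrase(FULL_SENTENCE), make_demo_scene(), CFG)
        pending_cos = None
        for e in res.events:
            if e["event"] == "cos_on":
                pending_cos = e["component"]
            elif e["event"] == "intention_on":
                assert pending_cos is None, "new process opened before full reset"
            elif e["event"] == "cos_off" and e["component"] == pending_cos:
                pending_cos = None

    @pytest.mark.parametrize("seed", range(6))
    def test_neural_matches_symbolic_assignment(self, seed):
        task = make_random_task(seed, n_objects=5, n_relations=2, n_actions=1)
        res = ground(task.cs, task.scene, CFG)
        assert res.status == "grounded"
        for idx, oid in task.ground_truth.items():
            assert res.locations[idx] == pytest.approx(task.scene[oid].pos, abs=4)

    def test_seed_reproducibility_with_noise(self):
        task = make_random_task(1, n_objects=4, n_relations=1, n_actions=0)
        cfg = GroundConfig(n_spatial=32, noise=0.1, seed=7)
        r1 = ground(task.cs, task.scene, cfg)
        r2 = ground(task.cs, task.scene, cfg)
        assert r1.to_json() == r2.to_json()

    def test_progress_candidate_rejection_adds_ior_mark(self):
        # every rejected candidate shows up as an IoR event, bounding the
        # number of select/check cycles
        scene = make_demo_scene()
        cs = parse_phrase(
            "the tree which is to the left of the lake and to the right of the house"
        )
        res = ground(cs, scene, CFG)
        assert res.status == "grounded"
        rejected = [e for e in res.events if e["event"] == "candidate_rejected"]
        selected = [e for e in res.events if e["event"] == "candidate_selected"]
        # each extra selection beyond one per index is matched by a rejection
        assert len(selected) - len(res.locations) == len(rejected)
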