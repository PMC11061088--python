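"""Tests for scene rendering, conjunction search and target selection."""

import numpy as np
import pytest

from fieldground.concepts import SHAPE_CLASSES, default_inventory
from fieldground.fields import detect_peaks
from fieldground.perception import (
    Scene,
    SceneGrids,
    SceneObject,
    cue_attention,
    make_ior_field,
    mark_ior,
    read_motion_dir,
    render_scene,
    reset_ior,
    select_target,
)
from fieldground.relations import guidance_bias, make_template


@pytest.fixture(scope="module")
def grids():
    return SceneGrids.make(n_spatial=48)


@pytest.fixture(scope="module")
def inventory():
    return default_inventory()


def scene_of(grids, *objs):
    return Scene(list(objs), grids.spatial)


class TestScene:
    def test_duplicate_ids_rejected(self, grids):
        o = SceneObject("a", (10, 10), 0.0, 5.0, "ball")
        with pytest.raises(ValueError):
            scene_of(grids, o, SceneObject("a", (50, 50), 0.0, 5.0, "tree"))

    def test_out_of_bounds_rejected(self, grids):
        with pytest.raises(ValueError):
            scene_of(grids, SceneObject("a", (150, 10), 0.0, 5.0, "ball"))

    def test_bad_feature_values_rejected(self):
        with pytest.raises(ValueError):
            SceneObject("a", (10, 10), 400.0, 5.0, "ball")
        with pytest.raises(ValueError):
            SceneObject("a", (10, 10), 0.0, 5.0, "blob")

    def test_json_round_trip(self, grids):
        sc = scene_of(
            grids,
            SceneObject("a", (30, 60), 10.0, 9.0, "tree", motion_dir=90.0),
            SceneObject("b", (70, 20), 240.0, 2.5, "ball"),
        )
        back = Scene.from_json(sc.to_json(), n=48)
        assert [o.id for o in back.objects] == ["a", "b"]
        assert back["a"].motion_dir == 90.0
        assert back["b"].motion_dir is None


class TestRenderScene:
    def test_empty_scene_subthreshold(self, grids):
        per = render_scene(scene_of(grids), grids)
        for f in per.fields.values():
            assert f.u.max() < 0

    def test_single_object_peak_location(self, grids):
        sc = scene_of(grids, SceneObject("a", (30, 60), 10.0, 5.0, "ball"))
        per = render_scene(sc, grids)
        peaks = detect_peaks(per.fields["hue"])
        assert len(peaks) == 1
        x, y, hue = peaks[0].location
        assert abs(x - 30) <= grids.spatial[0].spacing
        assert abs(y - 60) <= grids.spatial[1].spacing
        hdim = grids.features["hue"]
        assert abs(hdim.distance(hue, 10.0)) <= hdim.spacing

    def test_two_objects_two_peaks_per_feature(self, grids):
        sc = scene_of(
            grids,
            SceneObject("a", (20, 20), 0.0, 9.0, "tree"),
            SceneObject("b", (80, 80), 240.0, 2.5, "ball"),
        )
        per = render_scene(sc, grids)
        for name in ("hue", "size", "shape"):
            assert len(detect_peaks(per.fields[name])) == 2

    def test_motion_direction_readout(self, grids):
        sc = scene_of(grids, SceneObject("a", (40, 40), 0.0, 5.0, "ball", motion_dir=45.0))
        per = render_scene(sc, grids)
        assert read_motion_dir(per, (40, 40)) == pytest.approx(45.0, abs=3.0)
        assert read_motion_dir(per, (80, 80)) is None


class TestCueAttention:
    def test_no_cues_all_objects_supra(self, grids, inventory):
        sc = scene_of(
            grids,
            SceneObject("a", (20, 20), 0.0, 9.0, "tree"),
            SceneObject("b", (80, 80), 240.0, 2.5, "ball"),
            SceneObject("c", (20, 80), 120.0, 5.0, "cube"),
        )
        att = cue_attention([], render_scene(sc, grids))
        assert len(detect_peaks(att)) == 3

    def test_color_cue_selects_matching_object(self, grids, inventory):
        sc = scene_of(
            grids,
            SceneObject("red1", (25, 50), 0.0, 5.0, "ball"),
            SceneObject("blue1", (75, 50), 240.0, 5.0, "ball"),
        )
        att = cue_attention([inventory["red"]], render_scene(sc, grids))
        peaks = detect_peaks(att)
        assert len(peaks) == 1
        assert peaks[0].location[0] == pytest.approx(25, abs=3)

    def test_conjunction_failure_leaves_nothing_supra(self, grids, inventory):
        # red cube + blue ball, cue {red, ball}: no object matches both
        sc = scene_of(
            grids,
            SceneObject("rc", (25, 50), 0.0, 5.0, "cube"),
            SceneObject("bb", (75, 50), 240.0, 5.0, "ball"),
        )
        att = cue_attention(
            [inventory["red"], inventory["ball"]], render_scene(sc, grids)
        )
        assert detect_peaks(att) == []

    def test_object_concept_cues_shape_dimension(self, grids, inventory):
        sc = scene_of(
            grids,
            SceneObject("t1", (30, 30), 120.0, 9.0, "tree"),
            SceneObject("b1", (70, 70), 120.0, 9.0, "ball"),
        )
        att = cue_attention([inventory["tree"]], render_scene(sc, grids))
        peaks = detect_peaks(att)
        assert len(peaks) == 1
        assert peaks[0].location[:2] == pytest.approx((30, 30), abs=3)

    def test_relation_concept_cannot_cue(self, grids, inventory):
        sc = scene_of(grids, SceneObject("a", (20, 20), 0.0, 9.0, "tree"))
        with pytest.raises(ValueError):
            cue_attention([inventory["left_of"]], render_scene(sc, grids))

    def test_soundness_and_completeness_vs_symbolic_oracle(self, grids, inventory):
        # supra-threshold locations == symbolic feature matches, random scenes
        rng = np.random.default_rng(17)
        hues = {"red": 0.0, "green": 120.0, "blue": 240.0}
        sizes = {"big": 9.0, "small": 2.5}

        def matches(o, cue_names):
            for cname in cue_names:
                for dim, (center, width) in inventory[cname].feature_templates.items():
                    v = o.feature_value(dim)
                    d = abs((v - center + 180) % 360 - 180) if dim == "hue" else abs(v - center)
                    if d > 2 * width:
                        return False
            return True

        for _ in range(15):
            k = int(rng.integers(2, 7))
            locs, objs = [], []
            while len(objs) < k:
                p = rng.uniform(8, 92, 2)
                if any(np.hypot(*(p - q)) < 10 for q in locs):
                    continue
                locs.append(p)
                objs.append(
                    SceneObject(
                        f"o{len(objs)}",
                        tuple(p),
                        float(rng.choice(list(hues.values()))),
                        float(rng.choice(list(sizes.values()))),
                        str(rng.choice(SHAPE_CLASSES[:4])),
                    )
                )
            sc = scene_of(grids, *objs)
            names = list(hues) + list(sizes) + list(SHAPE_CLASSES[:4])
            cues = list(rng.choice(names, int(rng.integers(0, 3)), replace=False))
            att = cue_attention([inventory[c] for c in cues], render_scene(sc, grids))
            peaks = detect_peaks(att)
            want = [o for o in objs if matches(o, cues)]
            assert len(peaks) == len(want)
            for o in want:
                assert any(
                    np.hypot(p.location[0] - o.pos[0], p.location[1] - o.pos[1]) < 4
                    for p in peaks
                )


@pytest.fixture(scope="module")
def two_tree_setup(grids):
    sc = Scene(
        [
            SceneObject("l", (30, 50), 0.0, 9.0, "tree"),
            SceneObject("r", (70, 50), 0.0, 9.0, "tree"),
        ],
        grids.spatial,
    )
    return render_scene(sc, grids)


class TestSelectTarget:

    def test_single_candidate_selected(self, grids, inventory):
        sc = scene_of(grids, SceneObject("a", (40, 60), 240.0, 5.0, "ball"))
        att = cue_attention([inventory["ball"]], render_scene(sc, grids))
        loc = select_target(att, make_ior_field(grids))
        assert loc == pytest.approx((40, 60), abs=3)

    def test_guidance_bias_decides_ties_every_time(self, grids, inventory, two_tree_setup):
        t = make_template("left_of", grids.spatial)
        bias = guidance_bias(t, (50, 50), grids.spatial)
        att = cue_attention([inventory["tree"]], two_tree_setup, guidance_bias=bias)
        for _ in range(10):
            loc = select_target(att, make_ior_field(grids))
            assert loc[0] == pytest.approx(30, abs=3)

    def test_ior_redirects_selection(self, grids, inventory, two_tree_setup):
        att = cue_attention([inventory["tree"]], two_tree_setup)
        ior = make_ior_field(grids)
        first = select_target(att, ior)
        mark_ior(ior, first)
        second = select_target(att, ior)
        assert abs(first[0] - second[0]) > 20  # the other tree

    def test_all_candidates_marked_yields_none(self, grids, inventory, two_tree_setup):
        att = cue_attention([inventory["tree"]], two_tree_setup)
        ior = make_ior_field(grids)
        mark_ior(ior, (30, 50))
        mark_ior(ior, (70, 50))
        assert select_target(att, ior) is None

    def test_reset_restores_original_selection(self, grids, inventory, two_tree_setup):
        att = cue_attention([inventory["tree"]], two_tree_setup)
        ior = make_ior_field(grids)
        first = select_target(att, ior)
        mark_ior(ior, first)
        reset_ior(ior)
        assert select_target(att, ior) == pytest.approx(first, abs=1e-6)

    def test_selection_uniqueness_during_settling(self, grids, inventory):
        # the target field never holds two simultaneous supra-threshold peaks
        from fieldground.fields import Field, FieldParams, kernel_preset
        from fieldground.perception import ATT_GAIN, _rate

        sc = scene_of(
            grids,
            SceneObject("a", (25, 30), 0.0, 9.0, "tree"),
            SceneObject("b", (75, 70), 0.0, 9.0, "tree"),
        )
        att = cue_attention([inventory["tree"]], render_scene(sc, grids))
        dims = list(grids.spatial)
        target = Field(dims, FieldParams(q=0.0), kernel_preset("select", dims), "target")
        s = ATT_GAIN * _rate(att.u)
        for _ in range(200):
            target.step(s, 1.0)
            # macroscopic (self-stabilized) peaks only: transient threshold
            # micro-crossings during the selection instability are not peaks
            assert len(detect_peaks(target, min_mass=0.5)) <= 1
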