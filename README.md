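# fieldground

Neural dynamic grounding of nested relational phrases in synthetic visual
scenes.

`fieldground` implements, end to end, a Dynamic Field Theory (DFT)
architecture that *perceptually grounds* phrases such as

> "the blue ball approaches the big tree, which is to the left of the lake
> and to the right of the house"

in a synthetic scene: it finds, one by one, which scene object each noun
phrase refers to, verifies every spatial and movement relation the phrase
asserts, and stores the answers in a neural working memory. Everything —
perception, attention, relation matching, working memory, and the
sequential control that orders the processing steps — is carried by the
same substrate: dynamic neural fields and bistable nodes.

It is intended for researchers and students in computational cognitive
science who want a compact, fully inspectable model of how localist neural
representations can support compositional, serially organized cognition.

## The model

The activation of every field evolves under the Amari field dynamics

```
τ u̇(x,t) = −u(x,t) + h + s(x,t) + ∫ w(x−x′) σ(u(x′,t)) dx′ + q ξ(x,t)
```

with resting level `h < 0`, sigmoidal output `σ(u) = 1/(1+exp(−βu))`
(zero is the transmission threshold), and a lateral kernel
`w(Δ) = w_exc exp(−Δ²/2σ_k²) − w_inhib` that excites locally and inhibits
globally. Discrete nodes obey the same dynamics with self-excitation in
place of the kernel. Three kernel regimes do all the work:

* **detect** — localized input pushes the field through a detection
  instability; the resulting peak survives weaker input (hysteresis) and
  several peaks may coexist;
* **select** — strong global inhibition: a slowly rising homogeneous boost
  lets exactly one candidate cross threshold and suppress all others
  (winner-take-all);
* **memory** — strong local excitation: peaks persist after their inducing
  input is removed (working memory).

On top of this substrate the architecture composes: feature/space
perception fields that bind object features through shared visual space;
cued conjunction search with match-count inhibition; gain-field coordinate
transforms that represent targets relative to a reference object (and
rotate into an agent's motion direction for movement relations); an
index-bound conceptual structure — every concept comes in four copies
along a discrete index axis, which solves both the *problem of 2* (two
trees, two indices) and the *massive binding problem* (one lake index can
fill different roles in different relations); and condition-of-satisfaction
node motifs that autonomously sequence the four grounding processes
(select candidate → check relations → commit to the index map → proceed).

## Worked example

```python
from fieldground import ground, GroundConfig, parse_phrase, make_demo_scene

scene = make_demo_scene()           # house, big tree, lake, distractor tree, ball
cs = parse_phrase(
    "the blue ball approaches the big tree, "
    "which is to the left of the lake and to the right of the house"
)
res = ground(cs, scene, GroundConfig(n_spatial=64))
print("status:", res.status)
for idx in sorted(res.locations):
    x, y = res.locations[idx]
    print(f"object {idx} grounded at ({x:.1f}, {y:.1f})")
print("verified:", res.verified)
print("commit order:", [e["index"] for e in res.events if e["event"] == "commit"])
```

prints

```
status: grounded
object 1 grounded at (24.6, 24.6)
object 2 grounded at (50.0, 60.3)
object 3 grounded at (80.2, 57.9)
object 4 grounded at (19.8, 61.9)
verified: {'relation_1': True, 'relation_2': True, 'action_1': True}
commit order: [3, 4, 2, 1]
```

Object 1 is the blue ball, 2 the big tree, 3 the lake, 4 the house. The
commit order shows the dependency-driven sequence: both reference objects
(lake, house) are grounded and memorized first, then the doubly
constrained tree — the relation checks reject nothing here because
guidance biases attention to the correct tree, not the distractor — and
finally the ball, whose "approach" is verified against the committed
tree location using the rotated relational match. `res.events` holds the
full timestamped log of every intention/condition-of-satisfaction
transition, candidate selection, relation check, and commit.

The same run is available from the shell:

```bash
fieldground synth-task --seed 0 --demo-scene --out scene.json
fieldground ground --scene scene.json \
    --phrase "the big tree which is to the left of the lake and to the right of the house" \
    --out result.json --snapshots run.npz
fieldground plot --snapshots run.npz --out panels.png
fieldground sweep --out sweep.json          # hysteresis of the detect regime
```

See `docs/methods.md` for the model's assumptions, parameter choices and
limitations.

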