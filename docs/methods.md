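# Methods

This note documents the model that `fieldground` simulates, the parameter
choices that matter, what the synthetic data emulate, and the numerical
decisions taken where the design was genuinely open.

## Dynamics

All representational state lives in dynamic neural fields

τ u̇(x,t) = −u + h + s + ∫ w(x−x′) σ(u(x′)) dx′ + q ξ

and in discrete nodes with self-excitation `w_se σ(u)` and competitive
inhibition in place of the kernel integral. Defaults: τ = 10 ms (membrane
time scale), h = −5 (resting level), β = 4 (sigmoid steepness; zero is the
transmission threshold), q = 0.1 when noise is enabled (off in most
tests). Integration is explicit Euler at dt = 1 ms (dt/τ = 0.1); the
noise increment is q·√dt per step from a seeded generator, with one master
seed fanned out to independent substreams. With q = 0 every result is
bit-reproducible and independent of the seed.

The interaction term is evaluated as a Gaussian smoothing of the
thresholded output along each continuous dimension (wrap-around on
circular dimensions such as hue and motion direction, zero padding on
scene space), scaled by the physical kernel integral so behavior is
resolution-invariant, plus a scalar global inhibition `−w_inhib ∫σ(u)`.
This is algebraically the correlation with the literal kernel
`w_exc exp(−Δ²/2σ_k²) − w_inhib`; the equivalence is asserted in the test
suite. Along discrete axes (concept and index axes) the local excitation
degenerates to per-sample self-excitation — the zero-width limit of the
same kernel.

### Kernel regimes

Three presets parameterize the kernel in resolution-free units: `boost`
is the excitatory drive at the center of a broad active region (w_exc
times the kernel integral) and `inhib` is the global inhibition exerted
by one standard peak. Values were calibrated numerically on the reference
2-D grid (scene 0–100, σ_k = 2.5):

| regime | boost | inhib | behavior |
| --- | --- | --- | --- |
| detect | 8.0 | 0.125 | detection/reverse-detection hysteresis (~1.5 amplitude units); ≥ 6 peaks coexist |
| select | 8.0 | 3.75 | winner-take-all under the boost protocol (below) |
| memory | 20.0 | 0.25 | peaks persist indefinitely after input removal; ≥ 6 simultaneous memories |

### Selection by rising boost

A winner-take-all field driven directly by strong multi-modal input has
stable two-peak equilibria when the inputs are nearly tied — near-exact
symmetry is not broken by deterministic dynamics. Selection decisions are
therefore induced the way the coupling taxonomy suggests: all candidate
drives are kept below the detection threshold and a homogeneous boost
(a resting-level shift, ramped at 0.05/ms up to a cap of 4.5) rises until
the strongest candidate undergoes the detection instability; its global
inhibition then locks out every other candidate. This yields a unique
winner even for exactly tied inputs, because crossings are serialized by
the ramp. A minuscule fixed gradient (0.02, favoring the lower-left of
the scene and lower indices) resolves mathematical ties deterministically;
it is two orders of magnitude below any meaningful bias.

A "peak" throughout means a connected supra-threshold region with
integrated activation of at least 0.5 (in physical volume units).
Transient threshold micro-crossings while a selection resolves are
transition states of the instability, not self-stabilized peaks, and are
not counted.

## Perception and conjunction search

Scenes contain up to six objects on a 0–100 × 0–100 plane with four
feature dimensions: hue (circular, 0–360°), size (0–12 units), shape (a
categorical axis with well-separated Gaussian centers 20 units apart per
class), and motion direction (circular). Each object renders as a
Gaussian blob (spatial width 2.5 units, widened to 1.2× the grid spacing
on coarse grids so off-grid objects stay resolvable) at (position,
feature value) in one three-dimensional perception field per feature
dimension; the two spatial dimensions are shared across all fields, so an
object's features bind through space.

Search is cued by concept templates (Gaussian prototypes: e.g. blue at
hue 240° width 30°, "big" as an absolute size prototype 9 ± 1.5). Each
cued feature value contributes one match channel: the perception output
plus the cue slice must jointly exceed threshold in the feature/space
attention layer, the contraction over the feature axis is squashed into a
near-binary match rate (soft count, calibrated against the contraction
mass of one exactly matching object — the calibration helper
`calibrate_match_mass` is part of the public surface), and the spatial
attention field receives `6·presence + 2.5·(matches) − 2.5·K` for K cued
channels. A full conjunction sits ~1 above threshold; missing one cue
sits ≥ 1.5 below. Relational guidance adds the reference-shifted template
(averaged over relations, gain 1.0) so it can order matching candidates
but never lift a conjunction failure over threshold. "Big" is an absolute
size range; a scene-relative reading would need a normalization stage
that is out of scope.

## Relations and transforms

The relational representation lives on difference coordinates
d = target − reference (extent ±100 at scene resolution). The reference-
centering transform is computed by cross-correlation with the (mass-
normalized) reference map — the identical input–output contract of the
explicit gain field, whose literal joint-field implementation is kept at
low resolution and verified against the fast path. Guidance is the exact
adjoint (template convolved with the reference map), so
⟨center(t,r), T⟩ = ⟨t, invert(T,r)⟩ holds to machine precision.
Coordinates: x rightward, y upward; "left of" means smaller target x.
Differences falling outside the relational grid are clipped (objects near
borders lose template overlap).

Relation templates are the product of an angular profile around the
canonical axis (Gaussian of width 45°, shifted to cross zero at 90°
off-axis, negative beyond — the inhibitory counterpart of the patterned
coupling) and a radial plateau that is zero inside 3 units and full
beyond 6, so a target coincident with its reference never matches. Match
detection settles a detect-regime field under a localized bump at the
observed difference (gain 3.0) plus the template as patterned input (gain
2.0/T₄₅ where T₄₅ is the angular profile at 45°), placing the decision
boundary at 45° off-axis on the plateau. Movement relations rotate the
difference plane by −motion_dir (bilinear interpolation for maps, the
exact rotation matrix for single vectors); "approach" holds when the
patient lies within the cone ahead of the agent along its motion axis.
The decision cone is orientation-only; requiring the distance to shrink
over time would need temporal differencing the mechanism does not use.

## Conceptual structure and production

The symbolic content of a phrase is held in eight discrete working-memory
fields (concept × index, or index × index for role bindings), each a grid
of bistable self-excitatory sites; a binding is a sustained peak. The
index depth is 4 (configurable). The phrase DSL covers determiner +
optional property + noun, "which is" relative clauses, bare
postmodifiers, "and"-conjoined relation phrases, and simple
subject-verb-object sentences; indices are recruited in first-mention
order and an identical description reuses its index. A bare "and"
continuation attaches to the nearest noun phrase that already owns a
relation clause. Readout is a ridge mechanism: sub-threshold memory input
(2.5) plus ridge input along the selected index (3.0) exceeds threshold
only at bound sites. Production fields select one index at a time through
the same boost protocol, with inhibition-of-return (−4) and a dependency
bias (−1.5 per ungrounded prerequisite: reference objects of relations in
which the index is the target, and the patient of an action whose agent
it is). Ties resolve lowest-index-first.

## Sequencing

Each of the four grounding processes is an intention/condition-of-
satisfaction (CoS) node motif: the intention (h = −2, w_se = 6, bistable)
is raised by a precondition boost (4.0); the CoS node (h = −4, w_se = 3)
needs both the intention's pre-activation (2.5) and the outcome input
(3.0) to switch on; its inhibition (−8) dismantles the intention, whose
decay removes the pre-activation and resets the CoS — the full on/off
cycle is asserted, in order, from the event log. The CoS "on" criterion
is output > 0.9 for 5 consecutive ms (debouncing threshold chatter). A
process that cannot reach its outcome (a failed relation check, an empty
candidate field) is dismantled by transient inhibition instead — the
rejection path — and the rejected candidate receives an
inhibition-of-return mark before selection reopens. Commits are immutable
within a run (recommitting an index is an error); when every scene
location for an index has been rejected the run is flagged failed with
that index. Per-process timeout is 2000 ms simulated, global timeout
60 000 ms.

Simulated time is one coherent clock: node motifs advance it at 1 ms per
step, and each field-settling operation advances it by its settling
budget (attention 80 ms, selection ≤ 210 ms, relation match 60 ms,
production ≤ 145 ms, memory imprint 180 ms). Snapshot export records the
attention field at each candidate selection and the index-map slice at
each commit.

## Synthetic tasks and the symbolic oracle

The task generator emulates the study conditions: scenes of up to six
objects with a minimum pairwise distance of 3× the blob width, a target
description (shape, optionally a size property), up to two spatial
relations and one movement action. Reference and patient descriptions are
required to be individually unambiguous in the scene, because references
are committed before the target and commits cannot be backtracked — the
demonstration scene has the same property. The target's description may
be shared by distractors; the relations then single it out and the
architecture finds it by rejection and inhibition of return. Relation
and action geometry is sampled at least 10° clear of the 45° decision
cone, so grid quantization cannot flip a decision. Rejection sampling
continues until the brute-force symbolic oracle — exhaustive enumeration
of injective index-to-object assignments, nearest-prototype feature
matching, difference-vector geometry with the same 45° cone and a 5-unit
minimum range — finds exactly one satisfying assignment. Everything is
deterministic per seed.

What passing these tasks does *not* show: performance on real images
(features are rendered, not extracted), motion estimated from video (the
motion direction map is given), scenes with occlusion or crowding below
the blob-resolution limit, phrases outside the restricted grammar, or
reference descriptions that are only disambiguated relationally (that
would need commit backtracking, which the architecture does not have).

## Problem sizes

The default spatial resolution is 64 × 64 (the demonstration scene and
the acceptance script use it); the test suite runs most end-to-end checks
at 32 × 32 and the dynamical-regime properties at 48 × 48, resolutions at
which the presets were verified to behave identically. The explicit gain
field is exercised at 16 × 16, where the full joint representation is
65 536 samples. Neural/symbolic equivalence is measured on 20 generated
tasks with up to five objects, two relations and one action, noise off
and at q = 0.1.

## Known limitations

* The conjunction calibration assumes feature prototypes at least ~2
  template widths apart; a denser concept inventory would need the
  match-count inhibition recalibrated (the helper is provided).
* Working-memory capacity is soft: beyond ~6 simultaneous peaks in one
  memory field, global inhibition begins to erode the weakest peak.
* The phrase DSL attaches a bare "and" continuation to the nearest open
  clause; genuinely ambiguous attachments are resolved by that fixed rule
  rather than surfaced.
* Failed runs halt with a diagnostic; there is no repair or re-grounding
  strategy.
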