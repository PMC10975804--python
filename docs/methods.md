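# Methods

This note records what the package models, the choices made where the design
was genuinely open, and what its tests do and do not demonstrate.

## Perturbation model

A targeted joint receives a single displacement built from spherical
coordinates — dx = r sin φ cos θ, dy = r sin φ sin θ, dz = r cos φ — so its
Euclidean norm is *exactly* the configured radius r, whatever the angles.
The displacement is added to that joint's position in **every frame**: the
joint moves rigidly through time, emulating a constant sensor offset rather
than per-frame jitter. Two consequences are worth keeping in mind when
reading metric values:

* the **velocity branch is invariant** to the perturbation (frame
  differences cancel a constant), so RISv's input-change denominator is
  floored at ε_min and RISv values are orders of magnitude larger than
  RISj/RISb — only comparisons across methods at the same radius are
  meaningful;
* the prediction gap measures sensitivity to *positional offsets*, not to
  disrupted dynamics.

Angles are Gaussian by default — θ ~ N(0, π²), φ ~ N(π/2, (π/4)²), i.e., a
forward-centered direction law. The literature this follows specifies only
"Gaussian angles" without parameters; no invariant the package relies on
(norm, frame-consistency, locality, metric definitions) depends on the
direction distribution, and `uniform_sphere=True` gives isotropic
directions for users who want them. The default radius is 2.5 cm and the
sweep grid 2.5/5/10/20/40/80 cm; radii ≤ 7 cm keep the perturbed skeleton
inside the 1–7 cm tracking-error band of Kinect-class depth sensors
(`within_device_tolerance`), which is the operational definition of the
neighborhood N_X. The larger grid radii deliberately violate it to probe
metric breakdown.

Each replicate redraws its displacements (seeded by replicate index): n
identical copies would make the expectation in PGI/PGU degenerate.
Displacements are deterministic per (seed, joint), so enlarging a target set
never re-randomizes joints already in it.

## Metrics

**Faithfulness.** The scalar f(·) in PGI/PGU is the post-softmax probability
of the class predicted on the *original* input, held fixed across
replicates — PGI/PGU are then guaranteed to lie in [0, 1]. k ranges over
1..V; per-instance curves are collapsed with a trapezoidal AUC normalized by
the k-span (a constant curve returns that constant, making AUCs comparable
across k-grids).

**Stability.** For one replicate, the ratio is

    ‖(e_X − e_X')/(e_X + ε_div)‖_p / max(‖(P_X − P_X')/(P_X + ε_div)‖_p, ε_min)

and the per-instance statistic is the maximum over admitted replicates.
ε_div (default 1e-9) handles exact zeros — min–max-normalized maps always
contain a 0, and the joint/bone branches are identically zero at the root —
and is distinct from ε_min (default 1e-6), the denominator floor. Both are
config-exposed. The payload P is the respective input branch for RISj/v/b
and the logits vector for RRS. For ROS the payload is the *scalar* f(X),
the same quantity PGI/PGU difference: a near-saturated classifier barely
moves it, so the floored denominator collapses and ROS explodes — the
saturation diagnostic the test suite checks by comparing an overtrained
surrogate (loss < 1e-3) against a barely trained one (ratio must exceed
100×; measured ~10³–10⁵).

Replicates that flip the predicted class are excluded from the stability
maxima by default (`label_preserving_only`), and the admitted count is
reported; an instance with no admitted replicate yields NaN and is skipped
by the class aggregation (`nanmean`). Stability perturbs **all** joints per
replicate (the neighborhood sweep); the metric definitions quantify over
X' ∈ N_X with no k, so per-radius reporting is the default and the AUC over
k applies to PGI/PGU only. A `stability_per_k` mode (perturb top-k, AUC over
k, like PGI) is available for comparison.

Misclassified instances stay in class evaluation (flagged and counted);
`correct_only` drops them.

**Random baseline.** The random attribution for an input is seeded from a
CRC32 of its coordinate bytes mixed with the run seed: identical inputs get
identical maps (so all stabilities are exactly 0 at r = 0, as for CAM),
while any actual perturbation yields a fresh map — which is precisely what
makes the random baseline unstable relative to CAM.

## Synthetic data

Each class plants a trajectory (sinusoid, linear raise, or rectified
"bounce", applied to the vertical coordinate) on a set of driver joints of a
fixed 25-joint standing rest pose, plus i.i.d. Gaussian noise on every
coordinate. The default noise sd is 1 cm — inside the depth-sensor error
band, i.e., the same regime the perturbation radius is calibrated to. The
four default classes use disjoint driver sets (right arm / left arm / right
leg / head) with distinct patterns and frequencies, so class identity is a
deterministic function of driver trajectories at zero noise and the
ground-truth importance of every joint is known by construction.

What the generator does **not** emulate: biomechanical joint limits,
inter-subject style variation, camera-view changes, occlusion artifacts,
multi-person interaction. Passing tests therefore demonstrate that the
metric pipeline behaves correctly on data with known structure — not that
any particular XAI method is trustworthy on real recordings.

## Surrogate classifier

One spatial graph convolution per input branch (sum over each joint's
neighborhood including a self-loop, 3 → C channels, shared across frames),
branch outputs summed, ReLU, global average pooling over (frame, joint), and
a linear softmax head — the minimal architecture for which CAM is defined
and the Grad-CAM channel weights are exact in closed form,
α_n = w_eff[n, class]/(T·V). Grad-CAM is therefore a positive rescaling of
CAM, and after min–max normalization the two maps — hence rankings, hence
PGI/PGU — coincide exactly; the suite asserts this on 100% of instances and
validates the closed-form gradient against central finite differences.

Two frozen affine preprocessing stages are part of the model:

* **input centering** — the per-(branch, joint, axis) mean over the training
  set is subtracted before aggregation. Raw root-relative coordinates are
  dominated by the class-independent rest pose; without centering, CAM maps
  rank anatomy rather than motion. Centering is linear, so branch *changes*
  under perturbation (the RIS payloads, computed from raw branches) are
  unaffected;
* **feature standardization** — pooled features are z-scored with
  per-channel mean/sd frozen from the training set. Since this is affine it
  folds into effective head weights w_eff = w/σ, keeping the network exactly
  GAP + linear in the feature maps, which CAM requires.

Training follows the random-features recipe: the seeded convolution kernels
stay fixed and only the linear head is fitted, by deterministic full-batch
gradient descent on the cross-entropy (default 300 epochs, step 0.5). The
head problem is convex, so the fit is fast (fractions of a second),
perfectly reproducible, and free of the step-size pathologies of jointly
descending both layers; on the default synthetic classes the standardized
random graph features are already linearly separable, and held-out accuracy
is 100%. The surrogate is a deliberately small reference model for
exercising the metrics, not a competitive HAR architecture — no temporal
convolutions, attention, or batch normalization, and no claim to benchmark
accuracy on real datasets.

## Attribution conventions

No ReLU clamp is applied to raw CAM/Grad-CAM maps before normalization (the
map definitions used here have none); `relu_map=True` provides the classical
clamped dialect. Normalization is (s − min)/(max − min), mapping a constant
raw map to all zeros with a `degenerate` flag. Rankings average the
normalized map over frames first and break ties by ascending joint index —
deterministic and documented; normalizing before frame-averaging is the
convention adopted, the alternative order would yield the same ranking up to
the (positive affine) normalization and differs only for the displayed
per-joint scores. Ranking targets joints, not frames, because the
perturbation operator targets body points.

## Problem sizes

Defaults mirror the standard protocol: n = 50 replicates, k = 1..25, the
six-radius grid. The test suite and the acceptance script run scaled-down
configurations chosen to exercise every code path at desk scale: 4 classes
× 50 training / 20 evaluation instances, 64 frames, n = 10 replicates,
radius subset {2.5, 10, 80} cm, 50 random rankings for the PGI comparison.
These sizes keep the full suite under a minute while leaving the qualitative
orderings (CAM more stable than random at every radius; ROS saturation
ratio; CAM ≥ random PGI margin under strong perturbation) reproducible
across seeds.

## Known limitations

* The faithfulness comparison is radius-dependent: at small radii the
  surrogate — like any model on root-relative coordinates — is most
  sensitive to perturbing the root joint, whose own branch columns are
  identically zero and hence invisible to position-wise attribution; random
  rankings that hit the root then out-score informed rankings on PGI. The
  package treats this as a property to measure (and documents it in the
  planted-importance test at 80 cm, where class evidence itself is
  disrupted), not as a bug to hide.
* RIS magnitudes depend on the branch definitions (root-relative position,
  forward difference, parent difference — a documented simplification of
  production HAR preprocessing chains, which add multi-window velocities and
  bone angles) and are not comparable across preprocessing variants.
* The NTU reader keeps only the first tracked body; multi-person interaction
  classes are out of scope.
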