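"""CAM, Grad-CAM, and random attribution over (frame, joint) positions.

CAM scores a position by the class-weighted sum of final feature maps,
e[t, v] = sum_n w[n, class] * F_n[t, v]; Grad-CAM replaces w with channel
weights alpha obtained by averaging the logit gradient over all positions.
For a GAP + linear head alpha is proportional to w, so the two maps differ
only by a positive scale and coincide after min-max normalization — the
property the evaluation pipeline relies on and the test suite asserts.

Maps are kept raw by default; no ReLU clamp is applied before normalization
(the classical Grad-CAM clamp is available via ``relu_map=True`` for users
wanting that dialect). Joint rankings average the normalized map over frames
and sort descending, ties broken by ascending joint index.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import ModelOutput, SurrogateModel, gradcam_channel_weights

__all__ = [
    "AttributionMap",
    "JointRanking",
    "cam",
    "grad_cam",
    "random_attribution",
    "normalize",
    "rank_joints",
    "explain",
    "METHODS",
]

METHODS = ("cam", "gradcam", "random")


@dataclass(frozen=True)
class AttributionMap:
    """Per-frame per-joint importance scores e_X.

    ``degenerate`` marks a map whose raw scores were constant, which
    normalization maps to all zeros by convention.
    """

    scores: np.ndarray
    method: str
    class_id: int | None = None
    normalized: bool = False
    degenerate: bool = False

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        if s.ndim != 2:
            raise ValueError(f"scores must be T×V, got shape {s.shape}")
        if self.normalized and not self.degenerate:
            if s.min() < -1e-12 or s.max() > 1 + 1e-12:
                raise ValueError("normalized scores must lie in [0, 1]")

    @property
    def joint_means(self) -> np.ndarray:
        """Frame-averaged score per joint (length V)."""
        return self.scores.mean(axis=0)


@dataclass(frozen=True)
class JointRanking:
    """Joints ordered most- to least-important by frame-averaged score."""

    order: tuple[int, ...]
    mean_scores: np.ndarray

    def top_k(self, k: int) -> frozenset[int]:
        if not 0 <= k <= len(self.order):
            raise ValueError(f"k={k} out of range [0, {len(self.order)}]")
        return frozenset(self.order[:k])

    def bottom(self, k: int) -> frozenset[int]:
        """Complement of the top-k set."""
        return frozenset(self.order[k:])


def cam(out: ModelOutput, model: SurrogateModel, class_id: int) -> AttributionMap:
    """Class Activation Map: e[t, v] = sum_n w[n, class] F_n[t, v] (raw).

    Uses the effective head weights, i.e. the weights the logit applies
    directly to GAP(F) after the frozen standardization is folded in.
    """
    if not 0 <= class_id < model.n_classes:
        raise ValueError(f"class_id {class_id} out of range")
    scores = out.feature_maps @ model.effective_class_weights[:, class_id]
    return AttributionMap(scores=scores, method="cam", class_id=class_id)


def grad_cam(out: ModelOutput, model: SurrogateModel, class_id: int) -> AttributionMap:
    """Grad-CAM: e[t, v] = sum_n alpha_n F_n[t, v], alpha the averaged gradient."""
    alpha = gradcam_channel_weights(model, out, class_id)
    scores = out.feature_maps @ alpha
    return AttributionMap(scores=scores, method="gradcam", class_id=class_id)


def random_attribution(T: int, V: int, seed: int) -> AttributionMap:
    """Uniform[0, 1) scores — the least-informative baseline attribution."""
    if T < 1 or V < 1:
        raise ValueError("T and V must be >= 1")
    rng = np.random.default_rng(seed)
    return AttributionMap(scores=rng.random((T, V)), method="random")


def normalize(amap: AttributionMap, relu_map: bool = False) -> AttributionMap:
    """Min-max rescale scores to [0, 1]; a constant map becomes all zeros.

    Idempotent on already-normalized maps. ``relu_map=True`` clamps negative
    raw scores to zero first (classical Grad-CAM convention; off by default).
    """
    s = amap.scores
    if not np.isfinite(s).all():
        raise ValueError("attribution scores must be finite")
    if relu_map:
        s = np.maximum(s, 0.0)
    lo, hi = s.min(), s.max()
    if hi - lo == 0.0:
        return replace(amap, scores=np.zeros_like(s), normalized=True, degenerate=True)
    return replace(amap, scores=(s - lo) / (hi - lo), normalized=True)


def rank_joints(amap: AttributionMap) -> JointRanking:
    """Rank joints by frame-averaged score, descending; ties by joint index."""
    if not amap.normalized:
        raise ValueError("rank_joints expects a normalized map")
    means = amap.joint_means
    order = np.argsort(-means, kind="stable")  # stable => ascending index on ties
    return JointRanking(order=tuple(int(i) for i in order), mean_scores=means)


def explain(
    model: SurrogateModel,
    out: ModelOutput,
    method: str,
    class_id: int | None = None,
    seed: int = 0,
    relu_map: bool = False,
) -> AttributionMap:
    """Normalized attribution of ``class_id`` (default: the predicted class)."""
    if class_id is None:
        class_id = out.predicted_class
    if method == "cam":
        raw = cam(out, model, class_id)
    elif method == "gradcam":
        raw = grad_cam(out, model, class_id)
    elif method == "random":
        T, V, _ = out.feature_maps.shape
        raw = random_attribution(T, V, seed)
    else:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return normalize(raw, relu_map=relu_map)
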