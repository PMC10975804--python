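"""A small graph-convolutional classifier used as the explained model.

The architecture is the minimal one for which Class Activation Mapping is
defined and the Grad-CAM channel weights have a closed form:

* one spatial graph-convolution layer per input branch (joint, velocity,
  bone): features aggregated over each joint's graph neighborhood (with a
  self-loop) and mapped 3 → C channels, shared across frames;
* the three branch outputs are summed and passed through a ReLU, giving
  feature maps F of shape T×V×C;
* global average pooling (GAP) over all (frame, joint) positions;
* a linear softmax head with class weights w (C×K) and bias.

Because the head is GAP + linear, the gradient of a class logit with respect
to the feature maps is constant: alpha_n = w_eff[n, class] / (T*V). This
makes Grad-CAM a positive rescaling of CAM, an exact algebraic property this
package exploits and tests.

Training follows the random-features (reservoir) recipe: the seeded graph
convolution kernels are kept fixed, and only the linear head is fitted by
deterministic full-batch gradient descent on the cross-entropy, over pooled
features standardized with per-channel mean/sd frozen from the training set.
The head problem is convex, so the fit is fast, reproducible, and free of
the conditioning pathologies of jointly training both layers with one step
size. The standardization is affine, hence it folds into *effective* class
weights w_eff = w / sigma (exposed as ``effective_class_weights``) — the
model remains exactly a GAP + linear network in the feature maps, which is
what CAM requires. No autodiff framework, no GPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .skeleton import (
    InputBranches,
    SkeletonGraph,
    SkeletonSequence,
    compute_branches,
    ntu_graph,
)

__all__ = [
    "SurrogateModel",
    "ModelOutput",
    "forward",
    "train",
    "train_surrogate",
    "gradcam_channel_weights",
    "save_model",
    "load_model",
]

BRANCH_NAMES = ("joint", "velocity", "bone")


@dataclass
class ModelOutput:
    """Forward-pass artifacts of one sequence.

    ``feature_maps`` is the post-ReLU T×V×C tensor F (channel n slice F_n);
    ``logits`` the pre-softmax K-vector L_X used as the model's internal
    representation; ``probs`` the softmax of the logits.
    """

    probs: np.ndarray
    logits: np.ndarray
    feature_maps: np.ndarray
    pooled: np.ndarray

    @property
    def predicted_class(self) -> int:
        return int(np.argmax(self.probs))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class SurrogateModel:
    """GCN classifier with joint/velocity/bone branches and a GAP+linear head.

    Parameters
    ----------
    graph
        Skeleton graph defining the spatial aggregation neighborhoods.
    branch_weights
        Per-branch C×3 graph-convolution kernels, keyed "joint"/"velocity"/"bone".
    class_weights
        C×K weight matrix w applied after global average pooling.
    class_bias
        Length-K bias.
    classes
        Original class labels, index-aligned with the logit axis.
    """

    graph: SkeletonGraph
    branch_weights: dict[str, np.ndarray]
    class_weights: np.ndarray
    class_bias: np.ndarray
    classes: tuple[int, ...]
    branch_center: dict[str, np.ndarray] | None = None
    feature_mu: np.ndarray | None = None
    feature_sigma: np.ndarray | None = None
    train_accuracy: float | None = None
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self):
        C = self.class_weights.shape[0]
        V = self.graph.joint_count
        if self.branch_center is None:
            self.branch_center = {n: np.zeros((V, 3)) for n in BRANCH_NAMES}
        if self.feature_mu is None:
            self.feature_mu = np.zeros(C)
        if self.feature_sigma is None:
            self.feature_sigma = np.ones(C)

    @property
    def hidden_channels(self) -> int:
        return self.class_weights.shape[0]

    @property
    def n_classes(self) -> int:
        return self.class_weights.shape[1]

    @classmethod
    def initialize(
        cls,
        graph: SkeletonGraph | None = None,
        n_classes: int = 4,
        hidden_channels: int = 16,
        seed: int = 0,
        classes: tuple[int, ...] | None = None,
        init_sd: float = 0.1,
    ) -> "SurrogateModel":
        """Seeded Gaussian initialization (sd ``init_sd``), zero bias."""
        graph = graph if graph is not None else ntu_graph()
        rng = np.random.default_rng(seed)
        C, K = hidden_channels, n_classes
        bw = {name: rng.normal(0.0, init_sd, size=(C, 3)) for name in BRANCH_NAMES}
        Wc = rng.normal(0.0, init_sd, size=(C, K))
        if classes is None:
            classes = tuple(range(K))
        if len(classes) != K:
            raise ValueError("classes must have one label per output")
        return cls(
            graph=graph,
            branch_weights=bw,
            class_weights=Wc,
            class_bias=np.zeros(K),
            classes=tuple(classes),
        )

    def copy(self) -> "SurrogateModel":
        return SurrogateModel(
            graph=self.graph,
            branch_weights={k: v.copy() for k, v in self.branch_weights.items()},
            class_weights=self.class_weights.copy(),
            class_bias=self.class_bias.copy(),
            classes=self.classes,
            branch_center={k: v.copy() for k, v in self.branch_center.items()},
            feature_mu=self.feature_mu.copy(),
            feature_sigma=self.feature_sigma.copy(),
            train_accuracy=self.train_accuracy,
            loss_history=list(self.loss_history),
        )

    @property
    def effective_class_weights(self) -> np.ndarray:
        """Head weights expressed directly on GAP(F): w_eff = w / sigma.

        logits = ((GAP(F) - mu) / sigma) @ w + b = GAP(F) @ w_eff + const,
        so CAM and the Grad-CAM closed form must use these weights.
        """
        return self.class_weights / self.feature_sigma[:, None]

    def class_index(self, label) -> int:
        return self.classes.index(label)

    # -- forward -----------------------------------------------------------

    def _aggregate(self, branches: InputBranches) -> dict[str, np.ndarray]:
        """Center each branch (frozen training means), then sum over the
        graph neighborhood of every joint (self-loop included)."""
        A = self.graph.adjacency(self_loops=True)
        return {
            name: np.einsum("uv,tud->tvd", A, arr - self.branch_center[name])
            for name, arr in branches.as_dict().items()
        }

    def forward(self, branches: InputBranches) -> ModelOutput:
        """Run the network on precomputed branches; see :func:`forward`."""
        T, V, _ = branches.joint.shape
        if V != self.graph.joint_count:
            raise ValueError(
                f"branches have V={V}, model graph has V={self.graph.joint_count}"
            )
        agg = self._aggregate(branches)
        pre = np.zeros((T, V, self.hidden_channels))
        for name in BRANCH_NAMES:
            pre += agg[name] @ self.branch_weights[name].T
        F = np.maximum(pre, 0.0)
        pooled = F.mean(axis=(0, 1))
        z = (pooled - self.feature_mu) / self.feature_sigma
        logits = z @ self.class_weights + self.class_bias
        return ModelOutput(
            probs=_softmax(logits), logits=logits, feature_maps=F, pooled=pooled
        )

    def forward_sequence(self, seq: SkeletonSequence) -> ModelOutput:
        return self.forward(compute_branches(seq, self.graph))


def forward(model: SurrogateModel, branches: InputBranches) -> ModelOutput:
    """Feature maps, logits, and softmax probabilities for one input.

    F[t, v, :] = ReLU(sum over branches of kernel @ (sum of the branch over
    the graph neighborhood of v, self-loop included)); logits are the linear
    head applied to the GAP of F; probs = softmax(logits).
    """
    return model.forward(branches)


def gradcam_channel_weights(
    model: SurrogateModel, out: ModelOutput, class_id: int
) -> np.ndarray:
    """Grad-CAM channel weights: gradients of the class logit averaged over (t, v).

    For a GAP + linear head this is exact and closed-form:
    alpha_n = w_eff[n, class] / (T*V), independent of the input, where
    w_eff absorbs the frozen feature standardization.
    """
    if not 0 <= class_id < model.n_classes:
        raise ValueError(f"class_id {class_id} out of range [0, {model.n_classes})")
    T, V, _ = out.feature_maps.shape
    return model.effective_class_weights[:, class_id] / (T * V)


# -- training ---------------------------------------------------------------


def _stack_aggregated(model, dataset):
    """Precompute graph-aggregated branches for every sequence, stacked N×T×V×3."""
    T0 = dataset[0].frame_count
    if any(s.frame_count != T0 for s in dataset):
        raise ValueError("training requires all sequences to share one frame count")
    aggs = {name: [] for name in BRANCH_NAMES}
    for seq in dataset:
        a = model._aggregate(compute_branches(seq, model.graph))
        for name in BRANCH_NAMES:
            aggs[name].append(a[name])
    return {name: np.stack(v) for name, v in aggs.items()}


def _pooled_features(m: SurrogateModel, agg) -> np.ndarray:
    """GAP of the post-ReLU feature maps for every sequence (N×C)."""
    pre = np.zeros(agg["joint"].shape[:3] + (m.hidden_channels,))
    for name in BRANCH_NAMES:
        pre += agg[name] @ m.branch_weights[name].T
    return np.maximum(pre, 0.0).mean(axis=(1, 2))


def train(
    model: SurrogateModel,
    dataset: list[SkeletonSequence],
    epochs: int = 300,
    learning_rate: float = 0.5,
    seed: int = 0,
) -> SurrogateModel:
    """Fit the linear head by deterministic full-batch gradient descent.

    The graph-convolution kernels stay at their seeded initialization
    (random graph features); the pooled features are standardized with
    per-channel mean/sd measured on ``dataset`` and frozen into the model,
    and the convex head problem is descended for ``epochs`` steps on the
    mean cross-entropy. Returns a new model (the input is untouched); with
    ``epochs=0`` the model is returned unchanged. The fit is deterministic
    given the initial weights; ``seed`` is accepted for API symmetry with
    the generators and reserved for stochastic variants.
    """
    del seed  # full-batch descent has no stochasticity
    if not dataset:
        raise ValueError("empty dataset")
    labels = [s.label for s in dataset]
    if any(lab is None for lab in labels):
        raise ValueError("all training sequences need labels")
    present = sorted(set(labels))
    if len(present) < 2:
        raise ValueError("training needs at least two classes")
    unknown = [lab for lab in present if lab not in model.classes]
    if unknown:
        raise ValueError(f"labels {unknown} not among model classes {model.classes}")

    m = model.copy()
    if epochs == 0:
        return m
    y = np.array([m.class_index(lab) for lab in labels])
    N = len(dataset)
    # freeze input centering: per-(branch, joint, axis) mean over the train set
    raw = [compute_branches(s, m.graph) for s in dataset]
    m.branch_center = {
        name: np.mean([b.as_dict()[name] for b in raw], axis=(0, 1))
        for name in BRANCH_NAMES
    }
    agg = _stack_aggregated(m, dataset)  # name -> N×T×V×3, centered
    pooled = _pooled_features(m, agg)
    m.feature_mu = pooled.mean(axis=0)
    m.feature_sigma = pooled.std(axis=0) + 1e-12
    Z = (pooled - m.feature_mu) / m.feature_sigma
    onehot = np.eye(m.n_classes)[y]

    m.loss_history = []
    for _ in range(epochs):
        logits = Z @ m.class_weights + m.class_bias
        probs = _softmax(logits)
        loss = -np.mean(np.log(probs[np.arange(N), y] + 1e-300))
        m.loss_history.append(float(loss))
        dlogits = (probs - onehot) / N
        m.class_weights -= learning_rate * (Z.T @ dlogits)
        m.class_bias -= learning_rate * dlogits.sum(axis=0)

    preds = np.argmax(Z @ m.class_weights + m.class_bias, axis=1)
    m.train_accuracy = float(np.mean(preds == y))
    return m


def train_surrogate(
    dataset: list[SkeletonSequence],
    graph: SkeletonGraph | None = None,
    hidden_channels: int = 16,
    epochs: int = 300,
    learning_rate: float = 0.5,
    seed: int = 0,
) -> SurrogateModel:
    """Initialize (seeded) and train a surrogate on a labeled dataset."""
    labels = sorted({s.label for s in dataset if s.label is not None})
    model = SurrogateModel.initialize(
        graph=graph,
        n_classes=len(labels),
        hidden_channels=hidden_channels,
        seed=seed,
        classes=tuple(labels),
    )
    return train(model, dataset, epochs=epochs, learning_rate=learning_rate, seed=seed)


def accuracy(model: SurrogateModel, dataset: list[SkeletonSequence]) -> float:
    """Fraction of sequences whose argmax class matches the label."""
    hits = 0
    for seq in dataset:
        out = model.forward_sequence(seq)
        hits += model.classes[out.predicted_class] == seq.label
    return hits / len(dataset)


# -- checkpointing ----------------------------------------------------------


def save_model(model: SurrogateModel, path) -> None:
    """Write weights to ``path`` (.npz) and hyperparameters to ``path + '.json'``."""
    path = Path(path)
    with open(path, "wb") as fh:  # handle keeps np.savez from appending .npz
        np.savez(
            fh,
            W_joint=model.branch_weights["joint"],
            W_velocity=model.branch_weights["velocity"],
            W_bone=model.branch_weights["bone"],
            class_weights=model.class_weights,
            class_bias=model.class_bias,
            center_joint=model.branch_center["joint"],
            center_velocity=model.branch_center["velocity"],
            center_bone=model.branch_center["bone"],
            feature_mu=model.feature_mu,
            feature_sigma=model.feature_sigma,
        )
    sidecar = {
        "hidden_channels": model.hidden_channels,
        "n_classes": model.n_classes,
        "classes": list(model.classes),
        "train_accuracy": model.train_accuracy,
        "graph": {
            "joint_count": model.graph.joint_count,
            "edges": [list(e) for e in model.graph.edges],
            "parent": list(model.graph.parent),
            "joint_names": list(model.graph.joint_names),
        },
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_model(path) -> SurrogateModel:
    """Read a checkpoint written by :func:`save_model`."""
    path = Path(path)
    with open(str(path) + ".json") as fh:
        side = json.load(fh)
    g = side["graph"]
    graph = SkeletonGraph(
        joint_count=g["joint_count"],
        edges=tuple(tuple(e) for e in g["edges"]),
        parent=tuple(g["parent"]),
        joint_names=tuple(g["joint_names"]),
    )
    with np.load(path, allow_pickle=False) as data:
        model = SurrogateModel(
            graph=graph,
            branch_weights={
                "joint": data["W_joint"],
                "velocity": data["W_velocity"],
                "bone": data["W_bone"],
            },
            class_weights=data["class_weights"],
            class_bias=data["class_bias"],
            branch_center={
                "joint": data["center_joint"],
                "velocity": data["center_velocity"],
                "bone": data["center_bone"],
            },
            feature_mu=data["feature_mu"],
            feature_sigma=data["feature_sigma"],
            classes=tuple(side["classes"]),
            train_accuracy=side.get("train_accuracy"),
        )
    return model
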