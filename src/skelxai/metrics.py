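"""Faithfulness (PGI/PGU) and stability (RIS/ROS/RRS) metrics for attributions.

Faithfulness compares the model's output change against what the attribution
claims matters:

* PGI (Prediction Gap on Important features): expected |f(X) - f(X')| when
  the top-k ranked joints are perturbed — higher is better;
* PGU (Prediction Gap on Unimportant features): the same with the complement
  of the top-k — lower is better.

Here f(.) is the post-softmax probability of the class predicted on the
*original* input, held fixed across replicates, and the expectation is the
mean over n perturbation replicates.

Stability measures how violently the explanation itself reacts to
neighborhood perturbations, as the worst-case ratio over admitted replicates
of the relative explanation change to the relative change of a reference
payload: the joint / velocity / bone input branch (RISj, RISv, RISb), the
output probability vector (ROS), or the pre-softmax logits (RRS). Values
near zero mean a robust explanation. Replicates that flip the predicted
class are excluded by default (the label-preservation constraint); the
admitted count is reported.

Per-instance PGI/PGU curves over k are collapsed with a span-normalized
trapezoidal AUC; class-level results are mean ± sd over instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .attribution import JointRanking, explain, rank_joints
from .model import SurrogateModel
from .perturbation import (
    RADIUS_GRID_M,
    PerturbationSpec,
    perturb_joints,
    replicate_perturbations,
)
from .skeleton import SkeletonSequence, compute_branches

__all__ = [
    "MetricConfig",
    "MetricResult",
    "EvaluationResult",
    "DegenerateExplanationError",
    "prediction_gap",
    "pgi",
    "pgu",
    "relative_stability",
    "stability_suite",
    "auc_over_k",
    "evaluate_class",
    "STABILITY_METRICS",
]

STABILITY_METRICS = ("RISj", "RISv", "RISb", "ROS", "RRS")
FAITHFULNESS_METRICS = ("PGI", "PGU")

_METHOD_TAG = {"cam": 11, "gradcam": 12, "random": 13}


class DegenerateExplanationError(ValueError):
    """The original explanation is identically zero; stability is undefined."""


@dataclass(frozen=True)
class MetricConfig:
    """Knobs of the evaluation pipeline.

    ``eps_min`` floors the stability denominator ratio; ``eps_div`` is added
    elementwise wherever a relative change divides by a quantity that can be
    exactly zero (min-max-normalized scores, zero branch entries).
    ``stability_per_k`` switches stability from one full-joint sweep per
    radius (default) to a top-k sweep aggregated by AUC like PGI/PGU.
    """

    p_norm: float = 2.0
    eps_min: float = 1e-6
    eps_div: float = 1e-9
    k_values: tuple[int, ...] | None = None  # default 1..V
    radius_grid_m: tuple[float, ...] = RADIUS_GRID_M
    n_replicates: int = 50
    label_preserving_only: bool = True
    correct_only: bool = False
    stability_per_k: bool = False
    uniform_sphere: bool = False
    relu_maps: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.p_norm < 1:
            raise ValueError("p_norm must be >= 1")
        if self.eps_min <= 0 or self.eps_div <= 0:
            raise ValueError("eps_min and eps_div must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def ks(self, V: int) -> tuple[int, ...]:
        if self.k_values is None:
            return tuple(range(1, V + 1))
        if any(not 0 <= k <= V for k in self.k_values):
            raise ValueError(f"k_values must lie in [0, {V}]")
        return tuple(self.k_values)


def _content_seed(seq: SkeletonSequence, base_seed: int) -> int:
    """Seed derived from the coordinate bytes: identical inputs, identical map."""
    import zlib

    return derive_seed(base_seed, zlib.crc32(np.ascontiguousarray(seq.coords).tobytes()))


def _explain_seq(model, seq, out, method, config, class_id=None):
    return explain(
        model,
        out,
        method,
        class_id=class_id,
        seed=_content_seed(seq, derive_seed(config.seed, _METHOD_TAG[method])),
        relu_map=config.relu_maps,
    )


# -- faithfulness -----------------------------------------------------------


def prediction_gap(
    model: SurrogateModel,
    seq: SkeletonSequence,
    target_joints,
    spec: PerturbationSpec,
) -> float:
    """Mean |f(X) - f(X')| over n replicates perturbing ``target_joints``.

    f is the probability of the class predicted on the original X, fixed
    across replicates. Empty target set (or r = 0) gives exactly 0.
    """
    out0 = model.forward_sequence(seq)
    c = out0.predicted_class
    f0 = out0.probs[c]
    gaps = [
        abs(f0 - model.forward_sequence(rep).probs[c])
        for rep in replicate_perturbations(seq, target_joints, spec)
    ]
    return float(np.mean(gaps))


def pgi(
    model: SurrogateModel,
    seq: SkeletonSequence,
    ranking: JointRanking,
    k: int,
    spec: PerturbationSpec,
) -> float:
    """Prediction gap when the top-k ranked joints are perturbed."""
    return prediction_gap(model, seq, ranking.top_k(k), spec)


def pgu(
    model: SurrogateModel,
    seq: SkeletonSequence,
    ranking: JointRanking,
    k: int,
    spec: PerturbationSpec,
) -> float:
    """Prediction gap when everything *except* the top-k joints is perturbed."""
    return prediction_gap(model, seq, ranking.bottom(k), spec)


# -- stability --------------------------------------------------------------


def _rel_change_norm(a: np.ndarray, b: np.ndarray, p: float, eps_div: float) -> float:
    """p-norm of the elementwise relative change (a - b) / (a + eps_div)."""
    rel = (np.asarray(a, float) - np.asarray(b, float)) / (np.asarray(a, float) + eps_div)
    return float(np.linalg.norm(rel.ravel(), ord=p))


def relative_stability(
    e_x: np.ndarray,
    e_xp: np.ndarray,
    payload_x: np.ndarray,
    payload_xp: np.ndarray,
    config: MetricConfig,
) -> float:
    """Stability ratio for ONE perturbation replicate.

    numerator   = || (e_X - e_X') / (e_X + eps_div) ||_p
    denominator = max(|| (P_X - P_X') / (P_X + eps_div) ||_p, eps_min)

    where P is the payload whose change normalizes the explanation change
    (an input branch, the probability vector, or the logits). The
    per-instance statistic is the max of this ratio over admitted
    replicates, taken by :func:`stability_suite`.
    """
    e_x = np.asarray(e_x, float)
    if not np.any(e_x != 0):
        raise DegenerateExplanationError(
            "original explanation is identically zero; stability is undefined"
        )
    if e_x.shape != np.asarray(e_xp).shape:
        raise ValueError("explanation shapes differ")
    num = _rel_change_norm(e_x, e_xp, config.p_norm, config.eps_div)
    den = max(
        _rel_change_norm(payload_x, payload_xp, config.p_norm, config.eps_div),
        config.eps_min,
    )
    return num / den


@dataclass
class StabilitySuiteResult:
    """Per-instance stability values plus the admitted-replicate count."""

    values: dict[str, float]
    n_admitted: int
    n_replicates: int


def stability_suite(
    model: SurrogateModel,
    seq: SkeletonSequence,
    method: str,
    spec: PerturbationSpec,
    config: MetricConfig,
    target_joints=None,
) -> StabilitySuiteResult:
    """Max-over-replicates RISj/RISv/RISb/ROS/RRS for one instance.

    Each replicate perturbs ``target_joints`` (default: every joint — the
    explanation-neighborhood sweep), recomputes the explanation of the
    originally predicted class on X', and forms the five stability ratios.
    With ``config.label_preserving_only`` only replicates whose predicted
    class matches the original are admitted to the maxima; if none are, the
    values are NaN and ``n_admitted`` is 0.
    """
    graph = model.graph
    if target_joints is None:
        target_joints = range(graph.joint_count)
    branches0 = compute_branches(seq, graph)
    out0 = model.forward(branches0)
    e0 = _explain_seq(model, seq, out0, method, config)
    if e0.degenerate:
        raise DegenerateExplanationError(
            "original explanation is constant (normalizes to all zeros)"
        )
    c0 = out0.predicted_class
    payloads0 = {
        "RISj": branches0.joint,
        "RISv": branches0.velocity,
        "RISb": branches0.bone,
        # ROS normalizes by the change of the scalar f(X): the probability of
        # the originally predicted class — the same scalar PGI/PGU difference.
        # Near-saturated classifiers barely move it, so the floored denominator
        # makes ROS blow up: the small-denominator saturation diagnostic.
        "ROS": np.array([out0.probs[c0]]),
        "RRS": out0.logits,
    }
    best = {m: -np.inf for m in STABILITY_METRICS}
    n_admitted = 0
    for i in range(spec.n_replicates):
        seq_p = perturb_joints(
            seq,
            target_joints,
            spec.radius_m,
            derive_seed(spec.seed, i),
            uniform_sphere=spec.uniform_sphere,
        )
        branches_p = compute_branches(seq_p, graph)
        out_p = model.forward(branches_p)
        if config.label_preserving_only and out_p.predicted_class != out0.predicted_class:
            continue
        n_admitted += 1
        e_p = _explain_seq(
            model, seq_p, out_p, method, config, class_id=out0.predicted_class
        )
        payloads_p = {
            "RISj": branches_p.joint,
            "RISv": branches_p.velocity,
            "RISb": branches_p.bone,
            "ROS": np.array([out_p.probs[c0]]),
            "RRS": out_p.logits,
        }
        for m in STABILITY_METRICS:
            val = relative_stability(
                e0.scores, e_p.scores, payloads0[m], payloads_p[m], config
            )
            best[m] = max(best[m], val)
    if n_admitted == 0:
        best = {m: float("nan") for m in STABILITY_METRICS}
    return StabilitySuiteResult(
        values={m: float(v) for m, v in best.items()},
        n_admitted=n_admitted,
        n_replicates=spec.n_replicates,
    )


# -- aggregation ------------------------------------------------------------


def auc_over_k(values, k_values=None) -> float:
    """Span-normalized trapezoidal AUC of a metric curve over k.

    A constant curve returns that constant, making AUCs comparable across
    different k grids. Needs at least two points.
    """
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("auc_over_k needs at least two k points")
    k = (
        np.arange(1, values.size + 1, dtype=float)
        if k_values is None
        else np.asarray(k_values, float)
    )
    if k.size != values.size:
        raise ValueError("k_values length must match values")
    if np.any(np.diff(k) <= 0):
        raise ValueError("k_values must be strictly increasing")
    return float(np.trapezoid(values, k) / (k[-1] - k[0]))


@dataclass
class MetricResult:
    """Class-level summary of one metric / method / radius combination."""

    metric: str
    method: str
    radius_m: float
    per_instance: np.ndarray
    n_instances: int
    n_label_preserving: int | None = None
    n_misclassified: int = 0

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.per_instance))

    @property
    def std(self) -> float:
        return float(np.nanstd(self.per_instance, ddof=0))

    @property
    def ci95(self) -> float:
        n = np.sum(~np.isnan(self.per_instance))
        return float(1.96 * self.std / np.sqrt(n)) if n > 0 else float("nan")


@dataclass
class EvaluationResult:
    """All metric results of one evaluation run, with a tabular view."""

    results: list[MetricResult]
    config: MetricConfig
    method: str

    def get(self, metric: str, radius_m: float) -> MetricResult:
        for r in self.results:
            if r.metric == metric and np.isclose(r.radius_m, radius_m):
                return r
        raise KeyError(f"no result for metric={metric!r}, radius={radius_m}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metric": r.metric,
                "method": r.method,
                "radius_cm": r.radius_m * 100,
                "mean": r.mean,
                "std": r.std,
                "ci95": r.ci95,
                "n": r.n_instances,
                "n_label_preserving": r.n_label_preserving,
                "n_misclassified": r.n_misclassified,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        with pd.option_context("display.width", 120):
            return self.to_frame().to_string(
                index=False, float_format=lambda x: f"{x:.6g}"
            )


def evaluate_class(
    model: SurrogateModel,
    instances: list[SkeletonSequence],
    method: str,
    config: MetricConfig,
) -> EvaluationResult:
    """Per-class evaluation: all seven metrics at every radius in the grid.

    For each instance and radius, PGI and PGU are computed for every k in
    the configured grid and collapsed by AUC; the stability suite runs once
    per instance per radius over a full-joint sweep (or per k, AUC-collapsed,
    when ``config.stability_per_k``). Mean ± sd is taken across instances.
    Misclassified instances are kept (and counted) unless
    ``config.correct_only``.
    """
    if not instances:
        raise ValueError("need at least one instance")
    V = model.graph.joint_count
    ks = config.ks(V)
    results: list[MetricResult] = []
    for ri, radius in enumerate(config.radius_grid_m):
        acc: dict[str, list[float]] = {
            m: [] for m in FAITHFULNESS_METRICS + STABILITY_METRICS
        }
        admitted_total = 0
        n_mis = 0
        n_used = 0
        for idx, seq in enumerate(instances):
            out0 = model.forward_sequence(seq)
            correct = (
                seq.label is None
                or model.classes[out0.predicted_class] == seq.label
            )
            if not correct:
                n_mis += 1
                if config.correct_only:
                    continue
            n_used += 1
            e0 = _explain_seq(model, seq, out0, method, config)
            ranking = rank_joints(e0)
            base = derive_seed(config.seed, ri, idx)
            pgi_vals = [
                pgi(model, seq, ranking, k,
                    PerturbationSpec(radius, config.n_replicates,
                                     derive_seed(base, 1, k),
                                     uniform_sphere=config.uniform_sphere))
                for k in ks
            ]
            pgu_vals = [
                pgu(model, seq, ranking, k,
                    PerturbationSpec(radius, config.n_replicates,
                                     derive_seed(base, 2, k),
                                     uniform_sphere=config.uniform_sphere))
                for k in ks
            ]
            acc["PGI"].append(auc_over_k(pgi_vals, ks) if len(ks) > 1 else pgi_vals[0])
            acc["PGU"].append(auc_over_k(pgu_vals, ks) if len(ks) > 1 else pgu_vals[0])
            if config.stability_per_k:
                per_k = {m: [] for m in STABILITY_METRICS}
                for k in ks:
                    suite = stability_suite(
                        model, seq, method,
                        PerturbationSpec(radius, config.n_replicates,
                                         derive_seed(base, 3, k),
                                         uniform_sphere=config.uniform_sphere),
                        config,
                        target_joints=ranking.top_k(k),
                    )
                    admitted_total += suite.n_admitted
                    for m in STABILITY_METRICS:
                        per_k[m].append(suite.values[m])
                for m in STABILITY_METRICS:
                    vals = per_k[m]
                    acc[m].append(
                        auc_over_k(vals, ks) if len(ks) > 1 else vals[0]
                    )
            else:
                suite = stability_suite(
                    model, seq, method,
                    PerturbationSpec(radius, config.n_replicates,
                                     derive_seed(base, 3),
                                     uniform_sphere=config.uniform_sphere),
                    config,
                )
                admitted_total += suite.n_admitted
                for m in STABILITY_METRICS:
                    acc[m].append(suite.values[m])
        for m in FAITHFULNESS_METRICS + STABILITY_METRICS:
            results.append(
                MetricResult(
                    metric=m,
                    method=method,
                    radius_m=radius,
                    per_instance=np.asarray(acc[m], float),
                    n_instances=n_used,
                    n_label_preserving=(
                        admitted_total if m in STABILITY_METRICS else None
                    ),
                    n_misclassified=n_mis,
                )
            )
    return EvaluationResult(results=results, config=config, method=method)
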