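"""Faithfulness and stability metrics against independent brute-force oracles."""

import numpy as np
import pytest

from skelxai import (
    MetricConfig,
    PerturbationSpec,
    SkeletonSequence,
    SurrogateModel,
    auc_over_k,
    cam,
    compute_branches,
    evaluate_class,
    normalize,
    perturb_joints,
    pgi,
    pgu,
    prediction_gap,
    rank_joints,
    relative_stability,
    stability_suite,
)
from skelxai._seeds import derive_seed
from skelxai.metrics import DegenerateExplanationError, STABILITY_METRICS, _explain_seq


@pytest.fixture
def toy_model(graph):
    """Untrained 2-class surrogate with seeded random weights."""
    return SurrogateModel.initialize(graph, n_classes=2, hidden_channels=4, seed=17)


@pytest.fixture
def toy_sequence(graph):
    rng = np.random.default_rng(23)
    return SkeletonSequence(
        coords=rng.normal(0.0, 0.3, size=(8, 25, 3)), label=0, instance_id="toy8"
    )


class TestPredictionGap:
    def test_zero_radius_gives_zero(self, toy_model, toy_sequence):
        spec = PerturbationSpec(radius_m=0.0, n_replicates=5, seed=1)
        assert prediction_gap(toy_model, toy_sequence, {1, 2}, spec) == 0.0

    def test_empty_target_set_gives_zero(self, toy_model, toy_sequence):
        spec = PerturbationSpec(radius_m=0.1, n_replicates=5, seed=1)
        assert prediction_gap(toy_model, toy_sequence, set(), spec) == 0.0

    def test_matches_bruteforce_replicate_loop(self, toy_model, toy_sequence):
        """Library value equals an explicit loop recomputing every
        |f(X) - f(X')| outside the metric code."""
        targets = {3, 8, 5}
        spec = PerturbationSpec(radius_m=0.1, n_replicates=10, seed=3)
        got = prediction_gap(toy_model, toy_sequence, targets, spec)
        out0 = toy_model.forward_sequence(toy_sequence)
        c = out0.predicted_class
        gaps = []
        for i in range(10):
            seq_p = perturb_joints(toy_sequence, targets, 0.1, derive_seed(3, i))
            gaps.append(abs(out0.probs[c] - toy_model.forward_sequence(seq_p).probs[c]))
        assert got == pytest.approx(sum(gaps) / 10, abs=1e-12)


class TestPgiPgu:
    def test_k0_pgi_and_kV_pgu_are_zero(self, toy_model, toy_sequence):
        out = toy_model.forward_sequence(toy_sequence)
        ranking = rank_joints(normalize(cam(out, toy_model, out.predicted_class)))
        spec = PerturbationSpec(radius_m=0.1, n_replicates=3, seed=2)
        assert pgi(toy_model, toy_sequence, ranking, 0, spec) == 0.0
        assert pgu(toy_model, toy_sequence, ranking, 25, spec) == 0.0

    def test_full_set_identities(self, toy_model, toy_sequence):
        """PGI at k=V and PGU at k=0 perturb the same (full) joint set, so
        with a shared spec they are equal exactly."""
        out = toy_model.forward_sequence(toy_sequence)
        ranking = rank_joints(normalize(cam(out, toy_model, out.predicted_class)))
        spec = PerturbationSpec(radius_m=0.05, n_replicates=4, seed=5)
        a = pgi(toy_model, toy_sequence, ranking, 25, spec)
        b = pgu(toy_model, toy_sequence, ranking, 0, spec)
        assert a == b and a > 0

    def test_pgu_matches_bruteforce(self, toy_model, toy_sequence):
        out = toy_model.forward_sequence(toy_sequence)
        c = out.predicted_class
        ranking = rank_joints(normalize(cam(out, toy_model, c)))
        k = 20
        spec = PerturbationSpec(radius_m=0.1, n_replicates=10, seed=4)
        got = pgu(toy_model, toy_sequence, ranking, k, spec)
        complement = set(range(25)) - set(ranking.order[:k])
        gaps = []
        for i in range(10):
            seq_p = perturb_joints(toy_sequence, complement, 0.1, derive_seed(4, i))
            gaps.append(abs(out.probs[c] - toy_model.forward_sequence(seq_p).probs[c]))
        assert got == pytest.approx(sum(gaps) / 10, abs=1e-12)

    def test_values_in_unit_interval(self, toy_model, toy_sequence):
        out = toy_model.forward_sequence(toy_sequence)
        ranking = rank_joints(normalize(cam(out, toy_model, out.predicted_class)))
        spec = PerturbationSpec(radius_m=0.8, n_replicates=5, seed=6)
        for k in (1, 10, 25):
            assert 0.0 <= pgi(toy_model, toy_sequence, ranking, k, spec) <= 1.0
            assert 0.0 <= pgu(toy_model, toy_sequence, ranking, k, spec) <= 1.0


class TestRelativeStability:
    def test_identical_explanations_give_zero(self):
        config = MetricConfig()
        e = np.array([0.5, 1.0])
        assert relative_stability(e, e, np.ones(2), np.full(2, 0.9), config) == 0.0

    def test_hand_arithmetic_example(self):
        config = MetricConfig()
        # numerator ||(0.5, 0)||_2 = 0.5; denominator relative change 0.1
        val = relative_stability(
            np.array([0.5, 1.0]), np.array([0.25, 1.0]),
            np.array([1.0]), np.array([0.9]), config,
        )
        assert val == pytest.approx(5.0, rel=1e-6)

    def test_unchanged_payload_floors_at_eps_min(self):
        config = MetricConfig(eps_min=1e-6)
        e0, e1 = np.array([0.5, 1.0]), np.array([0.25, 1.0])
        payload = np.array([2.0, 3.0])
        val = relative_stability(e0, e1, payload, payload.copy(), config)
        num = np.linalg.norm((e0 - e1) / (e0 + config.eps_div))
        assert val == pytest.approx(num / 1e-6, rel=1e-9)

    def test_scale_invariance_of_percent_change_numerator(self):
        config = MetricConfig()
        rng = np.random.default_rng(2)
        e0 = rng.uniform(0.1, 1.0, size=(4, 5))
        e1 = e0 + rng.normal(0, 0.05, size=(4, 5))
        pay0, pay1 = np.ones(3), np.full(3, 1.1)
        a = relative_stability(e0, e1, pay0, pay1, config)
        b = relative_stability(100 * e0, 100 * e1, pay0, pay1, config)
        assert b == pytest.approx(a, rel=1e-5)

    def test_all_zero_explanation_rejected(self):
        with pytest.raises(DegenerateExplanationError):
            relative_stability(
                np.zeros(3), np.ones(3), np.ones(3), np.ones(3), MetricConfig()
            )


class TestStabilitySuite:
    def test_zero_radius_gives_all_zero(self, trained_model, eval_data):
        config = MetricConfig(seed=3)
        spec = PerturbationSpec(radius_m=0.0, n_replicates=3, seed=1)
        for method in ("cam", "gradcam", "random"):
            res = stability_suite(trained_model, eval_data[0], method, spec, config)
            assert res.n_admitted == 3
            assert all(v == 0.0 for v in res.values.values())

    def test_matches_bruteforce_loop(self, trained_model, eval_data):
        """All five stability values equal a from-scratch loop implementing
        the max-over-replicates ratio with explicit norms."""
        seq = eval_data[1]
        config = MetricConfig(seed=3)
        spec = PerturbationSpec(radius_m=0.025, n_replicates=10, seed=7)
        got = stability_suite(trained_model, seq, "cam", spec, config)

        def rel_norm(a, b):
            return np.linalg.norm(((a - b) / (a + config.eps_div)).ravel())

        b0 = compute_branches(seq, trained_model.graph)
        out0 = trained_model.forward_sequence(seq)
        c = out0.predicted_class
        e0 = _explain_seq(trained_model, seq, out0, "cam", config).scores
        best = {m: -np.inf for m in STABILITY_METRICS}
        admitted = 0
        for i in range(10):
            sp = perturb_joints(seq, range(25), 0.025, derive_seed(7, i))
            bp = compute_branches(sp, trained_model.graph)
            op = trained_model.forward_sequence(sp)
            if op.predicted_class != c:
                continue
            admitted += 1
            ep = _explain_seq(trained_model, sp, op, "cam", config, class_id=c).scores
            num = rel_norm(e0, ep)
            payloads = {
                "RISj": (b0.joint, bp.joint),
                "RISv": (b0.velocity, bp.velocity),
                "RISb": (b0.bone, bp.bone),
                "ROS": (np.array([out0.probs[c]]), np.array([op.probs[c]])),
                "RRS": (out0.logits, op.logits),
            }
            for m, (pa, pb) in payloads.items():
                den = max(rel_norm(pa, pb), config.eps_min)
                best[m] = max(best[m], num / den)
        assert admitted == got.n_admitted
        for m in STABILITY_METRICS:
            assert got.values[m] == pytest.approx(best[m], rel=1e-12)

    def test_label_preservation_filter_reported(self, trained_model, eval_data):
        config = MetricConfig(seed=3, label_preserving_only=True)
        spec = PerturbationSpec(radius_m=0.8, n_replicates=10, seed=2)
        res = stability_suite(trained_model, eval_data[0], "cam", spec, config)
        assert 0 <= res.n_admitted <= 10
        if res.n_admitted == 0:
            assert all(np.isnan(v) for v in res.values.values())
        else:
            assert all(v >= 0 for v in res.values.values())


class TestAucOverK:
    def test_constant_curve_returns_constant(self):
        assert auc_over_k([0.7] * 25) == pytest.approx(0.7)

    def test_single_trapezoid(self):
        assert auc_over_k([0.0, 1.0], k_values=[1, 2]) == pytest.approx(0.5)

    def test_matches_independent_trapezoid(self):
        rng = np.random.default_rng(3)
        vals = rng.random(25)
        k = np.arange(1, 26)
        expected = sum(
            (vals[i] + vals[i + 1]) / 2 * (k[i + 1] - k[i]) for i in range(24)
        ) / (k[-1] - k[0])
        assert auc_over_k(vals) == pytest.approx(expected, rel=1e-12)

    def test_needs_two_points(self):
        with pytest.raises(ValueError, match="two"):
            auc_over_k([1.0])


class TestEvaluateClass:
    def test_single_instance_has_zero_std(self, trained_model, eval_data):
        config = MetricConfig(
            k_values=(1, 13, 25), radius_grid_m=(0.025,), n_replicates=10, seed=1
        )
        ev = evaluate_class(trained_model, eval_data[:1], "cam", config)
        for res in ev.results:
            assert res.n_instances == 1
            assert res.std == 0.0

    def test_zero_radius_gives_zero_faithfulness(self, trained_model, eval_data):
        config = MetricConfig(
            k_values=(1, 25), radius_grid_m=(0.0,), n_replicates=1, seed=1
        )
        ev = evaluate_class(trained_model, eval_data[:2], "cam", config)
        assert ev.get("PGI", 0.0).mean == 0.0
        assert ev.get("PGU", 0.0).mean == 0.0

    def test_frame_has_all_metric_radius_rows(self, trained_model, eval_data):
        config = MetricConfig(
            k_values=(1, 25), radius_grid_m=(0.025, 0.1), n_replicates=2, seed=1
        )
        ev = evaluate_class(trained_model, eval_data[:2], "random", config)
        frame = ev.to_frame()
        assert len(frame) == 7 * 2  # 7 metrics × 2 radii
        assert set(frame["metric"]) == {"PGI", "PGU", *STABILITY_METRICS}
        assert "mean" in frame and "ci95" in frame
        assert len(ev.summary().splitlines()) == len(frame) + 1

    def test_per_k_stability_mode_runs(self, trained_model, eval_data):
        config = MetricConfig(
            k_values=(1, 25), radius_grid_m=(0.025,), n_replicates=2,
            stability_per_k=True, seed=1,
        )
        ev = evaluate_class(trained_model, eval_data[:2], "cam", config)
        assert np.isfinite(ev.get("RISj", 0.025).mean)
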