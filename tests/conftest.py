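"""Shared fixtures: graphs, synthetic datasets, and trained surrogates.

Heavy objects (trained models, evaluation datasets) are session-scoped so
the whole suite trains each model configuration exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from skelxai import (
    MotionClassSpec,
    SkeletonGraph,
    SkeletonSequence,
    default_class_specs,
    generate_dataset,
    ntu_graph,
    train_surrogate,
)


@pytest.fixture(scope="session")
def graph() -> SkeletonGraph:
    return ntu_graph()


@pytest.fixture(scope="session")
def class_specs() -> list[MotionClassSpec]:
    return default_class_specs(4, noise_sd_m=0.01)


@pytest.fixture(scope="session")
def train_data(class_specs, graph):
    return generate_dataset(class_specs, 50, 64, graph, seed=7)


@pytest.fixture(scope="session")
def eval_data(class_specs, graph):
    """Held-out evaluation set: 20 instances per class, independent seed."""
    return generate_dataset(class_specs, 20, 64, graph, seed=101)


@pytest.fixture(scope="session")
def trained_model(train_data):
    model = train_surrogate(train_data, epochs=300, learning_rate=0.5, seed=7)
    assert model.train_accuracy is not None and model.train_accuracy > 0.9
    return model


@pytest.fixture
def chain3_graph() -> SkeletonGraph:
    """3-joint chain 0-1-2 rooted at joint 0 for hand-checkable arithmetic."""
    return SkeletonGraph(
        joint_count=3,
        edges=((0, 1), (1, 2)),
        parent=(0, 0, 1),
        joint_names=("root", "mid", "tip"),
    )


@pytest.fixture
def random_sequence(graph):
    rng = np.random.default_rng(42)
    return SkeletonSequence(
        coords=rng.normal(0.0, 0.3, size=(10, graph.joint_count, 3)),
        label=0,
        instance_id="rand10",
    )
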