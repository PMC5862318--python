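import numpy as np
import pandas as pd
import pytest

from unprofit import CohortConfig, generate_cohort, generate_vocabulary
from unprofit.cohort import DrugVocabulary


@pytest.fixture(scope="session")
def default_vocab():
    return generate_vocabulary(CohortConfig())


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete cohort for fast pipeline tests."""
    return CohortConfig(
        n=400, seed=5, n_classes=12, n_groups=3, n_generic=4, n_maintenance=3,
        class_prevalences=np.linspace(0.3, 0.05, 12),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    vocab = generate_vocabulary(small_config)
    table = generate_cohort(vocab, small_config)
    return table


@pytest.fixture
def toy_vocab():
    """Hand-built vocabulary: one singleton group, two multi-class groups."""
    classes = [f"c{i}" for i in range(1, 11)]
    group_of = {"c1": "g1"}
    for c in classes[1:5]:
        group_of[c] = "g2"
    for c in classes[5:]:
        group_of[c] = "g3"
    return DrugVocabulary(
        class_ids=tuple(classes),
        group_of=group_of,
        generic_flags=("gx_a", "gx_b"),
        maintenance_flags=("mx_a",),
        forced_ids=("c4",),
        generic_of={c: ("gx_a" if i % 2 else "gx_b") for i, c in enumerate(classes)},
        maintenance_of={c: "mx_a" for c in classes},
    )


def build_table_from_indicators(vocab, class_matrix, costs=None, risks=None):
    """Assemble a valid EnrolleeTable from a class-indicator matrix."""
    from unprofit.cohort import EnrolleeTable

    n = class_matrix.shape[0]
    frame = pd.DataFrame(
        {
            "id": np.arange(n),
            "cost": costs if costs is not None else np.full(n, 100.0),
            "risk_score": risks if risks is not None else np.ones(n),
        }
    )
    for j, c in enumerate(vocab.class_ids):
        frame[c] = class_matrix[:, j].astype(np.int8)
    for g in vocab.group_ids:
        members = list(vocab.classes_in_group(g))
        frame[g] = frame[members].to_numpy().max(axis=1)
    for flags, mapping in (
        (vocab.generic_flags, vocab.generic_of),
        (vocab.maintenance_flags, vocab.maintenance_of),
    ):
        for f in flags:
            members = [c for c in vocab.class_ids if mapping[c] == f]
            frame[f] = frame[members].to_numpy().max(axis=1) if members else 0
    return EnrolleeTable(frame=frame, vocab=vocab)
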