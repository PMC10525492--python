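"""Shared fixtures: small synthetic cohorts and (session-scoped) trained
models reused by the model, interpretability and acceptance tests."""

import warnings

import numpy as np
import pytest

from ictalkit.experiments import preprocess_cohort
from ictalkit.preprocessing import SplitSpec, class_weights, make_splits
from ictalkit.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Four 80 s subjects, three seizures each — quick but label-diverse."""
    cfg = CohortConfig(n_subjects=4, record_duration_s=80.0,
                       seizures_per_record=3, seed=7)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    _, cohort = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        windows, tensors, labels = preprocess_cohort(cohort)
    return windows, tensors, labels


@pytest.fixture(scope="session")
def default_cohort_data():
    """The generator's default study conditions (12 subjects, 5 seizures)."""
    cfg = CohortConfig(seed=0)
    cohort = simulate_cohort(cfg)
    windows, tensors, labels = preprocess_cohort(cohort)
    return cfg, cohort, windows, tensors, labels


@pytest.fixture(scope="session")
def trained_binary(default_cohort_data):
    """Binary detector trained on the default cohort (held-out eval split)."""
    from ictalkit.models import TrainingConfig, build_binary_cnn, train_model

    _, _, windows, tensors, labels = default_cohort_data
    yb = ["bckg" if l == "bckg" else "seiz" for l in labels]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tr, va, te = make_splits(windows, SplitSpec(seed=0))
    ev = sorted(va + te)
    model = build_binary_cnn((21, 33, 8), seed=0)
    tcfg = TrainingConfig(epochs=8, seed=0,
                          class_weights=class_weights([yb[i] for i in tr]))
    train_model(model, (tensors[tr], [yb[i] for i in tr]), None, tcfg)
    return model, tensors, yb, ev


@pytest.fixture(scope="session")
def trained_multigroup(default_cohort_data):
    """8-class typer trained on the default cohort's seizure windows."""
    from ictalkit.models import TrainingConfig, build_multigroup_model, train_model

    _, _, windows, tensors, labels = default_cohort_data
    sz = [i for i, l in enumerate(labels) if l != "bckg"]
    szw = [windows[i] for i in sz]
    szy = [labels[i] for i in sz]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tr, va, te = make_splits(szw, SplitSpec(seed=0))
    ev = sorted(va + te)
    model = build_multigroup_model((21, 33, 8), seed=0)
    tcfg = TrainingConfig(epochs=10, seed=0,
                          class_weights=class_weights([szy[i] for i in tr]))
    train_model(model, (tensors[sz][tr], [szy[i] for i in tr]), None, tcfg)
    return model, tensors[sz], szy, ev
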