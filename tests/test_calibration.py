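"""Threshold calibration: balanced accuracy and the threshold search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afs.calibration import (
    balanced_accuracy,
    best_threshold,
    calibrate,
    infer_thresholds,
    train_calibration_model,
    ThresholdSet,
)
from afs.metrics import MetricMatrix
from afs.models import ModelSpec
from afs.simulate import gen_gaussian_blobs
from afs.training import TrainConfig, evaluate_accuracy

from conftest import FAST_CONFIG


def make_matrix(labels, conf, ent, corr=None):
    labels = np.asarray(labels)
    n = len(labels)
    return MetricMatrix(
        np.arange(n), labels,
        np.asarray(corr if corr is not None else np.ones(n), dtype=np.int8),
        np.asarray(conf, dtype=float), np.asarray(ent, dtype=float),
    )


@pytest.mark.parametrize("t,members,nons,direction,expected", [
    (0.5, [0.9, 0.8], [0.1, 0.2], "ge", 1.0),
    (0.45, [0.9, 0.4], [0.5, 0.1], "ge", 0.5),   # brute-force count on 4 values
    (0.5, [0.1, 0.2], [0.9, 0.8], "le", 1.0),
])
def test_balanced_accuracy_counting(t, members, nons, direction, expected):
    assert balanced_accuracy(t, members, nons, direction) == pytest.approx(expected)


def test_balanced_accuracy_validates_inputs():
    with pytest.raises(ValueError, match="non-empty"):
        balanced_accuracy(0.5, [], [0.1], "ge")
    with pytest.raises(ValueError, match="direction"):
        balanced_accuracy(0.5, [0.1], [0.2], "up")


def test_identical_distributions_cap_at_half():
    scores = [0.1, 0.4, 0.7]
    _, ba = best_threshold(scores, scores, "ge")
    assert ba == pytest.approx(0.5)


def test_perfect_separation_reaches_one():
    t, ba = best_threshold([0.8, 0.9], [0.1, 0.2], "ge")
    assert ba == 1.0
    assert 0.2 < t < 0.8


def _oracle_best_threshold(members, nonmembers, direction):
    """Exhaustive loop over midpoint candidates with exact rational
    balanced accuracy (independent oracle)."""
    from fractions import Fraction

    members = np.asarray(members, dtype=float)
    nonmembers = np.asarray(nonmembers, dtype=float)
    pooled = np.unique(np.concatenate([members, nonmembers]))
    cands = [pooled[0] - 1.0]
    cands += [(a + b) / 2 for a, b in zip(pooled[:-1], pooled[1:])]
    cands += [pooled[-1] + 1.0]
    best_t, best_ba = None, Fraction(-1)
    for t in cands:
        if direction == "ge":
            tp = int((members >= t).sum())
            tn = int((nonmembers < t).sum())
        else:
            tp = int((members <= t).sum())
            tn = int((nonmembers > t).sum())
        ba = (Fraction(tp, len(members)) + Fraction(tn, len(nonmembers))) / 2
        if ba > best_ba:  # strict: first (smallest) maximiser kept
            best_t, best_ba = t, ba
    return best_t, float(best_ba)


@settings(max_examples=200, deadline=None)
@given(st.integers(0, 10_000), st.sampled_from(["ge", "le"]))
def test_threshold_search_matches_exhaustive_oracle(seed, direction):
    rng = np.random.default_rng(seed)
    m = rng.normal(rng.uniform(-1, 1), 1.0, size=rng.integers(1, 50))
    nm = rng.normal(rng.uniform(-1, 1), 1.0, size=rng.integers(1, 50))
    if rng.random() < 0.3:  # exercise ties
        m = np.round(m, 1)
        nm = np.round(nm, 1)
    t, ba = best_threshold(m, nm, direction)
    t_o, ba_o = _oracle_best_threshold(m, nm, direction)
    assert ba == pytest.approx(ba_o)
    assert t == pytest.approx(t_o)
    # returned threshold is at least as good as any other candidate
    assert ba >= balanced_accuracy(float(np.median(np.concatenate([m, nm]))),
                                   m, nm, direction) - 1e-12


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 10_000))
def test_balanced_accuracy_invariant_to_monotone_rescaling(seed):
    rng = np.random.default_rng(seed)
    m = rng.normal(0.5, 1.0, size=20)
    nm = rng.normal(-0.5, 1.0, size=20)
    _, ba = best_threshold(m, nm, "ge")
    _, ba_scaled = best_threshold(np.exp(m), np.exp(nm), "ge")
    assert ba == pytest.approx(ba_scaled)


def test_infer_thresholds_per_class_and_fallback():
    # class 0 populated on both sides; class 1 only among members -> fallback
    labels_m = [0] * 6 + [1] * 6
    labels_n = [0] * 6
    conf_m = [0.9] * 6 + [0.8] * 6
    conf_n = [0.1] * 6
    ent_m = [0.1] * 12
    ent_n = [2.0] * 6
    ts = infer_thresholds(make_matrix(labels_m, conf_m, ent_m),
                          make_matrix(labels_n, conf_n, ent_n), num_classes=2)
    assert 0 in ts.per_class["confidence"]
    assert 1 not in ts.per_class["confidence"]       # falls back
    t0, d0 = ts.resolve("confidence", 0)
    t1, d1 = ts.resolve("confidence", 1)
    assert d0 == d1 == "ge"
    assert 0.1 < t0 < 0.9
    assert t1 == ts.fallback["confidence"]
    # correctness stays a fixed binary vote
    assert ts.resolve("correctness", 0) == (0.5, "ge")
    # entropy member side is "<="
    te, de = ts.resolve("entropy", 0)
    assert de == "le" and 0.1 < te < 2.0


def test_infer_thresholds_requires_data():
    m = make_matrix([0], [0.5], [0.5])
    empty = make_matrix([], [], [])
    with pytest.raises(ValueError, match="non-empty"):
        infer_thresholds(m, empty)


def test_threshold_set_json_roundtrip(tmp_path):
    ts = ThresholdSet({"confidence": {0: 0.7}, "entropy": {}, "correctness": {}},
                      {"correctness": 0.5, "confidence": 0.6, "entropy": 1.0},
                      num_classes=2, provenance={"seed": 1})
    path = tmp_path / "ths.json"
    ts.to_json(path)
    back = ThresholdSet.from_json(path)
    assert back.resolve("confidence", 0) == (0.7, "ge")
    assert back.resolve("confidence", 1) == (0.6, "ge")
    assert back.provenance == {"seed": 1}


def test_calibration_model_trains_and_is_seeded():
    data = gen_gaussian_blobs(200, 3, 10, 6.0, seed=0)
    a = train_calibration_model(ModelSpec("mlp", 3, (10,), hidden=(32,)), data,
                                FAST_CONFIG, seed=0)
    b = train_calibration_model(ModelSpec("mlp", 3, (10,), hidden=(32,)), data,
                                FAST_CONFIG, seed=0)
    assert a.fingerprint == b.fingerprint
    assert evaluate_accuracy(a, data) >= 0.9  # separable blobs are learnable
    untrained = train_calibration_model(
        ModelSpec("mlp", 3, (10,), hidden=(32,)), data,
        TrainConfig(epochs=0, lr=1e-3), seed=0)
    from afs.models import build_model
    assert untrained.fingerprint == build_model(
        ModelSpec("mlp", 3, (10,), hidden=(32,)), 0).fingerprint


def test_calibrate_is_deterministic_and_covers_classes():
    data = gen_gaussian_blobs(300, 3, 10, 6.0, seed=1)
    spec = ModelSpec("mlp", 3, (10,), hidden=(32,))
    a = calibrate(spec, data, FAST_CONFIG, seed=4)
    b = calibrate(spec, data, FAST_CONFIG, seed=4)
    assert a.per_class == b.per_class
    assert a.fallback == b.fallback
    for metric in ("correctness", "confidence", "entropy"):
        for y in range(3):
            t, _ = a.resolve(metric, y)
            assert np.isfinite(t)
    assert a.provenance["cal_train_n"] == 150


def test_calibrate_rejects_tiny_input():
    data = gen_gaussian_blobs(3, 3, 4, 1.0, seed=0)
    with pytest.raises(ValueError, match="at least 2"):
        calibrate(ModelSpec("mlp", 3, (4,)), data.take(np.array([0])), FAST_CONFIG)
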