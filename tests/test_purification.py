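"""Knowledge-purification losses and the audit-guided training loop."""

import numpy as np
import pytest

from afs.data import QueryDataset, QueryMode, build_query, make_splits
from afs.models import ModelSpec, build_model, softmax
from afs.purification import (
    ForgetConfig,
    afs_train,
    forget_loss,
    kd_loss,
    soften,
    total_loss,
)
from afs.simulate import gen_gaussian_blobs
from afs.training import TrainConfig, train_supervised

from conftest import FAST_CONFIG


def test_kd_loss_zero_iff_identical():
    p = np.array([[0.2, 0.8], [0.6, 0.4]])
    assert kd_loss(p, p, T=2.0) == pytest.approx(0.0, abs=1e-12)
    q = np.array([[0.3, 0.7], [0.6, 0.4]])
    assert kd_loss(q, p, T=2.0) > 0


def test_kd_loss_onehot_teacher_uniform_student():
    # KL(one-hot || uniform) over 2 classes at T=1 is ln 2
    student = np.array([[0.5, 0.5]])
    teacher = np.array([[1.0, 0.0]])
    assert kd_loss(student, teacher, T=1.0) == pytest.approx(np.log(2))


def test_kd_loss_temperature_scaling_nonnegative():
    rng = np.random.default_rng(0)
    s_logits = rng.normal(size=(5, 4))
    t_logits = rng.normal(size=(5, 4))
    vals = []
    for T in (1.0, 2.0, 4.0):
        v = kd_loss(soften(softmax(s_logits), T), soften(softmax(t_logits), T), T)
        assert v >= 0
        vals.append(v)
    assert len(set(np.round(vals, 12))) == 3  # T genuinely changes the value


def test_kd_loss_shape_mismatch():
    with pytest.raises(ValueError, match="shape mismatch"):
        kd_loss(np.ones((2, 3)) / 3, np.ones((2, 4)) / 4, T=1.0)


@pytest.mark.parametrize("rows,expected", [
    (np.full((4, 5), 0.2), 0.0),                       # uniform
    (np.eye(5)[[0, 1, 2]], np.log(5)),                 # one-hot
    (np.array([[0.9, 0.1]]),
     np.log(2) + 0.9 * np.log(0.9) + 0.1 * np.log(0.1)),  # = 0.3680
])
def test_forget_loss_entropy_arithmetic(rows, expected):
    assert forget_loss(rows) == pytest.approx(expected, abs=1e-9)


def test_forget_loss_empty_batch():
    with pytest.raises(ValueError, match="empty"):
        forget_loss(np.empty((0, 3)))


@pytest.mark.parametrize("hard,kd,forget,a,b,expected", [
    (1.0, 2.0, 3.0, 0.5, 0.1, 1.8),
    (7.0, 99.0, 99.0, 0.0, 0.0, 7.0),     # reduces to supervised loss
    (1.0, 2.0, 99.0, 0.3, 0.0, 1.3),      # reduces to distillation
])
def test_total_loss_arithmetic(hard, kd, forget, a, b, expected):
    assert total_loss(hard, kd, forget, a, b) == pytest.approx(expected)


def test_soften_validates_and_flattens():
    p = np.array([[0.9, 0.1]])
    s = soften(p, T=2.0)
    assert s[0, 0] < 0.9  # higher temperature flattens
    np.testing.assert_allclose(s.sum(axis=1), 1.0)
    with pytest.raises(ValueError, match="positive"):
        soften(p, T=0.0)


@pytest.fixture(scope="module")
def tiny_study():
    pool = gen_gaussian_blobs(500, 3, 20, 6.0, seed=0)
    splits = make_splits(pool, 200, 100, 100, seed=0)
    spec = ModelSpec("mlp", 3, (20,), hidden=(32,))
    teacher = train_supervised(build_model(spec, 0), splits.train, FAST_CONFIG, 0)
    return splits, spec, teacher


def test_reduction_to_supervised_training(tiny_study):
    """kd_weight=0, beta=0, empty forget set, full retain fraction:
    the update sequence equals plain hard-label training."""
    splits, spec, teacher = tiny_study
    empty = QueryDataset(splits.train.take(np.array([], dtype=np.int64)),
                         QueryMode.QF, 0.0)
    cfg = ForgetConfig(kd_weight=0.0, beta_init=0.0, retain_fraction=1.0,
                       train=TrainConfig(epochs=3, lr=1e-3, batch_size=32))
    ths = _flat_ths()
    student, _ = afs_train(teacher, spec, splits.train, empty, splits.calibration,
                           cfg, seed=9, thresholds=ths)
    ref = train_supervised(build_model(spec, 9), splits.train,
                           cfg.train, seed=9)
    for a, b in zip(student.parameters, ref.parameters):
        np.testing.assert_allclose(a, b, atol=1e-6)


def _flat_ths():
    from afs.calibration import ThresholdSet
    return ThresholdSet({"correctness": {}, "confidence": {}, "entropy": {}},
                        {"correctness": 0.5, "confidence": 0.5, "entropy": 0.5},
                        num_classes=3)


def test_beta_zero_ignores_forget_set(tiny_study):
    """With beta=0 the forget set must not influence the trajectory."""
    splits, spec, teacher = tiny_study
    qf = build_query(splits, "QF", 20, seed=2)
    empty = QueryDataset(splits.train.take(np.array([], dtype=np.int64)),
                         QueryMode.QF, 0.0)
    cfg = lambda: ForgetConfig(beta_init=0.0, retain_fraction=1.0,  # noqa: E731
                               train=TrainConfig(epochs=2, lr=1e-3, batch_size=32))
    ths = _flat_ths()
    # same retain set in both runs: train minus qf in the first call,
    # the precomputed remainder in the second
    from afs.data import retain_set
    ret = retain_set(splits.train, qf)
    with_qf, _ = afs_train(teacher, spec, splits.train, qf, splits.calibration,
                           cfg(), seed=3, thresholds=ths)
    # second run: same data, forget list empty
    without, _ = afs_train(teacher, spec, ret, empty, splits.calibration,
                           cfg(), seed=3, thresholds=ths)
    # ret already excludes qf, so both train on identical data
    for a, b in zip(with_qf.parameters, without.parameters):
        np.testing.assert_allclose(a, b, atol=0)


def test_afs_train_bookkeeping_and_determinism(tiny_study):
    splits, spec, teacher = tiny_study
    qf = build_query(splits, "QF", 20, seed=5)
    cfg = ForgetConfig(retain_fraction=0.5, patience=10_000,
                       train=TrainConfig(epochs=4, lr=1e-3, batch_size=32))
    ths = _flat_ths()
    s1, t1 = afs_train(teacher, spec, splits.train, qf, splits.calibration,
                       cfg, test=splits.test, seed=1, thresholds=ths)
    s2, t2 = afs_train(teacher, spec, splits.train, qf, splits.calibration,
                       cfg, test=splits.test, seed=1, thresholds=ths)
    assert s1.fingerprint == s2.fingerprint
    assert len(t1) == 4  # one record per epoch, no early stop
    assert t1.p_value == t2.p_value
    assert all(0.0 <= p <= 1.0 for p in t1.p_value)
    assert all(b >= 0 for b in t1.beta)
    assert t1.stop_reason == "completed"


def test_afs_train_early_stop(tiny_study):
    """A forgettable query plus a permissive accuracy budget stops early."""
    splits, spec, teacher = tiny_study
    qf = build_query(splits, "QF", 30, seed=6)
    cfg = ForgetConfig(retain_fraction=0.5, patience=1, accuracy_budget=1.0,
                       target_p=1.1,  # any p counts as forgotten
                       train=TrainConfig(epochs=10, lr=1e-3, batch_size=32))
    _, trace = afs_train(teacher, spec, splits.train, qf, splits.calibration,
                         cfg, test=splits.test, seed=1, thresholds=_flat_ths())
    assert len(trace) == 1
    assert "audit p <=" in trace.stop_reason


def test_afs_train_validates_class_counts(tiny_study):
    splits, spec, teacher = tiny_study
    qf = build_query(splits, "QF", 10, seed=0)
    bad_spec = ModelSpec("mlp", 4, (20,), hidden=(8,))
    with pytest.raises(ValueError, match="class-count"):
        afs_train(teacher, bad_spec, splits.train, qf, splits.calibration,
                  ForgetConfig(), thresholds=_flat_ths())


def test_forget_config_validation():
    with pytest.raises(ValueError, match="kd_weight"):
        ForgetConfig(kd_weight=1.5)
    with pytest.raises(ValueError, match="temperature"):
        ForgetConfig(temperature=-1.0)
    with pytest.raises(ValueError, match="retain_fraction"):
        ForgetConfig(retain_fraction=0.0)
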