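"""Shared fixtures.

The heavy session fixtures run the reference blob study once per
replicate seed (five replicates, matching the averaged-replicate
protocol) and are shared between the property tests and the acceptance
tests: a memorising teacher, calibrated thresholds, member/non-member
audits, a purity sweep, and the forgetting comparison runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from afs.audit import audit_metric_matrix
from afs.baselines import train_independent
from afs.calibration import ThresholdSet, calibrate
from afs.data import build_query
from afs.metrics import metric_matrix
from afs.models import build_model
from afs.purification import ForgetConfig, afs_train
from afs.simulate import blob_study
from afs.training import TrainConfig, evaluate_accuracy, train_supervised

SEEDS = (0, 1, 2, 3, 4)
QUERY_N = 200
QF_N = 100

#: small, fast protocol for unit tests that only need *a* trained model
FAST_CONFIG = TrainConfig(epochs=5, lr=1e-3, batch_size=32)


@pytest.fixture(scope="session")
def studies():
    return {s: blob_study(s) for s in SEEDS}


@pytest.fixture(scope="session")
def teachers(studies):
    out = {}
    for s, st in studies.items():
        model = build_model(st.teacher_spec, s)
        out[s] = train_supervised(model, st.splits.train, st.train_config, s)
    return out


@pytest.fixture(scope="session")
def thresholds(studies) -> dict[int, ThresholdSet]:
    return {
        s: calibrate(st.student_spec, st.splits.calibration, st.train_config, seed=s)
        for s, st in studies.items()
    }


def audit_p(model, data, ths) -> float:
    return audit_metric_matrix(metric_matrix(model, data), ths).p_value


@pytest.fixture(scope="session")
def member_nonmember_audits(studies, teachers, thresholds):
    """p-values for size-200 member (QO) and non-member (QNO) queries."""
    out = {}
    for s, st in studies.items():
        qo = build_query(st.splits, "QO", QUERY_N, seed=s)
        qno = build_query(st.splits, "QNO", QUERY_N, seed=s)
        out[s] = {
            "p_member": audit_p(teachers[s], qo.data, thresholds[s]),
            "p_nonmember": audit_p(teachers[s], qno.data, thresholds[s]),
        }
    return out


PURITY_GRID = (1.0, 0.75, 0.5, 0.25, 0.0)


@pytest.fixture(scope="session")
def purity_audits(studies, teachers, thresholds):
    """Audit p per purity k, per replicate seed (mixed QM queries)."""
    out = {}
    for s, st in studies.items():
        out[s] = {}
        for k in PURITY_GRID:
            qm = build_query(st.splits, "QM", QUERY_N, k=k, seed=1000 + s)
            out[s][k] = audit_p(teachers[s], qm.data, thresholds[s])
    return out


@pytest.fixture(scope="session")
def forgetting_runs(studies, teachers, thresholds):
    """Per seed: forget-set audits and held-out accuracy for the teacher,
    the audit-guided student, the no-audit ablation, and the independent
    student retrained at the same retain fraction."""
    out = {}
    for s, st in studies.items():
        sp = st.splits
        qf = build_query(sp, "QF", QF_N, seed=s)
        ths = thresholds[s]
        afs_cfg = ForgetConfig(retain_fraction=0.5)
        student, trace = afs_train(
            teachers[s], st.student_spec, sp.train, qf, sp.calibration,
            afs_cfg, test=sp.test, seed=s, thresholds=ths,
        )
        abl_cfg = ForgetConfig(retain_fraction=0.5, beta_init=0.0)
        ablation, _ = afs_train(
            teachers[s], st.student_spec, sp.train, qf, sp.calibration,
            abl_cfg, test=sp.test, seed=s, thresholds=ths,
        )
        independent = train_independent(
            st.student_spec, sp.train, k=0.5, exclude=qf, seed=s,
            config=st.train_config,
        )
        out[s] = {
            "qf": qf,
            "p_teacher": audit_p(teachers[s], qf.data, ths),
            "p_afs": audit_p(student, qf.data, ths),
            "p_ablation": audit_p(ablation, qf.data, ths),
            "p_independent": audit_p(independent, qf.data, ths),
            "acc_afs": evaluate_accuracy(student, sp.test),
            "acc_ablation": evaluate_accuracy(ablation, sp.test),
            "acc_independent": evaluate_accuracy(independent, sp.test),
            "trace": trace,
            "student": student,
        }
    return out


def mean_over_seeds(results: dict, key) -> float:
    return float(np.mean([results[s][key] for s in results]))
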