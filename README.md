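# afs-unlearn

**Audit-to-forget for classifiers**: decide whether a query dataset was
used to train a model (dataset-level membership auditing), and make a
model forget a query dataset without full retraining (audit-guided
knowledge purification).

The package is aimed at practitioners who hold a trained classifier and
must answer data-revocation requests: *was this patient cohort in the
training set?* and, if so, *produce a model that no longer carries its
information, at acceptable utility cost*.

## The method

**Auditing.** For each query sample \(x\) with label \(y\), a target
model \(F\) yields three membership signals:

- correctness: \(\mathbb{1}\{\arg\max_i F(x)_i = y\}\),
- confidence: \(F(x)_y\), member side \(\ge \tau_y\),
- entropy: \(-\sum_i F(x)_i \ln F(x)_i\), member side \(\le \hat\tau_y\).

The per-class thresholds \(\tau_y, \hat\tau_y\) are calibrated on a
*calibration dataset* disjoint from training: half of it trains a shadow
model with known members/non-members, and each threshold maximises the
balanced accuracy \((\mathrm{TPR}(t)+\mathrm{TNR}(t))/2\) between the
two score populations. A sample votes "member" if **at least one**
signal lands on its member side. The dataset-level verdict is the
two-tailed pooled two-sample *t*-test (df \(=2N-2\)) comparing the vote
vector with an all-one vector: large *p* means the votes are
indistinguishable from full membership; small *p* denies membership.

**Forgetting.** Knowledge purification trains a smaller student from
the teacher on a fraction *k* of the retain set with the loss

\[
\mathcal{L} = (1-\alpha_{KD})\,\mathcal{L}_{hard}
 + \alpha_{KD}\,\mathcal{L}_{KD}^{(T)}
 + \beta\,\bigl(\ln C - \bar H_{QF}\bigr),
\]

where the last term pushes the student toward maximal uncertainty on
the forget set QF. After every epoch the forget set is audited on the
current student; \(\beta\) grows while the audit still calls QF
member-like and relaxes once it does not — a negative-feedback loop
that spends forgetting pressure only when needed.

Baselines for comparison: independent retraining at fraction *k* with
QF excluded, SISA sharded unlearning (only affected shards retrain),
and CF-k / EU-k (fine-tune or re-initialise only the last *k* parameter
groups).

Models are small numpy networks (MLP, small CNN) trained with Adam via
manual backprop; the registry also carries the standard ResNet-18/34
layer plans (11,177,538 / 21,285,698 trainable parameters with a
2-class head) for parameter accounting and inference.

## Worked example

```python
from afs import *
from afs.simulate import blob_study
from afs.models import build_model
from afs.training import train_supervised, evaluate_accuracy
from afs.calibration import calibrate
from afs.metrics import metric_matrix
from afs.audit import audit_metric_matrix

study = blob_study(seed=0)                 # 5-class blobs, 1000 train samples
sp = study.splits
teacher = train_supervised(build_model(study.teacher_spec, 0),
                           sp.train, study.train_config, seed=0)
print(evaluate_accuracy(teacher, sp.train), evaluate_accuracy(teacher, sp.test))
# 1.0 0.616   <- memorised training set, modest generalisation

ths = calibrate(study.student_spec, sp.calibration, study.train_config, seed=0)
qo = build_query(sp, "QO", 200, seed=0)    # 200 training members
qno = build_query(sp, "QNO", 200, seed=0)  # 200 held-out non-members
print(audit_metric_matrix(metric_matrix(teacher, qo.data), ths).p_value)
# 1.0             <- member-like: every sample votes member
print(audit_metric_matrix(metric_matrix(teacher, qno.data), ths).p_value)
# 6.27e-11        <- membership denied

qf = build_query(sp, "QF", 100, seed=0)    # 100 training samples to forget
student, trace = afs_train(teacher, study.student_spec, sp.train, qf,
                           sp.calibration, ForgetConfig(retain_fraction=0.5),
                           test=sp.test, seed=0, thresholds=ths)
print(audit_metric_matrix(metric_matrix(student, qf.data), ths).p_value)
# 2.74e-28        <- QF audits as non-member on the purified student
```

The audit p-value on QF drops from 1.0 (teacher) to ~1e-28 (purified
student), below the no-audit distillation ablation (~1e-20), while the
student's held-out accuracy stays within the budget of an independent
student retrained on the same data fraction.

The same workflow is available from the shell:

```bash
afs simulate blobs --out train.csv --n 1000 --seed 0
afs train  --data train.csv --out teacher.npz
afs audit  --model teacher.npz --query query.csv --calibration cal.csv --out report.json
afs forget --teacher teacher.npz --train-data train.csv \
           --forget-data qf.csv --calibration cal.csv --k 0.5 --out-dir run/
```

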