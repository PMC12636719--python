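"""Training (cross-entropy on slide labels) and the evaluation surfaces:
per-task AUROC, sensitivity by circulating-blast bin, and the count-only
cytometry baseline.

Bags have unequal cell counts, so "batching" is gradient accumulation over
bags processed one at a time; there is no padding. Model selection uses
validation macro AUROC, the reported metric, rather than loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._tensor import Tensor
from .aggregators import AggregatorConfig
from .bags import CellBag, CohortSplit, SlideRecord, composition_vector
from .gated import GatedMilConfig, GatedMilModel, gated_forward, gated_predict_proba
from .model import CaremilConfig, CaremilModel, forward, predict_proba

__all__ = ["TrainConfig", "TaskSpec", "BlastBinTable", "train_model",
           "evaluate_auroc", "auroc", "sensitivity_by_blast_bin",
           "cytometry_baseline", "BLAST_BINS"]


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_bags_per_step: int = 8
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    class_weighting: bool = True
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.epochs <= 0 or self.learning_rate < 0:
            raise ValueError("epochs must be positive and learning_rate nonnegative")
        if self.early_stop_patience < 0:
            raise ValueError("patience must be >= 0")


@dataclass
class TaskSpec:
    """A classification task over a subset of diagnosis labels.

    ``classes`` is the ordered label set; records with other labels are
    ignored. For binary tasks the last class is treated as the positive
    (disease-probability) class by :func:`disease_probability`.
    """

    name: str
    classes: Sequence[str]

    def __post_init__(self):
        self.classes = tuple(self.classes)
        if len(self.classes) < 2:
            raise ValueError("a task needs at least two classes")

    def filter(self, records: Sequence[SlideRecord]) -> list:
        return [r for r in records if r.label in self.classes]

    def target(self, record: SlideRecord) -> int:
        return self.classes.index(record.label)


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUROC via the Mann-Whitney rank statistic; ties contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: need at least one positive and one negative")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _proba_fn(model) -> Callable[[CellBag], np.ndarray]:
    if isinstance(model, CaremilModel):
        return lambda bag: predict_proba(model, bag)
    if isinstance(model, GatedMilModel):
        return lambda bag: gated_predict_proba(model, bag)
    if callable(model):
        return model
    raise TypeError(f"cannot evaluate object of type {type(model).__name__}")


def evaluate_auroc(model, records: Sequence[SlideRecord], task: TaskSpec) -> Dict:
    """One-vs-rest AUROC per class plus the macro average."""
    recs = task.filter(records)
    fn = _proba_fn(model)
    probs = np.array([fn(r.bag) for r in recs])
    targets = np.array([task.target(r) for r in recs])
    per_class = {}
    for i, cls in enumerate(task.classes):
        y = (targets == i).astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError(f"AUROC undefined for class {cls!r}: one-class input")
        per_class[cls] = auroc(probs[:, i], y)
    return {"per_class": per_class, "macro": float(np.mean(list(per_class.values())))}


def disease_probability(model, records: Sequence[SlideRecord], task: TaskSpec) -> np.ndarray:
    """P(last task class) per record — the disease probability for binary tasks."""
    fn = _proba_fn(model)
    return np.array([fn(r.bag)[len(task.classes) - 1] for r in records])


# ---------------------------------------------------------------------------
# Optimizer + training loop
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: Dict[str, Tensor], lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _cross_entropy(logits: Tensor, target: int, weight: float) -> Tensor:
    shifted = logits - Tensor(logits.data.max())
    lse = shifted.exp().sum().log()
    return (lse - shifted[target]) * weight


def _forward_dispatch(arch: str):
    if arch == "caremil":
        return forward
    if arch == "gated":
        return gated_forward
    raise ValueError(f"unknown architecture {arch!r}; expected 'caremil' or 'gated'")


def _default_model(arch: str, D: int, n_classes: int, seed: int, model_config=None):
    if model_config is not None:
        return CaremilModel(model_config) if arch == "caremil" else GatedMilModel(model_config)
    if arch == "caremil":
        return CaremilModel(CaremilConfig(D=D, n_classes=n_classes, seed=seed))
    return GatedMilModel(GatedMilConfig(D=D, n_classes=n_classes, seed=seed))


def train_model(arch: str, split: CohortSplit, task: TaskSpec, tcfg: TrainConfig,
                model_config=None):
    """Train a CAREMIL or gated-MIL model on the split's train partition.

    Returns ``(model, history)`` where the model carries the parameters of
    the epoch with the best validation macro AUROC and ``history`` is a
    DataFrame with per-epoch train loss and validation AUROC. Deterministic
    given the config seed.
    """
    fwd = _forward_dispatch(arch)
    train_recs = task.filter(split.train)
    val_recs = task.filter(split.validation)
    if not train_recs:
        raise ValueError("no training records for this task")
    counts = {c: sum(1 for r in train_recs if r.label == c) for c in task.classes}
    missing = [c for c, n in counts.items() if n == 0]
    if missing:
        raise ValueError(f"task classes absent from the train set: {missing}")

    D = train_recs[0].bag.dim
    model = _default_model(arch, D, len(task.classes), tcfg.seed, model_config)

    if tcfg.class_weighting:
        inv = {c: 1.0 / counts[c] for c in task.classes}
        norm = len(task.classes) / sum(inv.values())
        weights = {c: inv[c] * norm for c in task.classes}
    else:
        weights = {c: 1.0 for c in task.classes}

    rng = np.random.default_rng(tcfg.seed)
    opt = _Adam(model.params, tcfg.learning_rate, tcfg.weight_decay)

    def val_score():
        if not val_recs:
            return float("nan"), float("nan")
        fn = _proba_fn(model)
        losses = []
        for r in val_recs:
            p = fn(r.bag)
            losses.append(-weights[r.label] * math.log(max(p[task.target(r)], 1e-12)))
        try:
            vauc = evaluate_auroc(model, val_recs, task)["macro"]
        except ValueError:
            vauc = float("nan")
        return vauc, float(np.mean(losses))

    # selection: best validation macro AUROC, validation loss as tie-break
    # (AUROC on a small validation set saturates early; the loss keeps
    # discriminating between checkpoints with identical rankings)
    best_auc, best_loss, best_params, best_epoch = -np.inf, np.inf, None, -1
    history = []
    stale = 0
    order = np.arange(len(train_recs))
    for epoch in range(tcfg.epochs):
        rng.shuffle(order)
        epoch_loss = 0.0
        model.zero_grad()
        pending = 0
        for pos, idx in enumerate(order):
            rec = train_recs[idx]
            logits = fwd(model, rec.bag, training=True, rng=rng)[0]
            loss = _cross_entropy(logits, task.target(rec), weights[rec.label])
            epoch_loss += float(loss.data)
            loss.backward()
            pending += 1
            if pending == tcfg.batch_bags_per_step or pos == len(order) - 1:
                for p in model.params.values():
                    if p.grad is not None:
                        p.grad /= pending
                opt.step()
                model.zero_grad()
                pending = 0
        vauc, vloss = val_score()
        history.append({"epoch": epoch, "train_loss": epoch_loss / len(train_recs),
                        "val_auroc": vauc, "val_loss": vloss})
        improved = (not math.isnan(vauc)
                    and (vauc > best_auc + 1e-12
                         or (vauc >= best_auc - 1e-12 and vloss < best_loss - 1e-12)))
        if improved:
            best_auc = max(best_auc, vauc)
            best_loss = vloss
            best_epoch = epoch
            best_params = {k: v.data.copy() for k, v in model.params.items()}
            stale = 0
        else:
            stale += 1
            if stale > tcfg.early_stop_patience:
                break

    if best_params is not None:
        for k, v in model.params.items():
            v.data = best_params[k]
    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# Sensitivity by blast-fraction bin
# ---------------------------------------------------------------------------

# overlapping bins by design: a 0.5% blast case counts in every bin but "high"
BLAST_BINS = (
    ("high", lambda f: f >= 0.20),
    ("low", lambda f: f < 0.20),
    ("very_low", lambda f: f <= 0.10),
    ("extremely_low", lambda f: f <= 0.05),
    ("invisible", lambda f: f <= 0.01),
)


@dataclass
class BlastBinTable:
    rows: list  # dicts with bin, n, n_called, sensitivity, empty
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def sensitivity_by_blast_bin(predictions: Sequence[float], records: Sequence[SlideRecord],
                             cutoff: float = 0.5, normal_label: str = "NL") -> BlastBinTable:
    """Per-bin sensitivity of disease calls (probability >= cutoff).

    ``predictions`` are disease probabilities aligned with ``records``; only
    records with a disease label (not ``normal_label``) enter the table.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    preds = np.asarray(predictions, dtype=float)
    if len(preds) != len(records):
        raise ValueError("predictions and records must be aligned")
    disease = [(p, r) for p, r in zip(preds, records) if r.label != normal_label]
    missing = [r.bag.slide_id for _, r in disease if r.blast_fraction is None]
    if missing:
        raise ValueError(f"disease records missing blast_fraction: {missing}")
    rows = []
    for name, pred in BLAST_BINS:
        members = [(p, r) for p, r in disease if pred(r.blast_fraction)]
        n = len(members)
        called = sum(1 for p, _ in members if p >= cutoff)
        rows.append({"bin": name, "n": n, "n_called": called,
                     "sensitivity": called / n if n else float("nan"),
                     "empty": n == 0})
    return BlastBinTable(rows=rows, cutoff=cutoff)


# ---------------------------------------------------------------------------
# Cytometry baseline
# ---------------------------------------------------------------------------

def cytometry_baseline(split: CohortSplit, task: TaskSpec,
                       vocabulary: Sequence[str],
                       C_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0),
                       seed: int = 0):
    """Multinomial logistic regression on cell-type fractions.

    The classical count-only comparator: it sees the blood differential and
    nothing of cell morphology. Regularization strength is selected on
    validation macro AUROC. Returns ``(predict_fn, test_auroc_dict)`` where
    ``predict_fn(bag) -> class probability vector`` is evaluable exactly like
    the MIL models.
    """
    from sklearn.linear_model import LogisticRegression

    vocab = list(vocabulary)

    def feats(recs):
        X = np.array([composition_vector(r.bag, vocab).as_array(vocab) for r in recs])
        y = np.array([task.target(r) for r in recs])
        return X, y

    train_recs = task.filter(split.train)
    val_recs = task.filter(split.validation)
    test_recs = task.filter(split.test)
    if any(r.bag.cell_types is None for r in train_recs + val_recs + test_recs):
        raise ValueError("cytometry baseline requires cell_types on every bag")
    Xtr, ytr = feats(train_recs)

    def fit(C):
        clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)
        clf.fit(Xtr, ytr)
        return clf

    def as_predict_fn(clf):
        classes = list(clf.classes_)

        def predict_fn(bag: CellBag) -> np.ndarray:
            x = composition_vector(bag, vocab).as_array(vocab)[None, :]
            p = clf.predict_proba(x)[0]
            full = np.zeros(len(task.classes))
            for c, pc in zip(classes, p):
                full[c] = pc
            return full

        return predict_fn

    best_fn, best_auc = None, -np.inf
    for C in C_grid:
        fn = as_predict_fn(fit(C))
        try:
            score = evaluate_auroc(fn, val_recs or train_recs, task)["macro"]
        except ValueError:
            score = 0.5
        if score > best_auc:
            best_auc, best_fn = score, fn
    test_auc = evaluate_auroc(best_fn, test_recs, task)
    return best_fn, test_auc
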