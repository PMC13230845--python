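"""Training protocol, cross-validation, metrics, and the SeedMatch baseline.

The protocol: Adam (lr 1e-3, weight decay 1e-4), batch size 64, binary
cross-entropy on the logit, an inner stratified validation split (10%)
monitored by ROC-AUC for early stopping (patience 4) with best-weight
restore, and a reduce-on-plateau learning-rate schedule (factor 0.5,
patience 2).  Per fold, the decision threshold is chosen on the inner
validation split by maximizing Youden's J = TPR - FPR; external test sets
use a fixed 0.5 threshold instead, to avoid post hoc tuning.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .featurize import (CHANNEL_GROUPS, FeaturizerConfig, ablation_mask,
                        featurize_records)
from .model import (Adam, InteractionCNN, ModelConfig, bce_with_logits,
                    save_checkpoint)
from .seq_io import LengthPolicy, PairRecord, fit_length_policy
from .structure import StructureCache, StructureConfig


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 64
    weight_decay: float = 1e-4
    early_stop_patience: int = 4
    scheduler_factor: float = 0.5
    scheduler_patience: int = 2
    max_epochs: int = 30
    inner_val_fraction: float = 0.1
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 < self.inner_val_fraction < 1:
            raise ValueError("inner_val_fraction must be in (0,1)")
        if self.early_stop_patience < 1 or self.scheduler_patience < 1:
            raise ValueError("patiences must be >= 1")


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_auc: float
    pr_auc: float
    threshold: float
    n_pos: int
    n_neg: int
    precision_undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc, "threshold": self.threshold,
            "n_pos": self.n_pos, "n_neg": self.n_neg,
        }


@dataclass
class FoldResult:
    fold: int
    metrics: MetricsReport
    history: list[dict]
    train_seconds: float


# ---------------------------------------------------------------------------
# splitting, thresholds, metrics
# ---------------------------------------------------------------------------


def stratified_folds(labels: Sequence[int], k: int, seed: int) -> list[np.ndarray]:
    """k disjoint, stratified, seed-deterministic test-index sets."""
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"k={k} exceeds the smaller class count {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


def select_threshold(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing Youden's J = TPR - FPR.

    Candidates are 0, 1 and all midpoints of sorted distinct scores; ties
    in J are broken toward the smaller threshold.  Hard calls downstream
    are ``probability >= threshold``.
    """
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("threshold selection needs both classes")
    distinct = np.unique(p)
    mids = (distinct[:-1] + distinct[1:]) / 2
    candidates = np.concatenate([[0.0], mids, [1.0]])
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    best_t, best_j = 0.0, -np.inf
    for t in candidates:
        calls = p >= t
        tpr = (calls & (y == 1)).sum() / n_pos
        fpr = (calls & (y == 0)).sum() / n_neg
        j = tpr - fpr
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def compute_metrics(probabilities: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> MetricsReport:
    """Confusion-matrix metrics at ``p >= threshold`` plus ROC-AUC / PR-AUC."""
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=np.float64)
    calls = p >= threshold
    tp = int((calls & (y == 1)).sum())
    fp = int((calls & (y == 0)).sum())
    fn = int((~calls & (y == 1)).sum())
    tn = int((~calls & (y == 0)).sum())
    accuracy = (tp + tn) / len(y)
    undefined = (tp + fp) == 0
    precision = 0.0 if undefined else tp / (tp + fp)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    if len(np.unique(y)) == 2:
        roc = float(roc_auc_score(y, p))
        prec_curve, rec_curve, _ = precision_recall_curve(y, p)
        pr = float(sk_auc(rec_curve, prec_curve))
    else:
        roc = pr = float("nan")
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall,
                         f1=f1, roc_auc=roc, pr_auc=pr, threshold=threshold,
                         n_pos=int((y == 1).sum()), n_neg=int((y == 0).sum()),
                         precision_undefined=undefined)


def roc_points(probabilities: np.ndarray, labels: np.ndarray):
    """(fpr, tpr, thresholds) of the full ROC curve."""
    return roc_curve(labels, probabilities)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _train_on_arrays(X: np.ndarray, y: np.ndarray, mcfg: ModelConfig,
                     tcfg: TrainConfig):
    """Core loop on pre-featurized arrays; returns (model, history, val split)."""
    idx_train, idx_val = train_test_split(
        np.arange(len(y)), test_size=tcfg.inner_val_fraction,
        stratify=y, random_state=tcfg.seed)
    Xtr, ytr = X[idx_train], y[idx_train]
    Xval, yval = X[idx_val], y[idx_val]

    rng = np.random.default_rng(tcfg.seed)
    model = InteractionCNN(mcfg, rng=rng)
    opt = Adam(model, lr=tcfg.lr, weight_decay=tcfg.weight_decay)

    best_auc, best_state, best_epoch = -np.inf, model.get_state(), -1
    bad_stop = bad_sched = 0
    history: list[dict] = []
    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(len(ytr))
        losses = []
        for s in range(0, len(order), tcfg.batch_size):
            sel = order[s:s + tcfg.batch_size]
            logits = model.forward(Xtr[sel], train=True)
            loss, dlogit = bce_with_logits(logits, ytr[sel])
            model.backward(dlogit)
            opt.step()
            losses.append(loss)
        val_prob = model.predict_proba(Xval)
        val_auc = float(roc_auc_score(yval, val_prob))
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_roc_auc": val_auc, "lr": opt.lr})
        if val_auc > best_auc:
            best_auc, best_state, best_epoch = val_auc, model.get_state(), epoch
            bad_stop = bad_sched = 0
        else:
            bad_stop += 1
            bad_sched += 1
            if bad_sched > tcfg.scheduler_patience:
                opt.lr *= tcfg.scheduler_factor
                bad_sched = 0
            if bad_stop >= tcfg.early_stop_patience:
                break
    model.set_state(best_state)
    return model, history, (Xval, yval), best_epoch


def train_model(records: Sequence[PairRecord],
                tcfg: TrainConfig = TrainConfig(),
                fcfg: FeaturizerConfig = FeaturizerConfig(),
                scfg: StructureConfig = StructureConfig(),
                mcfg: ModelConfig | None = None,
                policy: LengthPolicy | None = None,
                cache: StructureCache | None = None):
    """Featurize, train with early stopping, and return (model, info).

    ``info`` carries the training history, the Youden threshold selected on
    the inner validation split, the length policy, and the best epoch.
    """
    labels = np.array([r.label for r in records])
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    if policy is None:
        policy = fit_length_policy(records)
    if mcfg is None:
        mcfg = ModelConfig(in_channels=fcfg.n_channels)
    X = featurize_records(records, policy, fcfg, scfg, cache)
    model, history, (Xval, yval), best_epoch = _train_on_arrays(
        X, labels, mcfg, tcfg)
    val_prob = model.predict_proba(Xval)
    threshold = select_threshold(val_prob, yval)
    info = {
        "history": history,
        "threshold": threshold,
        "best_epoch": best_epoch,
        "policy": policy,
        "fcfg": fcfg,
        "scfg": scfg,
        "tcfg": tcfg,
    }
    return model, info


def _checkpoint_extra(info: dict) -> dict:
    fcfg: FeaturizerConfig = info["fcfg"]
    scfg: StructureConfig = info["scfg"]
    policy: LengthPolicy = info["policy"]
    return {
        "featurizer_config": {"k": fcfg.k, "channel_mask": list(fcfg.channel_mask)},
        "structure_config": {"l_min": scfg.l_min, "allow_gu": scfg.allow_gu},
        "length_policy": {"L_p": policy.L_p, "L_m": policy.L_m},
        "threshold": info["threshold"],
    }


def save_trained(path, model: InteractionCNN, info: dict) -> None:
    save_checkpoint(path, model, extra=_checkpoint_extra(info))


def run_cv(records: Sequence[PairRecord], k: int = 5,
           tcfg: TrainConfig = TrainConfig(),
           fcfg: FeaturizerConfig = FeaturizerConfig(),
           scfg: StructureConfig = StructureConfig(),
           policy: LengthPolicy | None = None,
           cache: StructureCache | None = None,
           X: np.ndarray | None = None) -> dict:
    """Stratified k-fold cross-validation.

    Per fold: train on k-1 folds with an inner validation split, pick the
    Youden threshold on that split, evaluate on the held-out fold.  Returns
    per-fold results, the average row, and held-out ROC curve points.
    Pass a pre-featurized ``X`` to reuse tensors across ablation modes.
    """
    labels = np.array([r.label for r in records])
    if policy is None:
        policy = fit_length_policy(records)
    if X is None:
        X = featurize_records(records, policy, fcfg, scfg, cache)
    mcfg = ModelConfig(in_channels=X.shape[1])
    folds = stratified_folds(labels, k, tcfg.seed)

    results: list[FoldResult] = []
    curves = []
    all_idx = np.arange(len(labels))
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        t0 = time.perf_counter()
        model, history, (Xval, yval), _ = _train_on_arrays(
            X[train_idx], labels[train_idx], mcfg, tcfg)
        elapsed = time.perf_counter() - t0
        threshold = select_threshold(model.predict_proba(Xval), yval)
        test_prob = model.predict_proba(X[test_idx])
        report = compute_metrics(test_prob, labels[test_idx], threshold)
        results.append(FoldResult(fold=fi, metrics=report, history=history,
                                  train_seconds=elapsed))
        fpr, tpr, _ = roc_points(test_prob, labels[test_idx])
        curves.append({"fold": fi, "fpr": fpr, "tpr": tpr})

    keys = ("accuracy", "precision", "recall", "f1", "roc_auc", "pr_auc",
            "threshold")
    average = {key: float(np.mean([getattr(r.metrics, key) for r in results]))
               for key in keys}
    return {"folds": results, "average": average, "curves": curves,
            "policy": policy, "k": k}


def run_ablation(records: Sequence[PairRecord], modes: Sequence[str],
                 k: int = 5, tcfg: TrainConfig = TrainConfig(),
                 base_fcfg: FeaturizerConfig = FeaturizerConfig(),
                 scfg: StructureConfig = StructureConfig(),
                 cache: StructureCache | None = None) -> dict[str, dict]:
    """Cross-validate each channel-ablation mode with identical splits.

    Channel groups are removed, not zero-filled: the tensor narrows and the
    model's input width follows.  The full tensor is featurized once and
    sliced per mode.
    """
    policy = fit_length_policy(records)
    full_fcfg = replace(base_fcfg, channel_mask=CHANNEL_GROUPS)
    X_full = featurize_records(records, policy, full_fcfg, scfg, cache)

    # canonical channel offsets within the full tensor
    offsets, pos = {}, 0
    from .featurize import GROUP_SIZES
    for g in CHANNEL_GROUPS:
        offsets[g] = (pos, pos + GROUP_SIZES[g])
        pos += GROUP_SIZES[g]

    out: dict[str, dict] = {}
    for mode in modes:
        mask = ablation_mask(mode)
        sel = np.concatenate([np.arange(*offsets[g]) for g in mask])
        fcfg = replace(base_fcfg, channel_mask=mask)
        out[mode] = run_cv(records, k=k, tcfg=tcfg, fcfg=fcfg, scfg=scfg,
                           policy=policy, X=np.ascontiguousarray(X_full[:, sel]))
    return out


# ---------------------------------------------------------------------------
# SeedMatch heuristic baseline
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "U"), ("U", "G")}


def seedmatch_score(rec: PairRecord, w: int = 7, allow_gu: bool = False) -> float:
    """Best w-nt window complementarity fraction, antiparallel alignment.

    Slides every w-long piRNA window against every w-long site window; in
    each alignment position t, piRNA base p[i+t] faces site base
    m[j+w-1-t].  Canonical complements (A-U, G-C) count 1; the G-U wobble
    counts only when ``allow_gu``.  Score = best count / w.
    """
    p = rec.pirna.bases
    m = rec.site.bases
    if len(p) < w or len(m) < w:
        raise ValueError(f"both sequences must be >= window length {w}")
    best = 0
    for i in range(len(p) - w + 1):
        pw = p[i:i + w]
        for j in range(len(m) - w + 1):
            mw = m[j:j + w]
            count = 0
            for t in range(w):
                a, b = pw[t], mw[w - 1 - t]
                if _COMPLEMENT[a] == b or (allow_gu and (a, b) in _WOBBLE):
                    count += 1
            if count > best:
                best = count
                if best == w:
                    return 1.0
    return best / w


def seedmatch_scores(records: Sequence[PairRecord], w: int = 7,
                     allow_gu: bool = False) -> np.ndarray:
    return np.array([seedmatch_score(r, w, allow_gu) for r in records])
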