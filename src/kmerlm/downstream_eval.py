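"""Frozen-embedding CNN classifier and binary-classification metrics.

The classifier is deliberately simple: embedding lookup (frozen by
default) -> 1-D convolutions of several widths -> ReLU -> global max
pool per kernel -> concatenate -> dense -> dropout -> sigmoid. It runs
on NumPy with hand-written gradients, like the transformer.

AUROC is computed with the midrank formula (equivalent to concordant-
pair counting, which the tests verify by brute force); AUPRC by
step-wise precision-recall integration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from ._nn import Adam, sigmoid
from .embeddings import EmbeddingTable
from .synthetic_data import LabeledSequenceSet


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

def auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the rank statistic with midranks."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined for single-class labels")
    ranks = rankdata(s)  # midranks for ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def auprc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve by step integration."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    if n_pos == 0 or (y == 0).sum() == 0:
        raise ValueError("AUPRC undefined for single-class labels")
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # evaluate only at distinct thresholds (last index of each block)
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.concatenate([distinct, [len(s) - 1]])
    precision = tp[idx] / (tp[idx] + fp[idx])
    recall = tp[idx] / n_pos
    area = 0.0
    prev_recall = 0.0
    for p, r in zip(precision, recall):
        area += (r - prev_recall) * p
        prev_recall = r
    return float(area)


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient from a confusion matrix."""
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / denom)


@dataclass
class MetricsReport:
    accuracy: float
    f1: float
    mcc: float
    auroc: float | None
    auprc: float | None
    threshold: float
    n: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compute_metrics(y_true: np.ndarray, scores: np.ndarray,
                    threshold: float = 0.5) -> MetricsReport:
    """Full metric suite at a single threshold plus ranking metrics.

    With a single-class label vector the ranking metrics are reported
    as None and the threshold metrics are still computed.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    acc = (tp + tn) / len(y)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    single_class = len(np.unique(y)) < 2
    return MetricsReport(
        accuracy=float(acc), f1=float(f1), mcc=mcc(tp, tn, fp, fn),
        auroc=None if single_class else auroc(y, s),
        auprc=None if single_class else auprc(y, s),
        threshold=threshold, n=len(y))


# --------------------------------------------------------------------------
# CNN classifier
# --------------------------------------------------------------------------

@dataclass
class ClassifierConfig:
    embedding: EmbeddingTable
    freeze_embeddings: bool = True
    kernel_widths: tuple[int, ...] = (7, 14, 27)
    kernels_per_width: int = 32
    dense_units: int = 64
    dropout: float = 0.2
    lr: float = 1e-2
    epochs: int = 10
    batch: int = 32
    seed: int = 0


@dataclass
class ClassifierState:
    cfg: ClassifierConfig
    params: dict[str, np.ndarray]
    input_length_tokens: int
    best_epoch: int | None = None

    @property
    def k(self) -> int:
        return len(self.cfg.embedding.row_labels[0])


def build_classifier(cfg: ClassifierConfig,
                     input_length_tokens: int) -> ClassifierState:
    """Initialize the CNN for a given tokenized input length.

    The (possibly frozen) embedding matrix is stored under
    ``params['emb']``; when frozen it never receives updates and is
    excluded from the trainable-parameter count.
    """
    if max(cfg.kernel_widths) >= input_length_tokens:
        raise ValueError(
            f"kernel width {max(cfg.kernel_widths)} must be smaller than "
            f"the tokenized input length {input_length_tokens}")
    rng = np.random.default_rng(cfg.seed)
    d = cfg.embedding.dim
    C = cfg.kernels_per_width
    params: dict[str, np.ndarray] = {
        "emb": cfg.embedding.matrix.astype(float).copy()}
    for w in cfg.kernel_widths:
        fan_in = w * d
        params[f"conv{w}.w"] = rng.normal(
            0, np.sqrt(2.0 / fan_in), size=(fan_in, C))
        params[f"conv{w}.b"] = np.zeros(C)
    zdim = C * len(cfg.kernel_widths)
    params["dense.w"] = rng.normal(0, np.sqrt(2.0 / zdim),
                                   size=(zdim, cfg.dense_units))
    params["dense.b"] = np.zeros(cfg.dense_units)
    params["out.w"] = rng.normal(0, np.sqrt(1.0 / cfg.dense_units),
                                 size=(cfg.dense_units,))
    params["out.b"] = np.zeros(1)
    return ClassifierState(cfg=cfg, params=params,
                           input_length_tokens=input_length_tokens)


def trainable_parameter_count(clf: ClassifierState) -> int:
    total = sum(v.size for k, v in clf.params.items() if k != "emb")
    if not clf.cfg.freeze_embeddings:
        total += clf.params["emb"].size
    return total


def tokenize_for_classifier(clf: ClassifierState,
                            sequences: list[str]) -> np.ndarray:
    """Overlapping k-mer row indices into the embedding table.

    No CLS/SEP tokens: the simple model uses token embeddings only.
    """
    k = clf.k
    index = clf.cfg.embedding.index
    ids = np.empty((len(sequences), len(sequences[0]) - k + 1), dtype=int)
    for i, seq in enumerate(sequences):
        for t in range(len(seq) - k + 1):
            ids[i, t] = index[seq[t:t + k]]
    return ids


def _forward(clf: ClassifierState, ids: np.ndarray, train: bool,
             rng: np.random.Generator | None):
    p = clf.params
    cfg = clf.cfg
    X = p["emb"][ids]  # (B, T, d)
    B, T, d = X.shape
    cache: dict = {"ids": ids, "X": X, "convs": {}}
    pooled = []
    for w in cfg.kernel_widths:
        win = np.lib.stride_tricks.sliding_window_view(X, w, axis=1)
        # (B, P, d, w) -> (B, P, w*d) matching conv weight layout
        col = win.transpose(0, 1, 3, 2).reshape(B, T - w + 1, w * d)
        pre = col @ p[f"conv{w}.w"] + p[f"conv{w}.b"]
        act = np.maximum(pre, 0.0)
        arg = act.argmax(axis=1)  # (B, C)
        mx = np.take_along_axis(act, arg[:, None, :], axis=1)[:, 0, :]
        cache["convs"][w] = dict(col=col, pre=pre, arg=arg)
        pooled.append(mx)
    z = np.concatenate(pooled, axis=1)
    h_pre = z @ p["dense.w"] + p["dense.b"]
    h = np.maximum(h_pre, 0.0)
    if train and cfg.dropout > 0:
        keep = (rng.random(h.shape) >= cfg.dropout) / (1 - cfg.dropout)
        h = h * keep
        cache["drop"] = keep
    else:
        cache["drop"] = None
    logit = h @ p["out.w"] + p["out.b"][0]
    cache.update(z=z, h_pre=h_pre, h=h)
    return logit, cache


def _backward(clf: ClassifierState, cache, dlogit: np.ndarray):
    p = clf.params
    cfg = clf.cfg
    grads: dict[str, np.ndarray] = {}
    h = cache["h"]
    grads["out.w"] = h.T @ dlogit
    grads["out.b"] = np.array([dlogit.sum()])
    dhid = np.outer(dlogit, p["out.w"])
    if cache["drop"] is not None:
        dhid = dhid * cache["drop"]
    dh_pre = dhid * (cache["h_pre"] > 0)
    grads["dense.w"] = cache["z"].T @ dh_pre
    grads["dense.b"] = dh_pre.sum(axis=0)
    dz = dh_pre @ p["dense.w"].T
    C = cfg.kernels_per_width
    dX = None if cfg.freeze_embeddings else np.zeros_like(cache["X"])
    B, T, d = cache["X"].shape
    for wi, w in enumerate(cfg.kernel_widths):
        c = cache["convs"][w]
        dmx = dz[:, wi * C:(wi + 1) * C]  # (B, C)
        dact = np.zeros_like(c["pre"])
        np.put_along_axis(dact, c["arg"][:, None, :], dmx[:, None, :],
                          axis=1)
        dpre = dact * (c["pre"] > 0)
        P = dpre.shape[1]
        grads[f"conv{w}.w"] = (c["col"].reshape(-1, w * d).T
                               @ dpre.reshape(-1, C))
        grads[f"conv{w}.b"] = dpre.sum(axis=(0, 1))
        if dX is not None:
            dcol = (dpre @ p[f"conv{w}.w"].T).reshape(B, P, w, d)
            for j in range(w):
                dX[:, j:j + P, :] += dcol[:, :, j, :]
    if dX is not None:
        demb = np.zeros_like(p["emb"])
        np.add.at(demb, cache["ids"].ravel(), dX.reshape(-1, d))
        grads["emb"] = demb
    return grads


def predict_scores(clf: ClassifierState, sequences: list[str],
                   batch: int = 256) -> np.ndarray:
    """Sigmoid scores in [0, 1] for a list of equal-length sequences."""
    ids = tokenize_for_classifier(clf, sequences)
    out = []
    for i in range(0, len(ids), batch):
        logit, _ = _forward(clf, ids[i:i + batch], train=False, rng=None)
        out.append(sigmoid(logit))
    return np.concatenate(out)


@dataclass
class BestEpochRecord:
    epoch: int
    dev_mcc: float
    history: list[dict] = field(default_factory=list)


def train_classifier(clf: ClassifierState, ds: LabeledSequenceSet,
                     ) -> tuple[ClassifierState, BestEpochRecord]:
    """Train with binary cross-entropy; keep the epoch with the best
    development-set MCC.

    Deterministic given ``cfg.seed``. With frozen embeddings the
    embedding matrix is bit-identical before and after training.
    """
    cfg = clf.cfg
    train_recs = ds.subset("train")
    dev_recs = ds.subset("dev")
    if not train_recs or not dev_recs:
        raise ValueError("dataset needs non-empty train and dev splits")
    y_train = np.array([r.label for r in train_recs], dtype=float)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training split contains a single class")
    ids_train = tokenize_for_classifier(
        clf, [r.sequence for r in train_recs])
    dev_seqs = [r.sequence for r in dev_recs]
    y_dev = np.array([r.label for r in dev_recs], dtype=int)

    clf = ClassifierState(cfg=cfg,
                          params={k: v.copy()
                                  for k, v in clf.params.items()},
                          input_length_tokens=clf.input_length_tokens)
    trainable = [k for k in clf.params
                 if k != "emb" or not cfg.freeze_embeddings]
    opt = Adam({k: clf.params[k] for k in trainable}, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)

    best = BestEpochRecord(epoch=0, dev_mcc=-np.inf)
    best_params = None
    n = len(ids_train)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        for i in range(0, n, cfg.batch):
            sel = order[i:i + cfg.batch]
            logit, cache = _forward(clf, ids_train[sel], train=True,
                                    rng=rng)
            prob = sigmoid(logit)
            dlogit = (prob - y_train[sel]) / len(sel)
            grads = _backward(clf, cache, dlogit)
            opt.step({k: v for k, v in grads.items() if k in trainable})
        dev_scores = predict_scores(clf, dev_seqs)
        report = compute_metrics(y_dev, dev_scores)
        best.history.append({"epoch": epoch, "dev_mcc": report.mcc,
                             "dev_auroc": report.auroc})
        if report.mcc > best.dev_mcc:
            best.dev_mcc = report.mcc
            best.epoch = epoch
            best_params = {k: v.copy() for k, v in clf.params.items()}
    clf.params = best_params
    clf.best_epoch = best.epoch
    return clf, best


def evaluate(clf: ClassifierState, ds: LabeledSequenceSet,
             threshold: float = 0.5) -> MetricsReport:
    """Metric suite on the test split only."""
    test = ds.subset("test")
    if not test:
        raise ValueError("dataset has an empty test split")
    scores = predict_scores(clf, [r.sequence for r in test])
    return compute_metrics(np.array([r.label for r in test]), scores,
                           threshold=threshold)
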