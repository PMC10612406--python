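"""Masked language model pre-training with dev-loss tracking.

Training samples fixed-length token windows uniformly from a corpus of
nucleotide strings, masks contiguous runs of ``k`` tokens, and
minimizes masked cross-entropy with Adam under a linear warmup. The
development loss is recorded at regular intervals together with an
exponentially smoothed trace used for convergence detection.

Two diagnostic statistics mirror the analysis this package implements:
masked-token accuracy, and the fraction of masked-token predictions
that agree with the characters forced by flanking unmasked tokens
(*overlap consistency*), which on uniform random text is the only
learnable part of the task.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import Adam
from .kmer_tokens import (
    TokenSequence, MaskingPlan, apply_mask, analyze_inferability,
    mask_contiguous, tokenize,
)
from .model_core import ModelState, mlm_loss_batch


@dataclass
class MaskConfig:
    rate: float = 0.15
    replace_probs: tuple[float, float, float] = (0.8, 0.1, 0.1)


@dataclass
class OptConfig:
    lr: float = 1e-3
    batch: int = 16
    steps: int = 1000
    eval_every: int = 50
    window_tokens: int = 64
    warmup_frac: float = 0.1
    smoothing_alpha: float = 0.1
    dev_batches: int = 4


@dataclass
class PretrainRunLog:
    """Dev-loss trace: (step, dev_loss, smoothed_loss) triples.

    ``smoothed_loss_t = alpha * dev_loss_t + (1-alpha) * smoothed_{t-1}``
    with the first smoothed value equal to the first dev loss.
    """

    eval_points: list[tuple[int, float, float]] = field(default_factory=list)
    alpha: float = 0.1
    config: dict = field(default_factory=dict)
    seed: int = 0

    def record(self, step: int, dev_loss: float) -> None:
        if self.eval_points and step <= self.eval_points[-1][0]:
            raise ValueError("eval steps must be strictly increasing")
        if not self.eval_points:
            smoothed = dev_loss
        else:
            smoothed = (self.alpha * dev_loss
                        + (1 - self.alpha) * self.eval_points[-1][2])
        self.eval_points.append((step, dev_loss, smoothed))

    @property
    def final_smoothed(self) -> float:
        return self.eval_points[-1][2]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("step\tdev_loss\tsmoothed_loss\n")
            for step, loss, smoothed in self.eval_points:
                fh.write(f"{step}\t{loss:.6f}\t{smoothed:.6f}\n")


@dataclass
class ConvergenceResult:
    threshold: float
    step_reached: int | None
    patience: int = 1


def convergence_step(log: PretrainRunLog,
                     threshold: float) -> ConvergenceResult:
    """First eval step whose smoothed loss is <= threshold, else None."""
    if not log.eval_points:
        raise ValueError("empty run log")
    for step, _, smoothed in log.eval_points:
        if smoothed <= threshold:
            return ConvergenceResult(threshold=threshold, step_reached=step)
    return ConvergenceResult(threshold=threshold, step_reached=None)


def _sample_window(corpus: list[str], window_nt: int,
                   rng: np.random.Generator) -> str:
    weights = np.array([max(1, len(s) - window_nt + 1) for s in corpus],
                       dtype=float)
    i = int(rng.choice(len(corpus), p=weights / weights.sum()))
    seq = corpus[i]
    if len(seq) <= window_nt:
        return seq
    start = int(rng.integers(0, len(seq) - window_nt + 1))
    return seq[start:start + window_nt]


def make_eval_set(state_or_vocab, corpus: list[str], n_windows: int,
                  window_tokens: int, mask_cfg: MaskConfig,
                  seed: int) -> list[tuple[TokenSequence, MaskingPlan]]:
    """Fixed (TokenSequence, MaskingPlan) pairs for repeatable evaluation."""
    vocab = getattr(state_or_vocab, "vocab", state_or_vocab)
    k = vocab.k
    window_nt = window_tokens + k - 1
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_windows):
        seq = _sample_window(corpus, window_nt, rng)
        ts = tokenize(seq, vocab, add_specials=True)
        plan = mask_contiguous(ts, mask_cfg.rate,
                               rng_seed=int(rng.integers(2 ** 31)),
                               replace_probs=mask_cfg.replace_probs)
        out.append((ts, plan))
    return out


def _batch_arrays(pairs, rng):
    """Stack equally long (ts, plan) pairs into id/label/mask arrays."""
    input_ids = np.array([apply_mask(ts, plan, rng) for ts, plan in pairs])
    labels = np.array([ts.ids for ts, _ in pairs])
    mask = np.zeros_like(labels, dtype=bool)
    for row, (_, plan) in enumerate(pairs):
        mask[row, plan.masked_positions] = True
    return input_ids, labels, mask


def evaluate_dev_loss(state: ModelState, eval_set) -> float:
    """Mean masked cross-entropy over a fixed eval set.

    Pairs of equal token length are evaluated as one batch.
    """
    groups: dict[int, list] = {}
    for ts, plan in eval_set:
        groups.setdefault(len(ts.ids), []).append((ts, plan))
    total, n = 0.0, 0
    rng = np.random.default_rng(0)
    for pairs in groups.values():
        input_ids, labels, mask = _batch_arrays(pairs, rng)
        loss, _ = mlm_loss_batch(state, input_ids, labels, mask)
        m = int(mask.sum())
        total += loss * m
        n += m
    return total / n


def pretrain(state: ModelState, corpus: list[str],
             mask_cfg: MaskConfig | None = None,
             opt_cfg: OptConfig | None = None,
             dev_corpus: list[str] | None = None,
             seed: int = 0,
             progress: bool = False) -> tuple[ModelState, PretrainRunLog]:
    """Train with masked-token cross-entropy; returns a new state.

    When ``dev_corpus`` is None, 20% of the corpus sequences are held
    out as the development set. Deterministic given (state, corpus,
    configs, seed); the input state is not mutated.
    """
    mask_cfg = mask_cfg or MaskConfig()
    opt_cfg = opt_cfg or OptConfig()
    if not corpus:
        raise ValueError("empty corpus")
    k = state.config.k
    if any(len(s) < k for s in corpus):
        raise ValueError(f"corpus sequences must be at least k={k} long")
    if opt_cfg.steps < 1:
        raise ValueError("steps must be >= 1")

    rng = np.random.default_rng(seed)
    if dev_corpus is None:
        n_dev = max(1, len(corpus) // 5)
        order = rng.permutation(len(corpus))
        dev_corpus = [corpus[i] for i in order[:n_dev]]
        corpus = [corpus[i] for i in order[n_dev:]] or dev_corpus

    state = state.copy()
    vocab = state.vocab
    window_nt = opt_cfg.window_tokens + k - 1

    eval_set = make_eval_set(vocab, dev_corpus, opt_cfg.dev_batches
                             * opt_cfg.batch // 4 or 1,
                             opt_cfg.window_tokens, mask_cfg,
                             seed=int(rng.integers(2 ** 31)))

    log = PretrainRunLog(alpha=opt_cfg.smoothing_alpha,
                         config={"mask": asdict(mask_cfg),
                                 "opt": asdict(opt_cfg),
                                 "model": asdict(state.config),
                                 **state.provenance},
                         seed=seed)
    opt = Adam(state.params, lr=opt_cfg.lr,
               warmup_steps=max(1, int(opt_cfg.warmup_frac
                                       * opt_cfg.steps)),
               total_steps=opt_cfg.steps)

    log.record(0, evaluate_dev_loss(state, eval_set))
    iterator = range(1, opt_cfg.steps + 1)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="pretrain")
        except ImportError:
            pass
    for step in iterator:
        pairs = []
        for _ in range(opt_cfg.batch):
            seq = _sample_window(corpus, window_nt, rng)
            ts = tokenize(seq, vocab, add_specials=True)
            plan = mask_contiguous(ts, mask_cfg.rate,
                                   rng_seed=int(rng.integers(2 ** 31)),
                                   replace_probs=mask_cfg.replace_probs)
            pairs.append((ts, plan))
        input_ids, labels, mask = _batch_arrays(pairs, rng)
        loss, _, grads = mlm_loss_batch(state, input_ids, labels, mask,
                                        with_grads=True, train=True, rng=rng)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss at step {step}: {loss}")
        opt.step(grads)
        if step % opt_cfg.eval_every == 0 or step == opt_cfg.steps:
            log.record(step, evaluate_dev_loss(state, eval_set))
    return state, log


def warm_start_pretrain(init_from: ModelState, corpus: list[str],
                        mask_cfg: MaskConfig | None = None,
                        opt_cfg: OptConfig | None = None,
                        dev_corpus: list[str] | None = None,
                        seed: int = 0,
                        expected_config=None,
                        progress: bool = False):
    """Pre-train starting from an existing checkpoint's weights.

    Contract identical to :func:`pretrain`, with initial weights copied
    from ``init_from``; the run log echoes the checkpoint provenance.
    ``expected_config``, when given, must structurally match the
    checkpoint's config (everything except the seed).
    """
    if expected_config is not None:
        a, b = dict(vars(expected_config)), dict(vars(init_from.config))
        a.pop("seed"), b.pop("seed")
        if a != b:
            mismatched = sorted(key for key in a if a[key] != b[key])
            raise ValueError(
                "warm-start checkpoint incompatible with requested "
                f"config (mismatched: {', '.join(mismatched)})")
    start = init_from.copy()
    start.provenance = {"warm_start_from": dict(init_from.provenance)}
    state, log = pretrain(start, corpus, mask_cfg=mask_cfg,
                          opt_cfg=opt_cfg, dev_corpus=dev_corpus,
                          seed=seed, progress=progress)
    return state, log


def _batched_predictions(state: ModelState, eval_set, batch: int = 64):
    """Yield (pairs, preds, labels, mask) over equal-length batches."""
    groups: dict[int, list] = {}
    for pair in eval_set:
        groups.setdefault(len(pair[0].ids), []).append(pair)
    rng = np.random.default_rng(0)
    for pairs in groups.values():
        for i in range(0, len(pairs), batch):
            chunk = pairs[i:i + batch]
            input_ids, labels, mask = _batch_arrays(chunk, rng)
            _, preds = mlm_loss_batch(state, input_ids, labels, mask)
            yield chunk, preds, labels, mask


def masked_token_accuracy(state: ModelState, eval_set) -> float:
    """Fraction of masked positions where argmax equals the true token."""
    correct, total = 0, 0
    for _, preds, labels, mask in _batched_predictions(state, eval_set):
        truth = labels[mask]
        correct += int((preds == truth).sum())
        total += truth.size
    if total == 0:
        raise ValueError("eval set contains no masked positions")
    return correct / total


def prediction_overlap_consistency(state: ModelState, eval_set) -> float:
    """Fraction of masked-token predictions consistent with their
    context-forced characters.

    For each masked token, the characters pinned by flanking unmasked
    tokens (``observed`` or ``deducible`` status of the covered source
    positions) define the consistency constraint; a prediction agrees
    when it is a k-mer matching all pinned characters. Tokens with no
    pinned characters are excluded. For an interior run of ``k`` masked
    tokens every token has ``k-1`` pinned characters, so the chance
    level for an argmax oblivious to context is ``4 / 4**k``.
    """
    k = state.config.k
    vocab = state.vocab
    agree, total = 0, 0
    for chunk, preds, _, _ in _batched_predictions(state, eval_set):
        offset = 0
        for ts, plan in chunk:
            report = analyze_inferability(ts, plan)
            pinned = [s in ("observed", "deducible")
                      for s in report.status]
            forced = ts.source
            off = ts.offset
            masked = plan.masked_positions
            for pred, pos in zip(preds[offset:offset + len(masked)],
                                 masked):
                src = pos - off
                spans = [(j, src + j) for j in range(k)
                         if pinned[src + j]]
                if not spans:
                    continue
                total += 1
                if vocab.is_special_id(int(pred)):
                    continue
                tok = vocab.token_of(int(pred))
                if all(tok[j] == forced[q] for j, q in spans):
                    agree += 1
            offset += len(masked)
    if total == 0:
        raise ValueError("eval set has no context-constrained predictions")
    return agree / total
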