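"""Desk-scale comparative experiments.

Four recipes, each returning an :class:`ExperimentReport` with one row
per (arm, seed) and mean/sd aggregates:

- ``pretrain_contrast``   — embedding geometry of models trained on
  random vs Markov text vs untrained;
- ``downstream_ablation`` — fine-tuning the full mini model under the
  four knockout arms (structured / random-data / encoding-reinit /
  all-reinit);
- ``embedding_comparison``— frozen-embedding CNN across one-hot,
  model-extracted and optional external tables;
- ``warm_start``          — convergence step of warm vs cold
  pre-training on structured text.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import Adam, sigmoid
from .downstream_eval import (
    ClassifierConfig, build_classifier, train_classifier, evaluate,
    compute_metrics,
)
from .embedding_analysis import (
    neighbor_overlap_statistic, central_nucleotide_separation,
    one_hot_table,
)
from .embeddings import load_embedding_table
from .kmer_tokens import tokenize
from .model_core import (
    ModelConfig, ModelState, build_model, extract_token_embeddings,
    forward_hidden, backward_hidden, reinitialize_module,
)
from .pretraining import (
    MaskConfig, OptConfig, pretrain, warm_start_pretrain,
    convergence_step,
)
from .synthetic_data import (
    BackgroundModel, generate_background, make_motif_discovery_dataset,
    make_promoter_dataset, markov_background, one_hot_pwm,
    tata_box_pwm, uniform_background, LabeledSequenceSet,
)


def mini_model_config(seed: int = 0, **over) -> ModelConfig:
    """Desk-scale pre-training model: 1 layer, H=32, tied MLM head.

    Tying matters: the output projection sharing the token-embedding
    table is what presses k-mers with interchangeable contexts (shared
    prefixes/suffixes) toward each other in embedding space.
    """
    base = dict(k=3, hidden=32, layers=1, heads=2, ffn=128,
                max_positions=24, seed=seed, dtype="float32",
                tie_weights=True)
    base.update(over)
    return ModelConfig(**base)


def mini_opt_config(steps: int = 2500, **over) -> OptConfig:
    """Optimizer recipe under which overlap consistency emerges within
    a few thousand steps on a single CPU."""
    base = dict(steps=steps, eval_every=max(25, steps // 20), batch=32,
                window_tokens=16, lr=3e-3)
    base.update(over)
    return OptConfig(**base)


def mini_mask_config(**over) -> MaskConfig:
    base = dict(rate=0.25)
    base.update(over)
    return MaskConfig(**base)


@dataclass
class ExperimentSpec:
    experiment: str
    seeds: list[int] = field(default_factory=lambda: [0, 1, 2])
    corpus_bases: int = 200_000
    steps: int = 2000
    n_per_dataset: int = 2000
    model: ModelConfig = field(default_factory=mini_model_config)
    opt: OptConfig = field(default_factory=mini_opt_config)
    mask: MaskConfig = field(default_factory=mini_mask_config)
    outdir: str | None = None
    external_table_path: str | None = None
    promoter_length: int = 100  # ablation fine-tune window (bp)
    one_hot_ks: tuple[int, ...] = (1, 2, 3, 4, 5)

    def __post_init__(self):
        known = {"pretrain_contrast", "embedding_comparison",
                 "downstream_ablation", "warm_start"}
        if self.experiment not in known:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if not self.seeds:
            raise ValueError("need at least one seed")

    def config_hash(self) -> str:
        payload = json.dumps({
            "experiment": self.experiment, "seeds": self.seeds,
            "corpus_bases": self.corpus_bases, "steps": self.steps,
            "n_per_dataset": self.n_per_dataset,
            "model": asdict(self.model), "opt": asdict(self.opt),
            "mask": asdict(self.mask),
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ExperimentReport:
    experiment: str
    rows: list[dict]
    config_hash: str
    seeds: list[int]
    warnings: list[str] = field(default_factory=list)

    @property
    def aggregates(self) -> dict[str, dict[str, float]]:
        """Per-arm mean and sd of every numeric column."""
        by_arm: dict[str, list[dict]] = {}
        for row in self.rows:
            by_arm.setdefault(row["arm"], []).append(row)
        out: dict[str, dict[str, float]] = {}
        for arm, rows in by_arm.items():
            agg: dict[str, float] = {}
            keys = [k for k in rows[0]
                    if isinstance(rows[0][k], (int, float))
                    and not isinstance(rows[0][k], bool)]
            for key in keys:
                vals = np.array([r[key] for r in rows
                                 if r[key] is not None], dtype=float)
                if vals.size:
                    agg[f"{key}_mean"] = float(vals.mean())
                    agg[f"{key}_sd"] = float(vals.std(ddof=1)) \
                        if vals.size > 1 else 0.0
            out[arm] = agg
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"experiment": self.experiment,
                       "config_hash": self.config_hash,
                       "seeds": self.seeds,
                       "rows": self.rows,
                       "aggregates": self.aggregates,
                       "warnings": self.warnings}, fh, indent=2)

    def to_tsv(self, path) -> None:
        if not self.rows:
            return
        cols = list(self.rows[0])
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in self.rows:
                fh.write("\t".join(str(row.get(c)) for c in cols) + "\n")


DEFAULT_MARKOV_TRANSITION = np.array([
    [0.70, 0.10, 0.10, 0.10],
    [0.10, 0.70, 0.10, 0.10],
    [0.10, 0.10, 0.70, 0.10],
    [0.10, 0.10, 0.10, 0.70],
])


def _make_corpus(bg: BackgroundModel, total_bases: int, seed: int,
                 chunk: int = 10_000) -> list[str]:
    rng = np.random.default_rng(seed)
    n_chunks = max(1, total_bases // chunk)
    return [generate_background(bg, chunk, rng) for _ in range(n_chunks)]


def _pretrained_arm(spec: ExperimentSpec, background: str, seed: int,
                    ) -> ModelState:
    """Build and pre-train one model on the requested background."""
    cfg = ModelConfig(**{**asdict(spec.model), "seed": seed})
    model = build_model(cfg)
    if background == "untrained":
        return model
    if background == "random":
        bg = uniform_background(seed)
    elif background == "markov":
        bg = markov_background(DEFAULT_MARKOV_TRANSITION, seed=seed)
    else:
        raise ValueError(background)
    corpus = _make_corpus(bg, spec.corpus_bases, seed)
    opt = OptConfig(**{**asdict(spec.opt), "steps": spec.steps})
    trained, _ = pretrain(model, corpus, mask_cfg=spec.mask,
                          opt_cfg=opt, seed=seed)
    return trained


def run_pretrain_contrast(spec: ExperimentSpec) -> ExperimentReport:
    """Embedding-geometry contrast across training regimes."""
    rows = []
    for seed in spec.seeds:
        for arm in ("trained-on-random", "trained-on-markov", "untrained"):
            background = {"trained-on-random": "random",
                          "trained-on-markov": "markov",
                          "untrained": "untrained"}[arm]
            model = _pretrained_arm(spec, background, seed)
            table = extract_token_embeddings(
                model, include_specials=False)
            stat = neighbor_overlap_statistic(table, seed=seed)
            sep = central_nucleotide_separation(table) \
                if spec.model.k % 2 == 1 else None
            rows.append({
                "arm": arm, "seed": seed,
                "observed_mean_overlap": stat.observed_mean_overlap,
                "null_mean": stat.null_mean, "null_sd": stat.null_sd,
                "empirical_p": stat.empirical_p, "z": stat.z,
                "silhouette": sep.silhouette if sep else None,
            })
    return ExperimentReport(experiment=spec.experiment, rows=rows,
                            config_hash=spec.config_hash(),
                            seeds=list(spec.seeds))


def finetune_sequence_classifier(state: ModelState,
                                 ds: LabeledSequenceSet,
                                 lr: float = 3e-4, epochs: int = 3,
                                 batch: int = 16, seed: int = 0):
    """Fine-tune the full model with a sigmoid head on the CLS state.

    Returns (scores on the test split, test labels). Model selection is
    by development-set MCC across epochs.
    """
    rng = np.random.default_rng(seed)
    state = state.copy()
    H = state.config.hidden
    head_w = rng.normal(0, 0.02, size=H)
    head_b = np.zeros(1)
    vocab = state.vocab
    params = dict(state.params)
    params["head.cls_w"] = head_w
    params["head.cls_b"] = head_b
    opt = Adam(params, lr=lr)

    def encode(seqs):
        return np.array([tokenize(s, vocab).ids for s in seqs])

    train = ds.subset("train")
    dev = ds.subset("dev")
    test = ds.subset("test")
    ids_train = encode([r.sequence for r in train])
    y_train = np.array([r.label for r in train], dtype=float)
    ids_dev = encode([r.sequence for r in dev])
    y_dev = np.array([r.label for r in dev], dtype=int)
    ids_test = encode([r.sequence for r in test])
    y_test = np.array([r.label for r in test], dtype=int)

    def score(ids):
        out = []
        for i in range(0, len(ids), 64):
            hidden, _ = forward_hidden(state, ids[i:i + 64])
            out.append(sigmoid(hidden[:, 0, :] @ head_w + head_b[0]))
        return np.concatenate(out)

    best_mcc, best_snapshot = -np.inf, None
    n = len(ids_train)
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in range(0, n, batch):
            sel = order[i:i + batch]
            hidden, cache = forward_hidden(state, ids_train[sel],
                                           train=True, rng=rng)
            cls = hidden[:, 0, :]
            prob = sigmoid(cls @ head_w + head_b[0])
            dlogit = (prob - y_train[sel]) / len(sel)
            gw = cls.T @ dlogit
            gb = np.array([dlogit.sum()])
            dhidden = np.zeros_like(hidden)
            dhidden[:, 0, :] = np.outer(dlogit, head_w)
            grads = backward_hidden(cache, dhidden)
            grads["head.cls_w"] = gw
            grads["head.cls_b"] = gb
            opt.step(grads)
        dev_mcc = compute_metrics(y_dev, score(ids_dev)).mcc
        if dev_mcc > best_mcc:
            best_mcc = dev_mcc
            best_snapshot = ({k: v.copy() for k, v in state.params.items()},
                             head_w.copy(), head_b.copy())
    state.params, head_w, head_b = best_snapshot
    return score(ids_test), y_test


def run_downstream_ablation(spec: ExperimentSpec) -> ExperimentReport:
    """Four-arm knockout comparison, fine-tuned on synthetic promoters."""
    import dataclasses

    rows = []
    warnings: list[str] = []
    bg = uniform_background(0)
    L = spec.promoter_length
    # fine-tuning consumes whole promoter windows: widen the position
    # table while keeping the rest of the pre-training recipe
    model_cfg = ModelConfig(**{**asdict(spec.model),
                               "max_positions": max(
                                   spec.model.max_positions, L + 4)})
    spec = dataclasses.replace(spec, model=model_cfg)
    for seed in spec.seeds:
        ds = make_promoter_dataset(tata_box_pwm(), bg,
                                   n=spec.n_per_dataset, variant="tata",
                                   L=L, seed=seed)
        structured = _pretrained_arm(spec, "markov", seed)
        arms = {
            "structured": structured,
            "dataRand": _pretrained_arm(spec, "random", seed),
            "encRand": reinitialize_module(structured, "encoding",
                                           seed=seed + 1000),
            "allRand": _pretrained_arm(spec, "untrained", seed),
        }
        for arm, model in arms.items():
            try:
                scores, y = finetune_sequence_classifier(
                    model, ds, seed=seed)
                rep = compute_metrics(y, scores)
                rows.append({"arm": arm, "seed": seed,
                             "accuracy": rep.accuracy, "f1": rep.f1,
                             "mcc": rep.mcc, "auroc": rep.auroc,
                             "auprc": rep.auprc})
            except Exception as exc:  # keep sibling arms alive
                warnings.append(f"arm={arm} seed={seed}: {exc}")
    return ExperimentReport(experiment=spec.experiment, rows=rows,
                            config_hash=spec.config_hash(),
                            seeds=list(spec.seeds), warnings=warnings)


def run_embedding_comparison(spec: ExperimentSpec) -> ExperimentReport:
    """Frozen-embedding CNN across embedding sources on a shared
    motif-discovery dataset (paired by seed)."""
    rows = []
    warnings: list[str] = []
    motif = one_hot_pwm("SITE", "TTTGGTCA")
    bg = uniform_background(0)
    arms: list[tuple[str, object]] = [
        (f"one_hot_k{k}", ("one_hot", k)) for k in spec.one_hot_ks]
    if spec.external_table_path:
        arms.append(("external", ("external", None)))
    arms += [("model_random", ("model", "random")),
             ("model_markov", ("model", "markov"))]

    for seed in spec.seeds:
        ds = make_motif_discovery_dataset(motif, bg, n=spec.n_per_dataset,
                                          seed=seed)
        extracted = {}
        for arm, (kind, param) in arms:
            try:
                if kind == "one_hot":
                    table = one_hot_table(param)
                elif kind == "external":
                    table = load_embedding_table(spec.external_table_path)
                else:
                    if param not in extracted:
                        model = _pretrained_arm(spec, param, seed)
                        extracted[param] = extract_token_embeddings(
                            model, include_specials=False)
                    table = extracted[param]
                cfg = ClassifierConfig(embedding=table, seed=seed,
                                       kernel_widths=(8, 14),
                                       epochs=5)
                k = len(table.row_labels[0])
                clf = build_classifier(cfg, ds.length - k + 1)
                clf, _ = train_classifier(clf, ds)
                rep = evaluate(clf, ds)
                rows.append({"arm": arm, "seed": seed, "dim": table.dim,
                             "accuracy": rep.accuracy, "f1": rep.f1,
                             "mcc": rep.mcc, "auroc": rep.auroc,
                             "auprc": rep.auprc})
            except FileNotFoundError as exc:
                warnings.append(f"arm={arm} skipped: {exc}")
            except Exception as exc:
                warnings.append(f"arm={arm} seed={seed}: {exc}")
    return ExperimentReport(experiment=spec.experiment, rows=rows,
                            config_hash=spec.config_hash(),
                            seeds=list(spec.seeds), warnings=warnings)


def run_warm_start(spec: ExperimentSpec) -> ExperimentReport:
    """Warm (random-data checkpoint) vs cold pre-training on Markov
    text; reports the first-crossing convergence step per arm."""
    rows = []
    for seed in spec.seeds:
        random_bg = uniform_background(seed)
        random_corpus = _make_corpus(random_bg, spec.corpus_bases, seed)
        markov_bg = markov_background(DEFAULT_MARKOV_TRANSITION,
                                      seed=seed + 1)
        markov_corpus = _make_corpus(markov_bg, spec.corpus_bases,
                                     seed + 1)
        cfg = ModelConfig(**{**asdict(spec.model), "seed": seed})
        opt = OptConfig(**{**asdict(spec.opt), "steps": spec.steps})
        init_model = build_model(cfg)
        warm_init, _ = pretrain(init_model, random_corpus,
                                mask_cfg=spec.mask, opt_cfg=opt,
                                seed=seed)
        warm_state, warm_log = warm_start_pretrain(
            warm_init, markov_corpus, mask_cfg=spec.mask,
            opt_cfg=opt, seed=seed)
        cold_state, cold_log = pretrain(
            build_model(cfg), markov_corpus, mask_cfg=spec.mask,
            opt_cfg=opt, seed=seed)
        threshold = max(warm_log.final_smoothed,
                        cold_log.final_smoothed) + 0.05
        for arm, log in (("warm", warm_log), ("cold", cold_log)):
            res = convergence_step(log, threshold)
            rows.append({"arm": arm, "seed": seed,
                         "threshold": threshold,
                         "convergence_step": res.step_reached,
                         "final_smoothed": log.final_smoothed})
    return ExperimentReport(experiment=spec.experiment, rows=rows,
                            config_hash=spec.config_hash(),
                            seeds=list(spec.seeds))


RUNNERS = {
    "pretrain_contrast": run_pretrain_contrast,
    "downstream_ablation": run_downstream_ablation,
    "embedding_comparison": run_embedding_comparison,
    "warm_start": run_warm_start,
}


def run_experiment(spec: ExperimentSpec) -> ExperimentReport:
    return RUNNERS[spec.experiment](spec)
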