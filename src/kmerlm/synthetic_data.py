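"""Synthetic corpora and labelled benchmark datasets.

Pre-training text comes from order-0 (i.i.d.) or order-1 (Markov)
background models; the order-0 uniform model is the "random corpus" and
the order-1 model is a structured stand-in for real genomic text.

Labelled sets cover four binary tasks over fixed-length windows:

- ``motif_discovery``   — positives carry one PWM instance, negatives
  are dinucleotide-preserving shuffles of the positives (101 bp);
- ``motif_occupancy``   — negatives are GC- and motif-strength-matched
  backgrounds with a centred motif instance (101 bp);
- ``promoter_tata``     — 300 bp windows; both classes contain a TATA
  PWM instance, but only positives place it at the canonical offset;
- ``promoter_nontata``  — negatives derived from positives by replacing
  12 of 20 equal segments with fresh background.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class GenerationError(RuntimeError):
    """Rejection-sampling failed to satisfy a matching constraint."""


# --------------------------------------------------------------------------
# Background models
# --------------------------------------------------------------------------

@dataclass
class BackgroundModel:
    """Order-0 or order-1 nucleotide background.

    For ``order == 0`` ``composition`` is a 4-vector of base
    probabilities; for ``order == 1`` it is a 4x4 row-stochastic
    transition matrix and ``initial`` the start distribution.
    """

    order: int = 0
    composition: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    initial: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    seed: int = 0

    def __post_init__(self):
        self.composition = np.asarray(self.composition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.order not in (0, 1):
            raise ValueError(f"order must be 0 or 1, got {self.order}")
        if self.order == 0:
            if self.composition.shape != (4,):
                raise ValueError("order-0 composition must be a 4-vector")
            rows = self.composition[None, :]
        else:
            if self.composition.shape != (4, 4):
                raise ValueError("order-1 composition must be 4x4")
            rows = self.composition
        if np.any(rows < 0) or np.any(np.abs(rows.sum(axis=1) - 1) > 1e-9):
            raise ValueError("probability rows must be >=0 and sum to 1")
        if (self.initial.shape != (4,) or np.any(self.initial < 0)
                or abs(self.initial.sum() - 1) > 1e-9):
            raise ValueError("initial distribution must be a 4-simplex point")


def uniform_background(seed: int = 0) -> BackgroundModel:
    return BackgroundModel(order=0, seed=seed)


def markov_background(transition: np.ndarray,
                      initial: np.ndarray | None = None,
                      seed: int = 0) -> BackgroundModel:
    transition = np.asarray(transition, dtype=float)
    if initial is None:
        # stationary distribution of the chain
        vals, vecs = np.linalg.eig(transition.T)
        i = int(np.argmin(np.abs(vals - 1)))
        pi = np.real(vecs[:, i])
        initial = pi / pi.sum()
    return BackgroundModel(order=1, composition=transition,
                           initial=np.asarray(initial, float), seed=seed)


def generate_background(model: BackgroundModel, length: int,
                        rng: np.random.Generator | None = None) -> str:
    """Draw a nucleotide string of the given length from the model."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    if model.order == 0:
        idx = rng.choice(4, size=length, p=model.composition)
        return "".join(ALPHABET[i] for i in idx)
    cum = np.cumsum(model.composition, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int8)
    state = int(np.searchsorted(np.cumsum(model.initial), u[0], side="right"))
    state = min(state, 3)
    out[0] = state
    for t in range(1, length):
        state = int(np.searchsorted(cum[state], u[t], side="right"))
        state = min(state, 3)
        out[t] = state
    return "".join(ALPHABET[i] for i in out)


# --------------------------------------------------------------------------
# Position weight matrices
# --------------------------------------------------------------------------

@dataclass
class PWMotif:
    """A motif as a 4 x w column-stochastic probability matrix."""

    name: str
    matrix: np.ndarray  # rows A,C,G,T; columns are positions

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 x w")
        if self.width < 4:
            raise ValueError(f"PWM width must be >= 4, got {self.width}")
        cols = self.matrix.sum(axis=0)
        if np.any(self.matrix < 0) or np.any(np.abs(cols - 1) > 1e-9):
            raise ValueError("PWM columns must be >=0 and sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=0))

    def log_likelihood(self, site: str) -> float:
        """Log-probability (nats) of a width-w site under the PWM."""
        if len(site) != self.width:
            raise ValueError("site length does not match PWM width")
        with np.errstate(divide="ignore"):
            logm = np.log(self.matrix)
        return float(sum(logm[_BASE_INDEX[c], j] for j, c in enumerate(site)))


def one_hot_pwm(name: str, consensus: str) -> PWMotif:
    """A degenerate PWM that always emits ``consensus``."""
    m = np.zeros((4, len(consensus)))
    for j, c in enumerate(consensus):
        m[_BASE_INDEX[c], j] = 1.0
    return PWMotif(name=name, matrix=m)


def tata_box_pwm(strength: float = 0.85) -> PWMotif:
    """A TATA-box-like PWM peaked on the TATAAA consensus."""
    m = np.full((4, 6), (1 - strength) / 3)
    for j, c in enumerate("TATAAA"):
        m[_BASE_INDEX[c], j] = strength
    return PWMotif(name="TATA", matrix=m)


def sample_pwm_instance(motif: PWMotif, rng: np.random.Generator) -> str:
    """Column-independent draw of a width-w site from the PWM."""
    out = []
    for j in range(motif.width):
        out.append(ALPHABET[rng.choice(4, p=motif.matrix[:, j])])
    return "".join(out)


# --------------------------------------------------------------------------
# Dinucleotide-preserving shuffle (Altschul-Erikson Euler-path method)
# --------------------------------------------------------------------------

def dinucleotide_counts(seq: str) -> collections.Counter:
    return collections.Counter(seq[i:i + 2] for i in range(len(seq) - 1))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving the exact multiset of adjacent base pairs.

    Views the sequence as an Euler path in the multigraph whose edges
    are its dinucleotides; samples a uniform-ish random Euler path with
    the same start and end vertex by the Altschul-Erikson construction
    (random last-edge tree toward the terminal vertex, then random
    ordering of the remaining out-edges).
    """
    if len(seq) < 2:
        raise ValueError("need at least 2 characters")
    edges: dict[str, list[str]] = collections.defaultdict(list)
    for i in range(len(seq) - 1):
        edges[seq[i]].append(seq[i + 1])
    first, last = seq[0], seq[-1]
    vertices = [v for v in edges]

    if len(vertices) == 1:
        return seq  # single-letter alphabet: only one Euler path

    # Choose a "last edge" for every non-terminal vertex such that the
    # chosen edges form a tree pointing at the terminal vertex.
    for _ in range(10_000):
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                if cur not in last_edge:  # dead end with no out-edge
                    ok = False
                    break
                cur = last_edge[cur]
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - rejection virtually always succeeds
        raise GenerationError("could not sample a valid last-edge tree")

    ordered: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        ordered[v] = rest

    out = [first]
    ptr = {v: 0 for v in vertices}
    cur = first
    for _ in range(len(seq) - 1):
        nxt = ordered[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


# --------------------------------------------------------------------------
# Labelled datasets
# --------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    id: str
    sequence: str
    label: int
    split: str = "train"


@dataclass
class LabeledSequenceSet:
    """Fixed-length binary-labelled sequences with train/dev/test splits."""

    task: str
    records: list[SequenceRecord]
    length: int
    provenance: dict = field(default_factory=dict)

    def subset(self, split: str) -> list[SequenceRecord]:
        return [r for r in self.records if r.split == split]

    def sequences(self, split: str | None = None) -> list[str]:
        recs = self.records if split is None else self.subset(split)
        return [r.sequence for r in recs]

    def labels(self, split: str | None = None) -> np.ndarray:
        recs = self.records if split is None else self.subset(split)
        return np.array([r.label for r in recs], dtype=int)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tsequence\tlabel\tsplit\n")
            for r in self.records:
                fh.write(f"{r.id}\t{r.sequence}\t{r.label}\t{r.split}\n")

    @classmethod
    def from_tsv(cls, path, task: str = "unknown") -> "LabeledSequenceSet":
        records = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("id\t"):
                raise ValueError("expected header 'id\\tsequence\\tlabel\\tsplit'")
            for line in fh:
                i, seq, lab, split = line.rstrip("\n").split("\t")
                records.append(SequenceRecord(i, seq, int(lab), split))
        length = len(records[0].sequence) if records else 0
        return cls(task=task, records=records, length=length)


def _implant(background: str, site: str, start: int) -> str:
    return background[:start] + site + background[start + len(site):]


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def split_dataset(ds: LabeledSequenceSet,
                  ratio: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0,
                  stratified: bool = True) -> LabeledSequenceSet:
    """Assign train/dev/test splits, stratified by label by default.

    Split sizes follow the ratio with largest-remainder rounding; the
    assignment is a deterministic function of ``seed``.
    """
    if abs(sum(ratio) - 1.0) > 1e-9:
        raise ValueError("ratio must sum to 1")
    rng = np.random.default_rng(seed)
    groups: list[list[int]]
    if stratified:
        by_label: dict[int, list[int]] = collections.defaultdict(list)
        for i, r in enumerate(ds.records):
            by_label[r.label].append(i)
        if any(len(v) == 0 for v in by_label.values()) or not by_label:
            raise ValueError("empty class under stratification")
        groups = [by_label[k] for k in sorted(by_label)]
    else:
        groups = [list(range(len(ds.records)))]

    names = ("train", "dev", "test")
    assignment = {}
    for idxs in groups:
        idxs = list(rng.permutation(idxs))
        n = len(idxs)
        sizes = [int(np.floor(r * n)) for r in ratio]
        rem = n - sum(sizes)
        # largest fractional remainders get the leftover records
        fracs = sorted(range(3), key=lambda j: -(ratio[j] * n - sizes[j]))
        for j in fracs[:rem]:
            sizes[j] += 1
        pos = 0
        for name, s in zip(names, sizes):
            for i in idxs[pos:pos + s]:
                assignment[i] = name
            pos += s
    records = [SequenceRecord(r.id, r.sequence, r.label, assignment[i])
               for i, r in enumerate(ds.records)]
    return LabeledSequenceSet(task=ds.task, records=records,
                              length=ds.length,
                              provenance={**ds.provenance,
                                          "split_ratio": list(ratio),
                                          "split_seed": seed})


def make_motif_discovery_dataset(motif: PWMotif, bg: BackgroundModel,
                                 n: int, L: int = 101, seed: int = 0,
                                 ratio=(0.8, 0.1, 0.1),
                                 center_motif: bool = False,
                                 ) -> LabeledSequenceSet:
    """Positives carry one implanted PWM instance; negatives are their
    dinucleotide-preserving shuffles."""
    w = motif.width
    if L <= w:
        raise ValueError(f"L={L} must exceed motif width {w}")
    if n % 2:
        raise ValueError("n must be even")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n // 2):
        background = generate_background(bg, L, rng)
        start = (L - w) // 2 if center_motif else int(rng.integers(0, L - w + 1))
        pos = _implant(background, sample_pwm_instance(motif, rng), start)
        neg = dinucleotide_shuffle(pos, rng)
        records.append(SequenceRecord(f"pos{i}", pos, 1))
        records.append(SequenceRecord(f"neg{i}", neg, 0))
    ds = LabeledSequenceSet(
        task="motif_discovery", records=records, length=L,
        provenance={"motif": motif.name, "n": n, "L": L, "seed": seed})
    return split_dataset(ds, ratio, seed=seed)


def make_motif_occupancy_dataset(motif: PWMotif, bg: BackgroundModel,
                                 n: int, L: int = 101, seed: int = 0,
                                 ratio=(0.8, 0.1, 0.1),
                                 gc_tol: float = 0.02,
                                 score_tol: float = 1.0,
                                 max_attempts: int = 1000,
                                 ) -> LabeledSequenceSet:
    """Centred-motif positives vs GC/strength-matched centred-motif
    negatives drawn from fresh background."""
    w = motif.width
    if L <= w:
        raise ValueError(f"L={L} must exceed motif width {w}")
    if n % 2:
        raise ValueError("n must be even")
    rng = np.random.default_rng(seed)
    start = (L - w) // 2
    records = []
    for i in range(n // 2):
        background = generate_background(bg, L, rng)
        site = sample_pwm_instance(motif, rng)
        pos = _implant(background, site, start)
        gc_pos = _gc_fraction(pos)
        score_pos = motif.log_likelihood(site)
        neg = None
        for _ in range(max_attempts):
            cand_bg = generate_background(bg, L, rng)
            cand_site = sample_pwm_instance(motif, rng)
            cand = _implant(cand_bg, cand_site, start)
            if (abs(_gc_fraction(cand) - gc_pos) <= gc_tol
                    and abs(motif.log_likelihood(cand_site) - score_pos)
                    <= score_tol):
                neg = cand
                break
        if neg is None:
            raise GenerationError(
                f"could not match GC/strength for record pos{i} "
                f"within {max_attempts} attempts")
        records.append(SequenceRecord(f"pos{i}", pos, 1))
        records.append(SequenceRecord(f"neg{i}", neg, 0))
    ds = LabeledSequenceSet(
        task="motif_occupancy", records=records, length=L,
        provenance={"motif": motif.name, "n": n, "L": L, "seed": seed,
                    "gc_tol": gc_tol, "score_tol": score_tol})
    return split_dataset(ds, ratio, seed=seed)


#: Hexamers implanted into non-TATA promoter positives as a stand-in for
#: regulatory k-mer bias (GC-box, CAAT-box, Inr-like).
REGULATORY_KMERS = ("GGGCGG", "CCAAT", "TCAGTC")


def make_promoter_dataset(tata_motif: PWMotif, bg: BackgroundModel,
                          n: int, L: int = 300,
                          variant: str = "tata", seed: int = 0,
                          ratio=(0.8, 0.1, 0.1),
                          canonical_start: int | None = None,
                          n_segments: int = 20,
                          n_substituted: int = 12,
                          ) -> LabeledSequenceSet:
    """300 bp promoter-window classification sets.

    ``tata`` variant: positives implant the TATA PWM at the canonical
    offset (default start 219, ~-30 from a TSS at index 249 of a
    -249..50 window); negatives implant the same PWM at a uniformly
    random non-canonical position, so motif presence alone cannot
    separate the classes.

    ``nontata`` variant: positives are background with regulatory
    hexamers implanted; each negative replaces ``n_substituted`` of
    ``n_segments`` equal segments of its source positive with fresh
    background.
    """
    if n % 2:
        raise ValueError("n must be even")
    if L < tata_motif.width + 2:
        raise ValueError("L too small for the motif")
    rng = np.random.default_rng(seed)
    w = tata_motif.width
    if canonical_start is None:
        canonical_start = 219 if L == 300 else (L - w) // 2
    records = []
    if variant == "tata":
        for i in range(n // 2):
            pos_bg = generate_background(bg, L, rng)
            pos = _implant(pos_bg, sample_pwm_instance(tata_motif, rng),
                           canonical_start)
            neg_bg = generate_background(bg, L, rng)
            while True:
                alt = int(rng.integers(0, L - w + 1))
                if abs(alt - canonical_start) >= w:
                    break
            neg = _implant(neg_bg, sample_pwm_instance(tata_motif, rng), alt)
            records.append(SequenceRecord(f"pos{i}", pos, 1))
            records.append(SequenceRecord(f"neg{i}", neg, 0))
        task = "promoter_tata"
    elif variant == "nontata":
        if not 0 < n_substituted <= n_segments:
            raise ValueError("need 0 < n_substituted <= n_segments")
        seg = L // n_segments
        for i in range(n // 2):
            pos = generate_background(bg, L, rng)
            for kmer in REGULATORY_KMERS:
                start = int(rng.integers(0, L - len(kmer) + 1))
                pos = _implant(pos, kmer, start)
            chosen = rng.choice(n_segments, size=n_substituted, replace=False)
            neg = pos
            for s in sorted(int(c) for c in chosen):
                lo = s * seg
                hi = L if s == n_segments - 1 else (s + 1) * seg
                neg = (neg[:lo] + generate_background(bg, hi - lo, rng)
                       + neg[hi:])
            records.append(SequenceRecord(f"pos{i}", pos, 1))
            records.append(SequenceRecord(f"neg{i}", neg, 0))
        task = "promoter_nontata"
    else:
        raise ValueError(f"unknown variant {variant!r}")
    ds = LabeledSequenceSet(
        task=task, records=records, length=L,
        provenance={"variant": variant, "n": n, "L": L, "seed": seed,
                    "canonical_start": canonical_start})
    return split_dataset(ds, ratio, seed=seed)


# --------------------------------------------------------------------------
# FASTA plumbing
# --------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str] | list[str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if isinstance(sequences, list):
        sequences = {f"seq{i}": s for i, s in enumerate(sequences)}
    recs = [SeqRecord(Seq(s), id=name, description="")
            for name, s in sequences.items()]
    SeqIO.write(recs, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(path, "fasta")}
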