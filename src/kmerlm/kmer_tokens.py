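"""Overlapping k-mer vocabulary, tokenization and contiguous-k masking.

A nucleotide string of length ``L`` is represented by its ``L - k + 1``
overlapping k-mers, so consecutive tokens share ``k - 1`` characters.
Masking is applied in contiguous runs of ``k`` tokens: a single masked
token is trivially recoverable from either unmasked neighbour (they pin
``k - 1`` of its characters), whereas an isolated run of ``k`` masked
tokens leaves exactly one underlying nucleotide undetermined.

Coordinates are 0-based and half-open throughout; interior token ``i``
covers source nucleotides ``[i, i + k)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"

#: Fixed special tokens, ids 0-4 in this order.
SPECIAL_TOKENS = ("[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]")

PAD_ID, UNK_ID, CLS_ID, SEP_ID, MASK_ID = range(5)

MAX_K = 8


class InputError(ValueError):
    """Invalid sequence input (non-ACGT character, too short, ...)."""


class ConsistencyError(ValueError):
    """Adjacent tokens do not overlap consistently."""


@dataclass(frozen=True)
class KmerVocabulary:
    """All ``4**k`` k-mers plus the 5 special tokens, with stable ids.

    Special tokens come first (ids 0-4), then k-mers in lexicographic
    order, giving ``4**k + 5`` tokens in total.
    """

    k: int
    tokens: tuple[str, ...]
    special_tokens: tuple[str, ...] = SPECIAL_TOKENS
    index: dict[str, int] = field(repr=False, default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def n_special(self) -> int:
        return len(self.special_tokens)

    @property
    def kmer_tokens(self) -> tuple[str, ...]:
        return self.tokens[self.n_special:]

    def is_special_id(self, token_id: int) -> bool:
        return 0 <= token_id < self.n_special

    def id_of(self, token: str) -> int:
        try:
            return self.index[token]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary (k={self.k})")

    def token_of(self, token_id: int) -> str:
        return self.tokens[token_id]

    def save_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for tok, i in self.index.items():
                fh.write(f"{tok}\t{i}\n")

    @classmethod
    def load_tsv(cls, path) -> "KmerVocabulary":
        pairs = []
        with open(path) as fh:
            for line in fh:
                tok, i = line.rstrip("\n").split("\t")
                pairs.append((int(i), tok))
        pairs.sort()
        tokens = tuple(tok for _, tok in pairs)
        specials = tuple(t for t in tokens if t.startswith("["))
        k = len(tokens[len(specials)])
        return cls(k=k, tokens=tokens, special_tokens=specials,
                   index={t: i for i, t in enumerate(tokens)})


def build_vocabulary(k: int) -> KmerVocabulary:
    """Build the vocabulary of all k-mers over ACGT plus special tokens.

    Parameters
    ----------
    k : int
        k-mer length, ``1 <= k <= 8``.

    Returns
    -------
    KmerVocabulary
        ``4**k + 5`` tokens: specials first, then lexicographic k-mers.
    """
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool):
        raise TypeError(f"k must be an integer, got {k!r}")
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    kmers = ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]
    tokens = tuple(SPECIAL_TOKENS) + tuple(kmers)
    return KmerVocabulary(
        k=k,
        tokens=tokens,
        index={t: i for i, t in enumerate(tokens)},
    )


def all_kmers(k: int) -> list[str]:
    """All k-mers over ACGT in lexicographic order."""
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]


@dataclass
class TokenSequence:
    """A tokenized nucleotide string.

    ``ids`` may carry a leading CLS and trailing SEP; the *interior*
    tokens are the overlapping k-mers of ``source`` in order.
    """

    vocab: KmerVocabulary
    ids: list[int]
    has_cls: bool = False
    has_sep: bool = False
    source: str | None = None

    @property
    def offset(self) -> int:
        """Index of the first interior token within ``ids``."""
        return 1 if self.has_cls else 0

    @property
    def n_interior(self) -> int:
        return len(self.ids) - int(self.has_cls) - int(self.has_sep)

    @property
    def interior_ids(self) -> list[int]:
        end = len(self.ids) - int(self.has_sep)
        return self.ids[self.offset:end]

    def interior_tokens(self) -> list[str]:
        return [self.vocab.token_of(i) for i in self.interior_ids]

    def to_text(self) -> str:
        """Whitespace-separated token line (interior tokens only)."""
        return " ".join(self.interior_tokens())


def tokenize(seq: str, vocab: KmerVocabulary,
             add_specials: bool = True) -> TokenSequence:
    """Convert a nucleotide string into its overlapping k-mer tokens.

    Raises
    ------
    InputError
        If ``seq`` contains a non-ACGT character (the message names the
        offending position) or is shorter than ``k``.
    """
    k = vocab.k
    for pos, ch in enumerate(seq):
        if ch not in ALPHABET:
            raise InputError(
                f"non-ACGT character {ch!r} at position {pos}")
    if len(seq) < k:
        raise InputError(
            f"sequence length {len(seq)} is shorter than k={k}")
    ids = [vocab.id_of(seq[i:i + k]) for i in range(len(seq) - k + 1)]
    if add_specials:
        ids = [CLS_ID] + ids + [SEP_ID]
    return TokenSequence(vocab=vocab, ids=ids, has_cls=add_specials,
                         has_sep=add_specials, source=seq)


def detokenize(ts: TokenSequence) -> str:
    """Reconstruct the unique nucleotide string behind a token sequence.

    The inverse of :func:`tokenize`; adjacent interior tokens must share
    an overlap of ``k - 1`` characters.

    Raises
    ------
    ConsistencyError
        Naming the first pair of adjacent tokens whose overlap breaks.
    """
    toks = ts.interior_tokens()
    if not toks:
        raise InputError("token sequence has no interior tokens")
    k = ts.vocab.k
    out = [toks[0]]
    for j in range(1, len(toks)):
        prev, cur = toks[j - 1], toks[j]
        if prev[1:] != cur[:-1] and k > 1:
            raise ConsistencyError(
                f"tokens {j - 1} and {j} overlap-inconsistent: "
                f"{prev!r} vs {cur!r}")
        out.append(cur[-1])
    return "".join(out)


@dataclass
class MaskingPlan:
    """Which token positions are masked, in contiguous runs of k.

    ``runs`` holds ``(start, length)`` pairs in ``ids`` coordinates;
    ``actions`` maps each masked position to one of ``mask-token``,
    ``random-token`` or ``keep`` (the BERT 80/10/10 recipe by default).
    """

    runs: list[tuple[int, int]]
    actions: dict[int, str]
    target_rate: float
    achieved_rate: float
    seed: int
    truncated: bool = False

    @property
    def masked_positions(self) -> list[int]:
        out: list[int] = []
        for start, length in self.runs:
            out.extend(range(start, start + length))
        return sorted(out)


def mask_contiguous(ts: TokenSequence, rate: float, rng_seed: int,
                    replace_probs: tuple[float, float, float] = (0.8, 0.1, 0.1),
                    ) -> MaskingPlan:
    """Sample non-overlapping runs of ``k`` contiguous masked tokens.

    The number of runs is ``max(1, round(rate * n / k))``; start
    positions are drawn uniformly without overlap by rejection sampling
    (greedy fallback if rejection stalls). Deterministic given
    ``rng_seed``.
    """
    k = ts.vocab.k
    n = ts.n_interior
    if n < k:
        raise InputError(f"need at least k={k} interior tokens, got {n}")
    if not 0.0 < rate < 1.0:
        raise ValueError(f"rate must be in (0, 1), got {rate}")
    if abs(sum(replace_probs) - 1.0) > 1e-9:
        raise ValueError("replace_probs must sum to 1")

    rng = np.random.default_rng(rng_seed)
    n_runs = max(1, round(rate * n / k))
    n_runs = min(n_runs, n // k)  # cannot pack more disjoint runs than this

    starts: list[int] = []
    max_start = n - k
    attempts = 0
    while len(starts) < n_runs and attempts < 200 * n_runs + 1000:
        cand = int(rng.integers(0, max_start + 1))
        attempts += 1
        if all(abs(cand - s) >= k for s in starts):
            starts.append(cand)
    if len(starts) < n_runs:
        # Greedy fallback over a shuffled list of feasible starts.
        feasible = [s for s in rng.permutation(max_start + 1)
                    if all(abs(s - t) >= k for t in starts)]
        for s in feasible:
            if len(starts) >= n_runs:
                break
            if all(abs(s - t) >= k for t in starts):
                starts.append(int(s))

    off = ts.offset
    runs = sorted((off + s, k) for s in starts)
    actions: dict[int, str] = {}
    p_mask, p_rand, _ = replace_probs
    for start, length in runs:
        for pos in range(start, start + length):
            u = rng.random()
            if u < p_mask:
                actions[pos] = "mask-token"
            elif u < p_mask + p_rand:
                actions[pos] = "random-token"
            else:
                actions[pos] = "keep"
    achieved = len(actions) / n
    return MaskingPlan(runs=runs, actions=actions, target_rate=rate,
                       achieved_rate=achieved, seed=rng_seed)


def apply_mask(ts: TokenSequence, plan: MaskingPlan,
               rng: np.random.Generator | None = None) -> list[int]:
    """Input ids after applying the plan's replacement actions.

    ``mask-token`` positions become ``[MASK]``; ``random-token``
    positions are replaced by a uniformly random k-mer token; ``keep``
    positions retain the original token (but are still predicted).
    """
    if rng is None:
        rng = np.random.default_rng(plan.seed + 1)
    vocab = ts.vocab
    ids = list(ts.ids)
    for pos in plan.masked_positions:
        action = plan.actions[pos]
        if action == "mask-token":
            ids[pos] = MASK_ID
        elif action == "random-token":
            ids[pos] = int(rng.integers(vocab.n_special, vocab.size))
    return ids


@dataclass
class InferabilityReport:
    """Per-nucleotide inferability status under a masking plan.

    status[i] is one of:

    - ``observed``  — covered by at least one unmasked token;
    - ``deducible`` — masked-only but forced to a single value by
      propagating overlap constraints from unmasked tokens;
    - ``free``      — masked-only with more than one consistent value.
    """

    status: list[str]
    count_free: int

    def positions(self, kind: str) -> list[int]:
        return [i for i, s in enumerate(self.status) if s == kind]


def analyze_inferability(ts: TokenSequence,
                         plan: MaskingPlan) -> InferabilityReport:
    """Classify each source nucleotide as observed, deducible or free.

    Candidate sets start at {A,C,G,T} per position; every unmasked
    interior token pins its ``k`` covered positions. Masked tokens
    impose no constraint (their value is unknown), so any masked-only
    position retaining >1 candidate is free. For an isolated interior
    run of exactly ``k`` masked tokens this leaves a single free
    nucleotide.
    """
    if ts.source is None:
        raise ValueError("token sequence carries no source string")
    k = ts.vocab.k
    L = len(ts.source)
    off = ts.offset
    masked = set(plan.masked_positions)
    for pos in masked:
        if pos < off or pos >= off + ts.n_interior:
            raise ValueError(f"plan position {pos} covers a special token")

    candidates: list[set[str]] = [set(ALPHABET) for _ in range(L)]
    for t in range(ts.n_interior):
        if (off + t) in masked:
            continue
        kmer = ts.vocab.token_of(ts.ids[off + t])
        for j, ch in enumerate(kmer):
            candidates[t + j] = {ch}

    observed = [False] * L
    for t in range(ts.n_interior):
        if (off + t) not in masked:
            for j in range(k):
                observed[t + j] = True

    status: list[str] = []
    for i in range(L):
        if observed[i]:
            status.append("observed")
        elif len(candidates[i]) == 1:
            status.append("deducible")
        else:
            status.append("free")
    count_free = sum(1 for s in status if s == "free")
    return InferabilityReport(status=status, count_free=count_free)


def non_trivial_label_space(vocab: KmerVocabulary) -> int:
    """Size of the label space once overlap-forced characters are fixed.

    A masked token flanked by unmasked neighbours has all but one
    character pinned, so only 4 nucleotide alternatives remain, plus the
    special-token labels: ``4 + 5``, independent of k.
    """
    return len(ALPHABET) + vocab.n_special


def write_token_lines(sequences, path) -> None:
    """Write token sequences as whitespace-separated lines."""
    with open(path, "w") as fh:
        for ts in sequences:
            fh.write(ts.to_text() + "\n")


def read_token_lines(path, vocab: KmerVocabulary) -> list[TokenSequence]:
    """Read whitespace-separated token lines into TokenSequences."""
    out = []
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if not toks:
                continue
            ids = [vocab.id_of(t) for t in toks]
            ts = TokenSequence(vocab=vocab, ids=ids)
            try:
                ts.source = detokenize(ts)
            except ConsistencyError:
                pass
            out.append(ts)
    return out
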