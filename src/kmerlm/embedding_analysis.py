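"""Geometry of k-mer embedding tables.

Quantifies the qualitative picture one gets from a 2-D projection:
k-mers sharing prefixes/suffixes clustering together (*overlap-
consistent representation*), and the four clusters indexed by the
central nucleotide. The neighbour statistic is tested against a
label-permutation null so "clusters are visible" becomes an empirical
p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .embeddings import EmbeddingTable, load_embedding_table  # noqa: F401
from .kmer_tokens import ALPHABET, all_kmers


def one_hot_table(k: int) -> EmbeddingTable:
    """Identity-matrix embedding of all ``4**k`` k-mers.

    Rows (and columns) are in lexicographic order; special tokens are
    not included. The dimension therefore grows as ``4**k`` (256 for
    4-mers, 1024 for 5-mers).
    """
    if not 1 <= k <= 8:
        raise ValueError(f"k must be in [1, 8], got {k}")
    labels = all_kmers(k)
    return EmbeddingTable(row_labels=labels,
                          matrix=np.eye(len(labels)),
                          source="one_hot", includes_specials=False)


def overlap_score(a: str, b: str) -> int:
    """Longest proper prefix/suffix overlap between two k-mers.

    The maximum ``m`` in ``[0, k-1]`` such that the length-m suffix of
    one argument equals the length-m prefix of the other (both
    directions are checked).
    """
    if len(a) != len(b):
        raise ValueError(
            f"length mismatch: {len(a)} vs {len(b)}")
    k = len(a)
    for m in range(k - 1, 0, -1):
        if a[k - m:] == b[:m] or b[k - m:] == a[:m]:
            return m
    return 0


def shared_affix_score(a: str, b: str) -> int:
    """Longest shared prefix or shared suffix between two k-mers.

    The maximum ``m`` in ``[0, k-1]`` with ``a[:m] == b[:m]`` or
    ``a[-m:] == b[-m:]``. This is the similarity behind the clustered
    k-mer pattern (families like CTCCN or NGCTT): tokens that can
    follow — or be followed by — the same neighbouring context share a
    long prefix or suffix.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    k = len(a)
    for m in range(k - 1, 0, -1):
        if a[:m] == b[:m] or a[k - m:] == b[k - m:]:
            return m
    return 0


SCORE_FUNCTIONS = {"shared_affix": shared_affix_score,
                   "overlap": overlap_score}


def overlap_matrix(labels: list[str],
                   score: str = "shared_affix") -> np.ndarray:
    """Pairwise score matrix (small k only; O(V^2 k))."""
    fn = SCORE_FUNCTIONS[score]
    n = len(labels)
    out = np.zeros((n, n), dtype=np.int16)
    for i in range(n):
        for j in range(i + 1, n):
            s = fn(labels[i], labels[j])
            out[i, j] = out[j, i] = s
    return out


@dataclass
class OverlapConsistencyReport:
    n_neighbors: int
    metric: str
    observed_mean_overlap: float
    null_mean: float
    null_sd: float
    permutations: int
    empirical_p: float
    z: float
    score: str = "shared_affix"

    def to_dict(self) -> dict:
        return {k: (float(v) if isinstance(v, (int, float, np.floating))
                    else v)
                for k, v in self.__dict__.items()}


def _check_kmer_table(table: EmbeddingTable) -> int:
    ks = {len(t) for t in table.row_labels}
    bad = [t for t in table.row_labels
           if any(c not in ALPHABET for c in t)]
    if bad or len(ks) != 1:
        raise ValueError(
            "table must contain k-mer rows only; exclude special tokens "
            "(e.g. via EmbeddingTable.kmers_only()) before analysis")
    return ks.pop()


def _neighbor_indices(table: EmbeddingTable, n_neighbors: int,
                      metric: str, seed: int = 0) -> np.ndarray:
    """n nearest neighbours per row (row indices), self excluded.

    Distance ties are broken by a seeded random rank: deterministic
    given the seed, but free of the prefix-sharing bias a lexicographic
    tie-break would inject into tie-heavy tables (e.g. one-hot, where
    all off-diagonal distances are equal).
    """
    dist = squareform(pdist(table.matrix, metric=metric))
    np.fill_diagonal(dist, np.inf)
    n = dist.shape[0]
    if n_neighbors > n - 1:
        raise ValueError("n_neighbors must be < number of rows")
    tie_rank = np.random.default_rng(seed).permutation(n)
    nb = np.empty((n, n_neighbors), dtype=int)
    for i in range(n):
        order = np.lexsort((tie_rank, dist[i]))
        nb[i] = order[:n_neighbors]
    return nb


def neighbor_overlap_statistic(table: EmbeddingTable, n_neighbors: int = 10,
                               metric: str = "cosine",
                               permutations: int = 999,
                               seed: int = 0,
                               score: str = "shared_affix",
                               ) -> OverlapConsistencyReport:
    """Mean prefix/suffix similarity with nearest neighbours vs a
    label-permutation null.

    observed = mean over all k-mers of the mean similarity score with
    their ``n_neighbors`` nearest rows. The null shuffles which label
    sits on which vector M times; ``empirical_p = (1 + #{null >=
    observed}) / (M + 1)``.

    ``score='shared_affix'`` (default) rewards neighbours sharing long
    common prefixes/suffixes — the clustered-family pattern learned
    embeddings actually exhibit. ``score='overlap'`` instead uses
    :func:`overlap_score` (suffix-of-one equals prefix-of-the-other),
    the adjacency notion used for masked-prediction consistency; that
    notion is near-orthogonal to affix-sharing proximity and is kept
    for comparison.
    """
    _check_kmer_table(table)
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    if metric not in ("cosine", "euclidean"):
        raise ValueError(f"unsupported metric {metric!r}")
    if score not in SCORE_FUNCTIONS:
        raise ValueError(f"unknown score {score!r}")
    nb = _neighbor_indices(table, n_neighbors, metric, seed=seed)
    labels = list(table.row_labels)
    ov = overlap_matrix(labels, score=score)
    rows = np.arange(len(labels))[:, None]
    observed = float(ov[rows, nb].mean())

    rng = np.random.default_rng(seed)
    null = np.empty(permutations)
    for m in range(permutations):
        perm = rng.permutation(len(labels))
        null[m] = ov[perm[rows], perm[nb]].mean()
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if permutations > 1 else 0.0
    p = float((1 + int((null >= observed).sum())) / (permutations + 1))
    z = (observed - null_mean) / null_sd if null_sd > 0 else np.inf
    return OverlapConsistencyReport(
        n_neighbors=n_neighbors, metric=metric,
        observed_mean_overlap=observed, null_mean=null_mean,
        null_sd=null_sd, permutations=permutations, empirical_p=p,
        z=float(z), score=score)


@dataclass
class SeparationReport:
    silhouette: float
    group_sizes: dict[str, int]
    metric: str = "cosine"


def central_nucleotide_separation(table: EmbeddingTable,
                                  metric: str = "cosine",
                                  ) -> SeparationReport:
    """Silhouette of the 4 classes given by each k-mer's central base.

    Requires odd k (otherwise there is no unique central position).
    For odd k the classes partition the ``4**k`` k-mers into 4 groups
    of ``4**(k-1)``.
    """
    k = _check_kmer_table(table)
    if k % 2 == 0:
        raise ValueError(
            f"central position undefined for even k={k}")
    centers = np.array([t[k // 2] for t in table.row_labels])
    sizes = {b: int((centers == b).sum()) for b in ALPHABET}
    if len(set(centers)) < 2:
        raise ValueError("need at least two central-base classes")
    sil = float(silhouette_score(table.matrix, centers, metric=metric))
    return SeparationReport(silhouette=sil, group_sizes=sizes,
                            metric=metric)


@dataclass
class Projection2D:
    coordinates: np.ndarray
    labels: list[str]
    params: dict = field(default_factory=dict)


def project_2d(table: EmbeddingTable, perplexity: float = 30.0,
               n_iter: int = 1000, seed: int = 0,
               plot_path=None) -> Projection2D:
    """t-SNE projection to 2-D, optionally rendering a scatter plot
    coloured by central nucleotide (specials in grey)."""
    from sklearn.manifold import TSNE

    if table.n_rows < 10:
        raise ValueError("need at least 10 rows to project")
    if np.allclose(table.matrix, table.matrix[0]):
        raise ValueError("degenerate table: all rows identical")
    tsne = TSNE(n_components=2, perplexity=min(perplexity,
                                               (table.n_rows - 1) / 3),
                max_iter=n_iter, random_state=seed, init="pca")
    coords = np.asarray(tsne.fit_transform(table.matrix), dtype=float)
    proj = Projection2D(coordinates=coords, labels=list(table.row_labels),
                        params={"perplexity": perplexity,
                                "n_iter": n_iter, "seed": seed})
    if plot_path is not None:
        _plot_projection(proj, plot_path)
    return proj


def _plot_projection(proj: Projection2D, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "tab:green", "T": "tab:red",
              "G": "tab:orange", "C": "tab:blue"}
    fig, ax = plt.subplots(figsize=(7, 6))
    lab = np.array([
        t[len(t) // 2] if all(c in ALPHABET for c in t) else "special"
        for t in proj.labels])
    for base in ["A", "T", "G", "C"]:
        sel = lab == base
        if sel.any():
            ax.scatter(proj.coordinates[sel, 0], proj.coordinates[sel, 1],
                       s=8, c=colors[base], label=base)
    sel = lab == "special"
    if sel.any():
        ax.scatter(proj.coordinates[sel, 0], proj.coordinates[sel, 1],
                   s=30, c="black", marker="x", label="special")
    ax.legend(title="central base", markerscale=2)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
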