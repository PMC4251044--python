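"""Unsupervised subtype discovery.

The pipeline trains a self-organizing map (SOM) on descriptor vectors,
treats the occupied neurons as an initial over-clustering, greedily merges
neuron pairs while the Davies-Bouldin index (DBI) keeps decreasing, and
hands the surviving cluster count and centroids to Lloyd k-means.  Because
SOM training is stochastic, the whole procedure is repeated many times
over a sweep of grid dimensions; the modal cluster count across runs is
taken as the number of subtypes, the best run (largest inter-minus-intra
cluster variance, then smallest DBI) provides the reference partition, and
a sample co-occurrence matrix summarizes the stability of the consensus.

Davies-Bouldin index
--------------------
For clusters ``C_1..C_k`` with centroids ``A_i``,

* ``S_i``  -- root-mean-square distance of members to their centroid
  (Minkowski exponent q = 2),
* ``M_ij`` -- Euclidean distance between centroids (order p = 2),
* ``R_ij = (S_i + S_j) / M_ij``, ``D_i = max_{j != i} R_ij``,
* ``DBI = mean_i D_i``.

Lower is better; coincident centroids (``M_ij = 0``) are rejected as
degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from seqsubtype.errors import DegenerateClusteringError, SeqSubtypeError

_MAX_SEED = 2**31


def _values(data) -> np.ndarray:
    """Accept a FeatureMatrix or a plain 2-D array."""
    if hasattr(data, "values") and hasattr(data, "row_ids"):
        return np.asarray(data.values, dtype=float)
    return np.asarray(data, dtype=float)


@dataclass(frozen=True)
class SOMGrid:
    """A trained rectangular SOM: prototypes plus best-matching-unit map."""

    rows: int
    cols: int
    prototypes: np.ndarray  # (rows*cols, d)
    bmu_of: np.ndarray  # (n,) neuron index per data point


@dataclass(frozen=True)
class ClusterModel:
    """One clustering: assignments, member-mean centroids and quality scores."""

    k: int
    centroids: np.ndarray  # (k, d)
    assignment: np.ndarray  # (n,) cluster index in 0..k-1
    dbi: float
    inter_var: float
    intra_var: float


@dataclass(frozen=True)
class ConsensusResult:
    """Outcome of repeated SOM -> merge -> k-means runs."""

    runs: tuple  # of (grid_dims, seed, ClusterModel)
    modal_k: int
    best_run: ClusterModel
    cooccurrence: np.ndarray = field(repr=False)


def train_som(
    data,
    rows: int,
    cols: int,
    iterations: int = 10_000,
    seed: int = 0,
    lr_start: float = 0.05,
    lr_end: float = 0.01,
    radius_end: float | None = None,
) -> SOMGrid:
    """Online SOM training on a rectangular grid.

    Prototypes are initialized by sampling data points.  Each iteration
    draws one random input, finds its best matching unit (BMU) by Euclidean
    distance, and pulls every prototype toward the input with a Gaussian
    neighborhood weight centred on the BMU.  The neighborhood radius decays
    linearly from ``max(rows, cols)/2`` to ``radius_end`` and the learning
    rate from ``lr_start`` to ``lr_end``.  Deterministic given ``seed``.

    By default the final radius is kept at 80% of the initial one (at
    least 1), so the map stays topographically stiff: neighbouring
    prototypes remain bunched and over-quantization of a single data mode
    into many crisp, well-separated micro-clusters is avoided.  That
    matters downstream -- the greedy DBI neuron merging only cascades
    correctly when the occupied neurons of one mode overlap.  A small
    ``radius_end`` (e.g. 0.5) instead yields a conventional fine-grained
    vector quantizer.
    """
    X = _values(data)
    if X.size == 0:
        raise ValueError("train_som requires non-empty data")
    n, d = X.shape
    m = rows * cols
    if m < 2:
        raise ValueError("SOM grid needs at least 2 neurons")
    rng = np.random.default_rng(seed)
    protos = X[rng.integers(0, n, size=m)].astype(float).copy()
    coords = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    r_start = max(rows, cols) / 2.0
    r_end = radius_end if radius_end is not None else max(1.0, 0.8 * r_start)
    denom = max(1, iterations - 1)
    for t in range(iterations):
        x = X[rng.integers(0, n)]
        frac = t / denom
        sigma = r_start + (r_end - r_start) * frac
        lr = lr_start + (lr_end - lr_start) * frac
        diff = x - protos
        bmu = int(np.argmin((diff * diff).sum(1)))
        h = np.exp(-grid_d2[bmu] / (2.0 * sigma * sigma))
        protos += (lr * h)[:, None] * diff
    bmu_of = np.argmin(cdist(X, protos, "sqeuclidean"), axis=1)
    return SOMGrid(rows=rows, cols=cols, prototypes=protos, bmu_of=bmu_of)


# ---------------------------------------------------------------------------
# Davies-Bouldin index


def _scatter(X: np.ndarray, members: np.ndarray, centroid: np.ndarray, q: float) -> float:
    dist = np.linalg.norm(X[members] - centroid, axis=1)
    return float((np.mean(dist**q)) ** (1.0 / q))


def _dbi_from_parts(S: np.ndarray, M: np.ndarray) -> float:
    k = len(S)
    R = (S[:, None] + S[None, :]) / np.where(M > 0, M, np.inf)
    np.fill_diagonal(R, -np.inf)
    return float(np.max(R, axis=1).mean())


def davies_bouldin(data, model: ClusterModel, q: float = 2.0, p: float = 2.0) -> float:
    """Davies-Bouldin index of a clustering (see module docstring).

    ``q`` is the scatter exponent (2 = root-mean-square member-to-centroid
    distance) and ``p`` the Minkowski order of the centroid separation.
    """
    X = _values(data)
    labels = np.asarray(model.assignment)
    k = model.k
    if k < 2:
        raise ValueError("davies_bouldin requires at least 2 clusters")
    members = [np.flatnonzero(labels == i) for i in range(k)]
    if any(m.size == 0 for m in members):
        raise DegenerateClusteringError("empty cluster")
    cents = np.asarray(model.centroids, dtype=float)
    S = np.array([_scatter(X, m, cents[i], q) for i, m in enumerate(members)])
    M = cdist(cents, cents, "minkowski", p=p)
    off = M[~np.eye(k, dtype=bool)]
    if np.any(off == 0):
        raise DegenerateClusteringError("coincident centroids (zero separation)")
    return _dbi_from_parts(S, M)


# ---------------------------------------------------------------------------
# neuron merging


def merge_to_k(som: SOMGrid, data, return_history: bool = False):
    """Greedy DBI-minimizing neuron merging.

    Empty neurons are dropped; the occupied neurons (with member-mean
    centroids) form the initial clustering.  At each step every distinct
    pair merge is evaluated; the candidate with the lowest DBI is accepted
    if it improves on the current DBI, otherwise merging stops.  Returns
    ``(k, centroids)``, plus the accepted-DBI trace if ``return_history``.

    Candidate DBIs are evaluated incrementally: the root-mean-square
    scatter of a merged cluster follows from cached member sums and
    sums-of-squares, so each candidate costs O(k + d) instead of a full
    re-clustering pass.
    """
    X = _values(data)
    members = [np.flatnonzero(som.bmu_of == j) for j in range(som.prototypes.shape[0])]
    clusters = [m for m in members if m.size > 0]
    if len(clusters) < 2:
        raise DegenerateClusteringError("fewer than 2 occupied neurons")

    sizes = np.array([m.size for m in clusters], dtype=float)
    sums = np.array([X[m].sum(axis=0) for m in clusters])
    ssq = np.array([(X[m] ** 2).sum() for m in clusters])
    cents = sums / sizes[:, None]

    def scatter_vec() -> np.ndarray:
        sq = ssq - sizes * (cents**2).sum(axis=1)
        return np.sqrt(np.maximum(sq, 0.0) / sizes)

    S = scatter_vec()
    M = cdist(cents, cents)
    if np.any(M[~np.eye(len(S), dtype=bool)] == 0):
        raise DegenerateClusteringError("coincident centroids among occupied neurons")

    history = [_dbi_from_parts(S, M)]
    while len(clusters) > 2:
        k = len(clusters)
        with np.errstate(divide="ignore", invalid="ignore"):
            R = (S[:, None] + S[None, :]) / M
        np.fill_diagonal(R, -np.inf)
        best = None  # (dbi, i, j)
        for i in range(k):
            for j in range(i + 1, k):
                n_m = sizes[i] + sizes[j]
                mc = (sums[i] + sums[j]) / n_m
                sq = ssq[i] + ssq[j] - n_m * float(mc @ mc)
                S_m = np.sqrt(max(sq, 0.0) / n_m)
                keep = np.ones(k, dtype=bool)
                keep[i] = keep[j] = False
                d_m = np.linalg.norm(cents[keep] - mc, axis=1)
                if np.any(d_m == 0):
                    continue
                R_m = (S[keep] + S_m) / d_m
                D_keep = np.maximum(R[keep][:, keep].max(axis=1), R_m)
                dbi = (D_keep.sum() + R_m.max()) / (k - 1)
                if best is None or dbi < best[0] - 1e-15:
                    best = (dbi, i, j)
        if best is None or best[0] >= history[-1]:
            break
        dbi, i, j = best
        keep_idx = [t for t in range(k) if t not in (i, j)]
        clusters = [clusters[t] for t in keep_idx] + [np.concatenate([clusters[i], clusters[j]])]
        sizes = np.append(sizes[keep_idx], sizes[i] + sizes[j])
        sums = np.vstack([sums[keep_idx], sums[i] + sums[j]])
        ssq = np.append(ssq[keep_idx], ssq[i] + ssq[j])
        cents = sums / sizes[:, None]
        S = scatter_vec()
        M = cdist(cents, cents)
        history.append(dbi)

    out = (len(clusters), cents.copy())
    if return_history:
        return out + (history,)
    return out


# ---------------------------------------------------------------------------
# k-means and run bookkeeping


def intra_cluster_variance(data, model: ClusterModel) -> float:
    """Mean Euclidean distance of points to their own cluster centroid."""
    X = _values(data)
    cents = np.asarray(model.centroids)
    return float(np.linalg.norm(X - cents[model.assignment], axis=1).mean())


def inter_cluster_variance(model: ClusterModel) -> float:
    """Mean pairwise Euclidean distance between cluster centroids."""
    cents = np.asarray(model.centroids)
    k = cents.shape[0]
    if k < 2:
        return 0.0
    D = cdist(cents, cents)
    return float(D[np.triu_indices(k, 1)].mean())


def kmeans_seeded(data, centroids, max_iter: int = 300) -> ClusterModel:
    """Lloyd k-means from given starting centroids.

    Iterates assignment (nearest centroid, ties to the lowest index) and
    member-mean centroid updates until the assignment is stable or
    ``max_iter`` passes.  A cluster that empties is re-seeded with the
    point currently farthest from its own centroid.
    """
    X = _values(data)
    cents = np.asarray(centroids, dtype=float).copy()
    k = cents.shape[0]
    n = X.shape[0]
    if k < 2:
        raise ValueError("kmeans_seeded requires k >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    labels = np.full(n, -1)
    for _ in range(max_iter):
        new_labels = np.argmin(cdist(X, cents, "sqeuclidean"), axis=1)
        for j in range(k):
            if not np.any(new_labels == j):
                dists = np.linalg.norm(X - cents[new_labels], axis=1)
                far = int(np.argmax(dists))
                cents[j] = X[far]
                new_labels[far] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            cents[j] = X[labels == j].mean(axis=0)
    model = ClusterModel(
        k=k, centroids=cents, assignment=labels, dbi=np.nan, inter_var=np.nan, intra_var=np.nan
    )
    dbi = davies_bouldin(X, model)
    return ClusterModel(
        k=k,
        centroids=cents,
        assignment=labels,
        dbi=dbi,
        inter_var=inter_cluster_variance(model),
        intra_var=intra_cluster_variance(X, model),
    )


def cooccurrence_matrix(assignments: list[np.ndarray]) -> np.ndarray:
    """Count, for every sample pair, how many runs place them together.

    Symmetric; the diagonal equals the number of runs.
    """
    if not assignments:
        raise ValueError("cooccurrence_matrix requires at least one assignment")
    n = len(assignments[0])
    out = np.zeros((n, n), dtype=int)
    for a in assignments:
        a = np.asarray(a)
        if len(a) != n:
            raise ValueError("all assignments must cover the same samples")
        out += a[:, None] == a[None, :]
    return out


def consensus(
    data,
    grid_dims: list[tuple[int, int]],
    runs_per_dim: int = 500,
    base_seed: int = 0,
    iterations: int = 10_000,
) -> ConsensusResult:
    """Repeated SOM -> merge -> k-means with modal-k selection.

    Each run uses a distinct seed derived from ``base_seed``.  The modal
    cluster count across all runs (ties to the smaller k) is the consensus
    number of subtypes; among runs reaching it, the best run maximizes
    ``inter_var - intra_var`` with ties broken by smaller DBI, then by
    smaller per-run seed.  Degenerate runs (a single occupied neuron) are
    recorded as skipped and excluded from voting.
    """
    X = _values(data)
    if runs_per_dim < 1:
        raise ValueError("runs_per_dim must be >= 1")
    total = len(grid_dims) * runs_per_dim
    seeds = np.random.SeedSequence(base_seed).generate_state(total) % _MAX_SEED
    runs = []
    assignments = []
    idx = 0
    for dims in grid_dims:
        rows, cols = dims
        for _ in range(runs_per_dim):
            seed = int(seeds[idx])
            idx += 1
            som = train_som(X, rows, cols, iterations=iterations, seed=seed)
            try:
                k, cents = merge_to_k(som, X)
                model = kmeans_seeded(X, cents)
            except DegenerateClusteringError:
                continue
            runs.append((dims, seed, model))
            assignments.append(model.assignment)
    if not runs:
        raise DegenerateClusteringError("every consensus run was degenerate")
    ks = np.array([m.k for _, _, m in runs])
    vals, counts = np.unique(ks, return_counts=True)
    modal_k = int(vals[counts == counts.max()].min())
    candidates = [(d, s, m) for d, s, m in runs if m.k == modal_k]
    best = min(candidates, key=lambda r: (-(r[2].inter_var - r[2].intra_var), r[2].dbi, r[1]))
    return ConsensusResult(
        runs=tuple(runs),
        modal_k=modal_k,
        best_run=best[2],
        cooccurrence=cooccurrence_matrix(assignments),
    )
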