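"""Convex non-negative matrix factorization of condition-averaged responses.

Electrodes are clustered by the shape of their condition-averaged amplitude
timecourses.  With the data arranged as X (time-condition features x
electrodes), convex NMF finds X ~ F G^T with F = X W, i.e. the cluster
centroids F are constrained to convex combinations of the data columns
(electrodes), which keeps them interpretable as prototypical timecourses
even though X is mixed-sign (z-units).  W (electrodes x rank) holds the
non-negative mixing weights and G (electrodes x rank) the non-negative
cluster memberships; the hard electrode assignment is the argmax over G.

The factors are fitted with the multiplicative updates of Ding, Li & Jordan
(convex-NMF variant of semi-NMF), initialized from a k-means partition of
the electrodes, with restarts; the squared reconstruction error
||X - X W G^T||^2 is non-increasing over iterations.

Rank selection uses four internal validity indices on the electrode
partition -- Wemmert-Gancarski, PBM, and the WB-index on the hard
assignments, plus the fuzzy Xie-Beni index on the normalized memberships --
combined by majority vote over the per-index optima (ties -> smallest rank).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .epochs import ConditionMatrix

_EPS = 1e-12


@dataclass
class Decomposition:
    """Fitted convex-NMF factors and the derived electrode partition."""

    W: np.ndarray  # electrodes x rank, non-negative mixing weights
    G: np.ndarray  # electrodes x rank, non-negative memberships
    F: np.ndarray  # features x rank, centroid timecourses (= X W)
    rank: int
    assignments: np.ndarray  # per-electrode hard label in [1, rank]
    reconstruction_error: float  # ||X - F G^T||^2 at convergence
    error_trace: np.ndarray  # per-iteration error of the winning restart
    seed: int | None
    n_restarts: int


@dataclass
class ValidityReport:
    """Validity-index values per candidate rank and the chosen rank."""

    ranks: list[int]
    indices: dict[str, dict[int, float]]  # index name -> rank -> value
    preferred: dict[str, int]  # index name -> preferred rank
    chosen_rank: int
    decompositions: dict[int, Decomposition]


def _as_feature_matrix(X) -> tuple[np.ndarray, int]:
    """Return (features x electrodes matrix, n_electrodes)."""
    if isinstance(X, ConditionMatrix):
        M = X.data.T  # electrodes are columns
    else:
        M = np.asarray(X, dtype=float)
    if M.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if not np.all(np.isfinite(M)):
        raise ValueError("X must be finite; impute NaN first (impute_nan_linear)")
    return M, M.shape[1]


def _init_factors(
    X: np.ndarray, rank: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """k-means-based initialization: G = H + 0.2, W = (H + 0.2) Dn^-1."""
    n = X.shape[1]
    seed = int(rng.integers(2**31 - 1))
    _, labels = kmeans2(X.T, rank, minit="++", seed=seed)
    # guard: kmeans2 may return empty clusters; reassign round-robin
    for k in range(rank):
        if not np.any(labels == k):
            labels[int(rng.integers(n))] = k
    H = np.zeros((n, rank))
    H[np.arange(n), labels] = 1.0
    sizes = H.sum(axis=0)
    G = H + 0.2
    W = (H + 0.2) / (sizes + 0.2 * n)[None, :]
    return W, G


def _cnmf_error(Y: np.ndarray, W: np.ndarray, G: np.ndarray, trX: float) -> float:
    """||X - XWG'||^2 via the Gram matrix Y = X'X."""
    YW = Y @ W
    return float(trX - 2.0 * np.sum(G * YW) + np.sum((W.T @ YW) * (G.T @ G)))


def cnmf_fit(
    X,
    rank: int,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 10,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> Decomposition:
    """Fit convex NMF of a condition matrix at a given rank.

    ``X`` is a ConditionMatrix (electrodes x features) or an ndarray
    (features x electrodes).  Runs ``n_restarts`` multiplicative-update
    optimizations from k-means initializations (plus the optional explicit
    ``init`` as an extra restart) and returns the restart with the smallest
    squared reconstruction error.  Iteration stops when the relative error
    improvement falls below ``tol``; an update that would increase the error
    is rejected, so the error trace is non-increasing.
    """
    M, n = _as_feature_matrix(X)
    if rank <= 1:
        raise ValueError("rank must be >= 2")
    if rank >= min(M.shape):
        raise ValueError(f"rank {rank} must be < min(matrix dimensions) {min(M.shape)}")
    rng = np.random.default_rng(seed)
    Y = M.T @ M
    Yp = (np.abs(Y) + Y) / 2.0
    Ym = (np.abs(Y) - Y) / 2.0
    trX = float(np.trace(Y))

    best: tuple[float, np.ndarray, np.ndarray, np.ndarray] | None = None
    inits = [init] if init is not None else []
    inits += [None] * n_restarts
    for ini in inits:
        W, G = ini if ini is not None else _init_factors(M, rank, rng)
        W, G = W.copy(), G.copy()
        err = _cnmf_error(Y, W, G, trX)
        trace = [err]
        for _ in range(max_iter):
            GtG = G.T @ G
            num = Yp @ W + G @ (W.T @ Ym @ W)
            den = Ym @ W + G @ (W.T @ Yp @ W)
            G_new = G * np.sqrt((num + _EPS) / (den + _EPS))
            GtG = G_new.T @ G_new
            num = Yp @ G_new + Ym @ W @ GtG
            den = Ym @ G_new + Yp @ W @ GtG
            W_new = W * np.sqrt((num + _EPS) / (den + _EPS))
            new_err = _cnmf_error(Y, W_new, G_new, trX)
            if new_err > trace[-1] + 1e-9 * max(abs(trace[-1]), 1.0):
                break  # reject a (numerically) ascending step
            W, G = W_new, G_new
            trace.append(new_err)
            if trace[-2] - trace[-1] <= tol * max(abs(trace[-2]), _EPS):
                break
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], W, G, np.array(trace))

    err, W, G, trace = best
    return Decomposition(
        W=W, G=G, F=M @ W, rank=rank,
        assignments=np.argmax(G, axis=1) + 1,
        reconstruction_error=err, error_trace=trace,
        seed=seed, n_restarts=n_restarts,
    )


# ---------------------------------------------------------------------------
# internal validity indices
# ---------------------------------------------------------------------------

def _centroids(points: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Cluster-weighted means of the electrode feature vectors (k x d)."""
    wsum = G.sum(axis=0)
    return (G.T @ points) / (wsum[:, None] + _EPS)


def wemmert_gancarski_index(points: np.ndarray, labels: np.ndarray,
                            centroids: np.ndarray) -> float:
    """Mean of per-cluster max(0, 1 - mean(d_own / d_nearest_other)); maximize."""
    d = cdist(points, centroids)
    n, k = d.shape
    own = d[np.arange(n), labels]
    d_other = d.copy()
    d_other[np.arange(n), labels] = np.inf
    ratio = own / (d_other.min(axis=1) + _EPS)
    total = 0.0
    for c in range(k):
        m = labels == c
        if m.any():
            total += m.sum() * max(0.0, 1.0 - ratio[m].mean())
    return total / n


def pbm_index(points: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """((1/K) * (E1/EK) * DK)^2 with E = summed distances to centroids; maximize."""
    k = centroids.shape[0]
    e1 = float(np.linalg.norm(points - points.mean(axis=0), axis=1).sum())
    ek = float(np.linalg.norm(points - centroids[labels], axis=1).sum())
    dk = float(cdist(centroids, centroids).max())
    return ((e1 * dk) / (k * ek + _EPS)) ** 2


def wb_index(points: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """K * SSW / SSB; minimize."""
    k = centroids.shape[0]
    ssw = float(np.sum((points - centroids[labels]) ** 2))
    grand = points.mean(axis=0)
    counts = np.bincount(labels, minlength=k).astype(float)
    ssb = float(np.sum(counts[:, None] * (centroids - grand) ** 2))
    return k * ssw / (ssb + _EPS)


def xie_beni_index(points: np.ndarray, memberships: np.ndarray,
                   centroids: np.ndarray, m: float = 2.0) -> float:
    """Fuzzy compactness / separation: sum u^m d^2 / (n min_jk d(c_j,c_k)^2); minimize."""
    d2 = cdist(points, centroids) ** 2
    num = float(np.sum(memberships**m * d2))
    cd2 = cdist(centroids, centroids) ** 2
    np.fill_diagonal(cd2, np.inf)
    return num / (points.shape[0] * (cd2.min() + _EPS))


def select_rank(
    X,
    candidate_ranks=range(2, 7),
    seed: int | None = None,
    n_restarts: int = 10,
    max_iter: int = 500,
) -> ValidityReport:
    """Fit every candidate rank and choose one by validity-index vote.

    Each rank k > min(candidates) gets one extra warm-started restart grown
    from the previous rank's solution (appending a small extra component),
    which also guarantees the best-of-restarts error is non-increasing in
    rank.  Per index the preferred rank is its optimum (max for
    Wemmert-Gancarski and PBM, min for WB and Xie-Beni); the chosen rank is
    the majority vote with ties broken toward the smallest rank.
    """
    M, n = _as_feature_matrix(X)
    points = M.T  # electrodes as rows
    ranks = sorted(candidate_ranks)
    indices: dict[str, dict[int, float]] = {
        "wemmert_gancarski": {}, "pbm": {}, "wb": {}, "xie_beni": {}
    }
    decomps: dict[int, Decomposition] = {}
    prev: Decomposition | None = None
    for r in ranks:
        init = None
        if prev is not None:
            W0 = np.column_stack([prev.W, np.full(n, 1.0 / n)])[:, :r]
            G0 = np.column_stack([prev.G, np.full(n, 0.2)])[:, :r]
            init = (W0, G0)
        dec = cnmf_fit(M, r, seed=seed, max_iter=max_iter,
                       n_restarts=n_restarts, init=init)
        decomps[r] = dec
        labels = dec.assignments - 1
        G = dec.G
        U = G / (G.sum(axis=1, keepdims=True) + _EPS)
        cents = _centroids(points, G)
        indices["wemmert_gancarski"][r] = wemmert_gancarski_index(points, labels, cents)
        indices["pbm"][r] = pbm_index(points, labels, cents)
        indices["wb"][r] = wb_index(points, labels, cents)
        indices["xie_beni"][r] = xie_beni_index(points, U, cents)
        prev = dec

    larger_better = {"wemmert_gancarski": True, "pbm": True, "wb": False, "xie_beni": False}
    preferred = {}
    for name, vals in indices.items():
        keyfun = (lambda r: (-vals[r], r)) if larger_better[name] else (lambda r: (vals[r], r))
        preferred[name] = min(ranks, key=keyfun)
    votes = np.array([preferred[name] for name in indices])
    counts = {r: int(np.sum(votes == r)) for r in set(votes)}
    top = max(counts.values())
    chosen = min(r for r, c in counts.items() if c == top)
    return ValidityReport(
        ranks=ranks, indices=indices, preferred=preferred,
        chosen_rank=int(chosen), decompositions=decomps,
    )


# ---------------------------------------------------------------------------
# imputation and projection
# ---------------------------------------------------------------------------

def impute_nan_linear(matrix: np.ndarray) -> np.ndarray:
    """Replace NaN runs by linear interpolation along the last axis.

    Leading/trailing NaN are filled with the nearest finite value.  A row
    with fewer than 2 finite values raises an error naming the row.
    """
    out = np.array(matrix, dtype=float, copy=True)
    flat = out.reshape(-1, out.shape[-1])
    idx = np.arange(out.shape[-1])
    for i, row in enumerate(flat):
        m = np.isnan(row)
        if not m.any():
            continue
        if (~m).sum() < 2:
            raise ValueError(f"row {i} has fewer than 2 finite values; cannot impute")
        row[m] = np.interp(idx[m], idx[~m], row[~m])
    return out


def impute_tensor(z: np.ndarray) -> np.ndarray:
    """Unfold electrodes x time x trials along trials, impute, refold."""
    e, t, n = z.shape
    unfolded = np.transpose(z, (0, 2, 1)).reshape(e, n * t)
    imputed = impute_nan_linear(unfolded)
    return np.transpose(imputed.reshape(e, n, t), (0, 2, 1))


def project_weights(W: np.ndarray, tensor) -> np.ndarray:
    """Project spatial weights onto a trial tensor: clusters x time x trials.

    Each cluster timecourse is the weighted average over electrodes using
    the corresponding column of W normalized to sum to 1.  The tensor must
    be NaN-free (impute first with impute_tensor / impute_nan_linear).
    """
    z = tensor.z if hasattr(tensor, "z") else np.asarray(tensor, dtype=float)
    if z.ndim != 3:
        raise ValueError("tensor must be electrodes x time x trials")
    if W.shape[0] != z.shape[0]:
        raise ValueError(
            f"W has {W.shape[0]} electrodes but tensor has {z.shape[0]}"
        )
    if np.isnan(z).any():
        raise ValueError("tensor contains NaN; impute before projecting")
    Wn = W / (W.sum(axis=0, keepdims=True) + _EPS)
    return np.einsum("ec,etn->ctn", Wn, z)


# ---------------------------------------------------------------------------
# partition comparison
# ---------------------------------------------------------------------------

def adjusted_rand_index(labels_a, labels_b) -> tuple[float, float]:
    """Adjusted Rand index and percent agreement between two partitions.

    ARI is the permutation-model chance-corrected Rand index computed from
    the contingency table (1 = identical partitions, 0 = chance-level
    similarity).  The second return value is the raw percent agreement
    (0-100) under the optimal one-to-one label matching (Hungarian
    assignment), as used for "X% of electrodes assigned to the same
    cluster" summaries.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    cont = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial
        ari = 1.0
    else:
        ari = float((sum_ij - expected) / (max_index - expected))
    row, col = linear_sum_assignment(-cont)
    agreement = 100.0 * cont[row, col].sum() / n
    return ari, float(agreement)
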