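"""Clustering fitted models by the shape of their covariate response curves.

Each retained model (one zooplankton group x net x metric) contributes a
multivariate series: its covariate-specific smooth curves on the common
1-100 index grid, stacked as dimensions (one per covariate, shared order).
Curves are z-scored per covariate before stacking so dynamic time warping
compares shapes, not amplitudes.  DTW distances (dependent-dimension
alignment: one shared warping path, Euclidean local cost across dimensions,
symmetric steps, no window) feed partitioning-around-medoids clustering over
k = 2..10; five validity indices vote for the cluster number, and classical
(Torgerson) multidimensional scaling embeds the models in 2-D.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from .gam import SmoothCurveSet

log = logging.getLogger(__name__)

DEV_THRESHOLD = 0.40
K_RANGE = range(2, 11)


@dataclass
class CurveSeries:
    model_id: str
    values: np.ndarray           # (length, n_dims): grid index x covariate
    dimensions: list[str]


@dataclass
class Clustering:
    k: int
    medoids: list[str]
    assignment: dict[str, int]
    cost: float


@dataclass
class ValidityIndices:
    calinski_harabasz: float
    dunn: float
    mean_silhouette: float
    davies_bouldin: float
    davies_bouldin_modified: float


# ---------------------------------------------------------------------------
# series assembly
# ---------------------------------------------------------------------------

def assemble_series(curve_sets: list[SmoothCurveSet],
                    dev_threshold: float = DEV_THRESHOLD,
                    standardize: str = "weighted") -> list[CurveSeries]:
    """Turn curve sets with %Dev above the threshold into DTW-ready series.

    Covariate order is fixed across the comparison set (union of all curve
    vocabularies, sorted); a model lacking a covariate contributes a
    zero-filled dimension (logged).

    Standardization modes:

    ``weighted`` (default)
        each curve is z-scored over its 100 grid points and then rescaled
        by its amplitude relative to the model's strongest curve.  Pure
        z-scoring gives a barely-wiggling spurious term the same weight as
        the dominant response; amplitude weighting keeps the comparison
        about shape while letting a term's weight reflect how much of the
        response it actually carries.
    ``zscore``
        plain per-curve z-scoring (shape only, all responding terms equal).
    ``raw``
        no standardization (amplitudes compared directly).
    """
    if standardize not in ("weighted", "zscore", "raw"):
        raise ValueError(f"unknown standardization {standardize!r}")
    retained = [cs for cs in curve_sets if cs.pct_dev > dev_threshold]
    if len(retained) < 3:
        raise ValueError(f"need >= 3 models above %Dev {dev_threshold}, "
                         f"got {len(retained)}")
    dims = sorted({c for cs in retained for c in cs.curves})
    out = []
    for cs in retained:
        raw, amp = {}, {}
        for d in dims:
            if d not in cs.curves:
                log.info("model %s lacks covariate %s; zero-filled",
                         cs.model_id, d)
                raw[d] = np.zeros(100)
                amp[d] = 0.0
            else:
                raw[d] = cs.curves[d]["value"].to_numpy(float)
                # amplitude = the term's spread over the observed data when
                # known (its contribution to the response), else grid spread
                amp[d] = float(cs.data_sd.get(d, raw[d].std()))
        max_amp = max(amp.values(), default=0.0)
        cols = []
        for d in dims:
            v = raw[d]
            sd = v.std()
            if standardize == "raw" or sd == 0:
                cols.append(v if sd > 0 else np.zeros(100))
                continue
            zc = (v - v.mean()) / sd
            if standardize == "weighted" and max_amp > 0:
                zc = zc * (amp[d] / max_amp)
            cols.append(zc)
        out.append(CurveSeries(model_id=cs.model_id,
                               values=np.column_stack(cols),
                               dimensions=dims))
    return out


# ---------------------------------------------------------------------------
# dynamic time warping
# ---------------------------------------------------------------------------

def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Unconstrained DTW distance between two (length, dims) series.

    Local cost is the Euclidean norm across dimensions; the alignment uses
    the symmetric step pattern D(i,j) = c(i,j) + min(D(i-1,j), D(i,j-1),
    D(i-1,j-1)) with no window and no path normalization.
    """
    A = np.asarray(a, float)
    B = np.asarray(b, float)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    if A.shape[1] != B.shape[1]:
        raise ValueError("series must share the dimension count")
    # full local-cost matrix
    diff = A[:, None, :] - B[None, :, :]
    C = np.sqrt(np.sum(diff * diff, axis=2))
    n, m = C.shape
    D = np.full((n, m), np.inf)
    D[0, 0] = C[0, 0]
    D[0, 1:] = C[0, 1:].cumsum() + C[0, 0]
    D[1:, 0] = C[1:, 0].cumsum() + C[0, 0]
    for i in range(1, n):
        row_prev = D[i - 1]
        row = D[i]
        for j in range(1, m):
            row[j] = C[i, j] + min(row_prev[j], row[j - 1], row_prev[j - 1])
    return float(D[n - 1, m - 1])


def dtw_matrix(series: list[CurveSeries]) -> pd.DataFrame:
    """Symmetric zero-diagonal DTW distance matrix over all series pairs."""
    if len(series) < 3:
        raise ValueError("need at least 3 series")
    ids = [s.model_id for s in series]
    n = len(series)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dtw_distance(series[i].values, series[j].values)
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# partitioning around medoids
# ---------------------------------------------------------------------------

def _pam_cost(D: np.ndarray, medoids: list[int]) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < k:
        cur = D[:, medoids].min(axis=1)
        gains = np.array([np.minimum(cur, D[:, c]).sum() if c not in medoids
                          else np.inf for c in range(n)])
        medoids.append(int(np.argmin(gains)))
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    n = D.shape[0]
    medoids = list(medoids)
    cost = _pam_cost(D, medoids)
    improved = True
    while improved:
        improved = False
        best = (cost, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                cand = medoids[:mi] + [h] + medoids[mi + 1:]
                c = _pam_cost(D, cand)
                if c < best[0] - 1e-12:
                    best = (c, mi, h)
        if best[1] is not None:
            cost, mi, h = best
            medoids[mi] = h
            improved = True
    return medoids, cost


def pam_cluster(D: pd.DataFrame, k: int, restarts: int = 10,
                seed: int = 0) -> Clustering:
    """PAM: greedy BUILD then steepest-descent SWAP, best of random restarts.

    Restart 0 starts from the deterministic BUILD medoids; the remaining
    restarts start from random medoid sets (seeded), which randomizes
    tie-breaking between equal-cost local optima.
    """
    ids = list(D.index)
    M = D.to_numpy(float)
    n = len(ids)
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    best_medoids, best_cost = _pam_swap(M, _pam_build(M, k))
    for _ in range(max(restarts - 1, 0)):
        start = list(rng.choice(n, size=k, replace=False))
        med, cost = _pam_swap(M, start)
        if cost < best_cost - 1e-12:
            best_medoids, best_cost = med, cost
    order = np.argsort(best_medoids)
    medoids = [best_medoids[i] for i in order]
    assign_idx = np.array(medoids)[np.argmin(M[:, medoids], axis=1)]
    # medoids are always their own cluster (zero self-distance wins ties)
    for m in medoids:
        assign_idx[m] = m
    label_of = {m: c + 1 for c, m in enumerate(medoids)}
    assignment = {ids[i]: label_of[assign_idx[i]] for i in range(n)}
    return Clustering(k=k, medoids=[ids[m] for m in medoids],
                      assignment=assignment, cost=best_cost)


# ---------------------------------------------------------------------------
# classical MDS
# ---------------------------------------------------------------------------

@dataclass
class MDSResult:
    coords: pd.DataFrame          # model_id x dim columns
    eigenvalues: np.ndarray       # all eigenvalues of the centred matrix
    n_clipped: int                # negative eigenvalues clipped to zero


def classical_mds(D: pd.DataFrame, dim: int = 2) -> MDSResult:
    """Torgerson scaling: B = -1/2 J (D*D) J, top-``dim`` eigenpairs.

    Negative eigenvalues (DTW distances need not be Euclidean) are clipped
    to zero and their count reported.
    """
    ids = list(D.index)
    M = D.to_numpy(float)
    n = M.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (M * M) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_clipped = int((evals < -1e-9 * max(abs(evals).max(), 1.0)).sum())
    pos = np.clip(evals[:dim], 0.0, None)
    coords = evecs[:, :dim] * np.sqrt(pos)[None, :]
    df = pd.DataFrame(coords, index=ids,
                      columns=[f"dim{i + 1}" for i in range(dim)])
    return MDSResult(coords=df, eigenvalues=evals, n_clipped=n_clipped)


# ---------------------------------------------------------------------------
# validity indices and k selection
# ---------------------------------------------------------------------------

def validity_indices(D: pd.DataFrame, clustering: Clustering,
                     mds_coords: pd.DataFrame) -> ValidityIndices:
    """Five cluster-validity indices for one clustering.

    Silhouette and Dunn work directly on the distance matrix; Calinski-
    Harabasz and both Davies-Bouldin variants need centroids and use the
    MDS coordinates.  Singleton silhouettes are zero by convention; the
    modified Davies-Bouldin is the max-separation variant (DB*).
    """
    ids = list(D.index)
    labels = np.array([clustering.assignment[i] for i in ids])
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 non-empty clusters")
    M = D.to_numpy(float)

    sil = float(skmetrics.silhouette_score(M, labels, metric="precomputed")) \
        if len(uniq) < len(ids) else 0.0

    # Dunn: min between-cluster distance over max within-cluster diameter
    min_between = np.inf
    max_diam = 0.0
    for a in uniq:
        ia = np.nonzero(labels == a)[0]
        if len(ia) > 1:
            max_diam = max(max_diam, float(M[np.ix_(ia, ia)].max()))
        for b in uniq:
            if b <= a:
                continue
            ib = np.nonzero(labels == b)[0]
            min_between = min(min_between, float(M[np.ix_(ia, ib)].min()))
    dunn = float(min_between / max_diam) if max_diam > 0 else np.inf

    X = mds_coords.loc[ids].to_numpy(float)
    ch = float(skmetrics.calinski_harabasz_score(X, labels))
    centroids = {a: X[labels == a].mean(axis=0) for a in uniq}
    scatter = {a: float(np.mean(np.linalg.norm(X[labels == a] - centroids[a],
                                               axis=1))) for a in uniq}
    db = float(skmetrics.davies_bouldin_score(X, labels))
    # DB*: per cluster, max pairwise scatter sum over min centroid separation
    ratios = []
    for a in uniq:
        num = max(scatter[a] + scatter[b] for b in uniq if b != a)
        den = min(float(np.linalg.norm(centroids[a] - centroids[b]))
                  for b in uniq if b != a)
        ratios.append(num / den if den > 0 else np.inf)
    db_star = float(np.mean(ratios))
    return ValidityIndices(calinski_harabasz=ch, dunn=dunn,
                           mean_silhouette=sil, davies_bouldin=db,
                           davies_bouldin_modified=db_star)


@dataclass
class KSelection:
    chosen_k: int
    table: pd.DataFrame                     # per-k index values
    votes: dict[str, int]                   # index name -> its best k
    clusterings: dict[int, Clustering] = field(repr=False, default_factory=dict)


def choose_k(D: pd.DataFrame, k_range=K_RANGE, seed: int = 0,
             restarts: int = 10, mds_dim: int | None = None) -> KSelection:
    """Cluster at each k, score the five indices, pick k by plurality vote.

    CH, Dunn and silhouette vote for their maximizing k; both Davies-
    Bouldin variants for their minimizing k; ties go to the smallest k
    among the tied.
    """
    n = len(D)
    ks = [k for k in k_range if 2 <= k < n]
    if not ks:
        raise ValueError("no feasible k in range")
    dim = mds_dim if mds_dim is not None else min(n - 1, 5)
    mds = classical_mds(D, dim=dim)
    rows, clusterings = [], {}
    for k in ks:
        cl = pam_cluster(D, k, restarts=restarts, seed=seed + k)
        vi = validity_indices(D, cl, mds.coords)
        clusterings[k] = cl
        rows.append((k, vi.calinski_harabasz, vi.dunn, vi.mean_silhouette,
                     vi.davies_bouldin, vi.davies_bouldin_modified))
    table = pd.DataFrame(rows, columns=["k", "calinski_harabasz", "dunn",
                                        "mean_silhouette", "davies_bouldin",
                                        "davies_bouldin_modified"])
    votes = {}
    for col in ("calinski_harabasz", "dunn", "mean_silhouette"):
        votes[col] = int(table.loc[table[col].idxmax(), "k"])
    for col in ("davies_bouldin", "davies_bouldin_modified"):
        votes[col] = int(table.loc[table[col].idxmin(), "k"])
    counts = pd.Series(list(votes.values())).value_counts()
    top = counts[counts == counts.max()].index.min()
    return KSelection(chosen_k=int(top), table=table, votes=votes,
                      clusterings=clusterings)
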