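"""Low-dimensional structure of ensemble activity.

1-s binned activity vectors (Gaussian-filtered, sigma = 1 bin) are embedded
with PCA or IsoMap (Euclidean metric, 5 neighbors); all downstream geometry
operates on the embedded point clouds:

* discrimination ratio between two environments' average projections;
* Vietoris-Rips persistent homology (Betti barcodes H0-H2, computed by
  boundary-matrix reduction over Z/2 -- practical for the modest point
  counts used here, with mandatory subsampling for H2);
* participation ratio (sum lambda)^2 / sum lambda^2 over covariance
  eigenvalues, an effective dimensionality;
* centroid-distance diagnostics (skewness, Kullback-Leibler divergence
  between histograms) for cell-removal experiments;
* alpha-shape volume overlap between two environments' 3-D point clouds;
* windowed total-least-squares planar fits with angle dynamics (localness,
  smoothness) and the two-sample Kuiper test on planar-angle distributions.

The IsoMap implementation builds the k-nearest-neighbor graph, bridges
disconnected components with minimum-spanning-tree links (preserving sample
count), runs graph shortest paths, and applies classical MDS; explained
variance is reported as 1 minus the residual variance of the geodesic
distances after embedding.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree, shortest_path
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Embedding",
    "BettiBarcode",
    "PlanarFitSeries",
    "embed",
    "smooth_binned",
    "discrimination_ratio",
    "betti_barcode",
    "participation_ratio",
    "centroid_distances",
    "skewness",
    "kl_divergence",
    "alpha_overlap",
    "planar_fit",
    "plane_dynamics",
    "kuiper_statistic",
    "rank_by_participation",
    "removal_experiment",
]

DEFAULT_NEIGHBORS = 5
PERSISTENCE_FRACTION = 0.3  # bar length fraction of filtration range deemed persistent


@dataclass
class Embedding:
    """Low-dimensional projection of activity vectors with provenance."""

    points: np.ndarray            # (n_samples, dims)
    method: str                   # "pca" | "isomap"
    dims: int
    explained_variance: np.ndarray
    preprocessing: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method == "pca" and len(self.explained_variance) > 1:
            ev = self.explained_variance
            if not np.all(np.diff(ev) <= 1e-12):
                raise ValueError("PCA variance fractions must be nonincreasing")


@dataclass
class BettiBarcode:
    """Persistence intervals (dim, birth, death) of a Vietoris-Rips filtration."""

    intervals: list[tuple[int, float, float]]
    threshold: float              # filtration cap used
    subsample_seed: int | None = None

    def bars(self, dim: int) -> np.ndarray:
        out = [(b, d) for k, b, d in self.intervals if k == dim]
        return np.array(out) if out else np.empty((0, 2))

    def persistent_bars(self, dim: int, fraction: float = PERSISTENCE_FRACTION) -> np.ndarray:
        bars = self.bars(dim)
        if not len(bars):
            return bars
        length = np.where(np.isinf(bars[:, 1]), self.threshold, bars[:, 1]) - bars[:, 0]
        return bars[length >= fraction * self.threshold]


@dataclass
class PlanarFitSeries:
    """Per-window total-least-squares plane fits of a 3-D trajectory."""

    normals: np.ndarray    # (n_windows, 3), unit length
    centroids: np.ndarray  # (n_windows, 3)
    residuals: np.ndarray  # rms out-of-plane distance
    window: int            # samples per window
    step: int = 1


def smooth_binned(binned: np.ndarray, sigma_bins: float = 1.0) -> np.ndarray:
    """Gaussian-filter each cell's binned activity series along time."""
    return gaussian_filter1d(np.asarray(binned, float), sigma=sigma_bins, axis=1)


def _classical_mds(D: np.ndarray, dims: int):
    n = D.shape[0]
    D2 = D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = np.clip(vals[:dims], 0, None)
    return vecs[:, :dims] * np.sqrt(pos), vals


def embed(
    vectors: np.ndarray,
    method: str = "isomap",
    dims: int = 2,
    neighbors: int = DEFAULT_NEIGHBORS,
    presmoothed: bool = False,
    sigma_bins: float = 1.0,
) -> Embedding:
    """Embed 1-s activity vectors (samples x cells) with PCA or IsoMap.

    Unless ``presmoothed``, each cell's time series is Gaussian-filtered with
    a 1-bin standard deviation first.  A disconnected neighbor graph is
    bridged by the shortest available inter-component links (taken from the
    minimum spanning tree of the full distance matrix) and reported in the
    provenance record rather than dropping samples.
    """
    X = np.asarray(vectors, float)
    if not presmoothed:
        X = smooth_binned(X.T, sigma_bins).T
    n = X.shape[0]
    if n < dims + 1:
        raise ValueError("need more samples than dimensions")
    prep = {"sigma_bins": None if presmoothed else sigma_bins, "centered": True}
    if method == "pca":
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        var = s ** 2
        ev = var[:dims] / var.sum()
        return Embedding(points=U[:, :dims] * s[:dims], method="pca", dims=dims,
                         explained_variance=ev, preprocessing=prep)
    if method != "isomap":
        raise ValueError(f"unknown method {method!r}")
    D = squareform(pdist(X))
    k = min(neighbors, n - 1)
    idx = np.argsort(D, axis=1)[:, 1:k + 1]
    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    graph = csr_matrix((D[rows, cols], (rows, cols)), shape=(n, n))
    graph = graph.maximum(graph.T)
    n_comp, labels = connected_components(graph, directed=False)
    bridged = 0
    if n_comp > 1:
        mst = minimum_spanning_tree(csr_matrix(D)).tocoo()
        extra_r, extra_c, extra_d = [], [], []
        for i, j, w in zip(mst.row, mst.col, mst.data):
            if labels[i] != labels[j]:
                extra_r += [i, j]
                extra_c += [j, i]
                extra_d += [w, w]
                bridged += 1
        graph = graph.maximum(csr_matrix((extra_d, (extra_r, extra_c)), shape=(n, n)))
    geo = shortest_path(graph, method="D", directed=False)
    coords, vals = _classical_mds(geo, dims)
    # residual-variance definition of explained variance
    iu = np.triu_indices(n, 1)
    g = geo[iu]
    ev = np.empty(dims)
    for d in range(dims):
        e = squareform(pdist(coords[:, : d + 1]))[iu]
        r = np.corrcoef(g, e)[0, 1]
        ev[d] = r ** 2
    ev = np.concatenate([[ev[0]], np.diff(ev)])  # per-dimension increments
    prep["bridged_links"] = bridged
    return Embedding(points=coords, method="isomap", dims=dims,
                     explained_variance=ev, preprocessing=prep)


def discrimination_ratio(
    projections: list[np.ndarray], environments: list[str], denominator: str = "mean"
) -> float:
    """Same-environment over different-environment separation of average 2-D
    projections; ~1 means indistinct, toward 0 means distinct.

    Expects the four daily recordings (two per environment) embedded jointly.
    The numerator is the mean distance between same-environment averages; the
    denominator aggregates the different-environment distances by their mean
    (default) or, more conservatively, their minimum -- with only four
    recordings the minimum is heavy-tailed and makes the ratio unstable.
    """
    envs = np.asarray(environments)
    means = np.stack([np.asarray(p)[:, :2].mean(axis=0) for p in projections])
    same, diff = [], []
    for a in range(len(means)):
        for b in range(a + 1, len(means)):
            d = float(np.linalg.norm(means[a] - means[b]))
            (same if envs[a] == envs[b] else diff).append(d)
    if not same or not diff:
        raise ValueError("need both same- and different-environment pairs")
    denom = min(diff) if denominator == "min" else float(np.mean(diff))
    if denom == 0:
        raise ValueError("zero different-environment separation")
    return float(np.mean(same) / denom)


# ---------------------------------------------------------------------------
# Vietoris-Rips persistent homology (Z/2 boundary-matrix reduction)
# ---------------------------------------------------------------------------

def _rips_persistence(D: np.ndarray, max_dim: int, threshold: float):
    n = D.shape[0]
    # simplices: (diameter, dim, vertex tuple), filtration order
    simplices = [(0.0, 0, (i,)) for i in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        if D[i, j] <= threshold:
            simplices.append((D[i, j], 1, (i, j)))
    if max_dim >= 1:
        for tri in itertools.combinations(range(n), 3):
            d = max(D[tri[0], tri[1]], D[tri[0], tri[2]], D[tri[1], tri[2]])
            if d <= threshold:
                simplices.append((d, 2, tri))
    if max_dim >= 2:
        for tet in itertools.combinations(range(n), 4):
            d = 0.0
            for a, b in itertools.combinations(tet, 2):
                if D[a, b] > d:
                    d = D[a, b]
            if d <= threshold:
                simplices.append((d, 3, tet))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index = {s[2]: k for k, s in enumerate(simplices)}
    low_to_col: dict[int, int] = {}
    columns: dict[int, int] = {}
    pairs = {}
    for k, (diam, dim, verts) in enumerate(simplices):
        if dim == 0:
            continue
        col = 0
        for face in itertools.combinations(verts, dim):
            col ^= 1 << index[face]
        while col:
            low = col.bit_length() - 1
            other = low_to_col.get(low)
            if other is None:
                break
            col ^= columns[other]
        if col:
            low = col.bit_length() - 1
            low_to_col[low] = k
            columns[k] = col
            pairs[low] = k  # simplex `low` gives birth; simplex k kills it
    intervals = []
    for k, (diam, dim, verts) in enumerate(simplices):
        if dim > max_dim:
            continue
        if k in pairs:
            death = simplices[pairs[k]][0]
            if death > diam:
                intervals.append((dim, diam, death))
        elif k not in columns or columns.get(k, 1) != 0:
            # unpaired and not a death column -> essential class
            if k not in columns:
                killed = any(v == k for v in pairs.values())
                if not killed:
                    intervals.append((dim, diam, np.inf))
    return intervals


def betti_barcode(
    points: np.ndarray,
    max_dim: int = 1,
    threshold: float | None = None,
    subsample: int | None = 700,
    max_points_h2: int = 40,
    seed: int = 0,
) -> BettiBarcode:
    """Vietoris-Rips persistence barcode of a point cloud.

    The filtration is capped at the enclosing radius (beyond which the
    complex is a cone and higher homology is trivial) unless ``threshold``
    is given.  Clouds larger than ``subsample`` points are randomly
    subsampled with a recorded seed; when ``max_dim >= 2`` the cap is
    ``max_points_h2`` -- the exact reduction is cubic-and-worse in point
    count, so second homology is only practical on small clouds.
    """
    rng = np.random.default_rng(seed)
    pts = np.asarray(points, float)
    cap = subsample if max_dim < 2 else (min(subsample or max_points_h2, max_points_h2))
    sub_seed = None
    if cap is not None and len(pts) > cap:
        pts = pts[rng.choice(len(pts), size=cap, replace=False)]
        sub_seed = seed
    D = squareform(pdist(pts))
    if threshold is None:
        threshold = float(D.max(axis=1).min()) * 1.001  # enclosing radius
    intervals = _rips_persistence(D, max_dim, threshold)
    return BettiBarcode(intervals=intervals, threshold=threshold, subsample_seed=sub_seed)


def participation_ratio(points: np.ndarray) -> float:
    """(Tr C)^2 / Tr(C^2) over the covariance of the supplied window.

    Equals (sum lambda)^2 / sum lambda^2 of the covariance eigenvalues;
    1 for one-dimensional data, the ambient dimension for isotropic data.
    """
    X = np.asarray(points, float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 points")
    C = np.cov(X.T)
    C = np.atleast_2d(C)
    tr = np.trace(C)
    tr2 = np.trace(C @ C)
    if tr2 == 0:
        raise ValueError("zero total variance")
    return float(tr ** 2 / tr2)


def centroid_distances(points: np.ndarray) -> np.ndarray:
    """Euclidean distance of every sample from the cloud centroid."""
    X = np.asarray(points, float)
    return np.linalg.norm(X - X.mean(axis=0), axis=1)


def skewness(x: np.ndarray) -> float:
    """Sample skewness: m3 / m2^(3/2) with biased central moments."""
    x = np.asarray(x, float)
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    if m2 == 0:
        return 0.0
    return float(((x - m) ** 3).mean() / m2 ** 1.5)


def kl_divergence(
    sample: np.ndarray, reference: np.ndarray, bins: int = 20, smoothing: float = 1e-6
) -> float:
    """KL divergence D(sample || reference) between histogram estimates on
    shared equal-width bins over the pooled range, with additive smoothing."""
    pooled = np.concatenate([sample, reference])
    edges = np.linspace(pooled.min(), pooled.max(), bins + 1)
    p, _ = np.histogram(sample, bins=edges)
    q, _ = np.histogram(reference, bins=edges)
    p = p + smoothing
    q = q + smoothing
    p = p / p.sum()
    q = q / q.sum()
    return float((p * np.log(p / q)).sum())


# ---------------------------------------------------------------------------
# alpha-shape overlap
# ---------------------------------------------------------------------------

def _circumradii(pts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a, b, c, d = (pts[tets[:, k]] for k in range(4))
    A = np.stack([b - a, c - a, d - a], axis=1)  # (m, 3, 3)
    rhs = 0.5 * np.stack([(b ** 2 - a ** 2).sum(1), (c ** 2 - a ** 2).sum(1),
                          (d ** 2 - a ** 2).sum(1)], axis=1)
    radii = np.full(len(tets), np.inf)
    for m in range(len(tets)):
        try:
            center = np.linalg.solve(A[m], rhs[m])
        except np.linalg.LinAlgError:
            continue
        radii[m] = np.linalg.norm(center - a[m])
    return radii


def _one_region_alpha(tri: Delaunay, radii: np.ndarray) -> float:
    """Smallest circumradius cutoff whose kept tetrahedra form one connected
    region covering every input point (the critical alpha)."""
    order = np.argsort(radii)
    m = len(order)
    n = tri.points.shape[0]
    # neighbor tets sharing a face
    lo, hi = 0, m - 1
    candidates = np.unique(radii[np.isfinite(radii)])

    def ok(cut):
        keep = radii <= cut
        if not keep.any():
            return False
        if not np.isin(np.arange(n), tri.simplices[keep]).all():
            return False
        kept_idx = np.flatnonzero(keep)
        pos = -np.ones(m, int)
        pos[kept_idx] = np.arange(len(kept_idx))
        parent = np.arange(len(kept_idx))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for ki, t in enumerate(kept_idx):
            for nb in tri.neighbors[t]:
                if nb >= 0 and pos[nb] >= 0:
                    ra, rb = find(ki), find(pos[nb])
                    if ra != rb:
                        parent[ra] = rb
        roots = {find(i) for i in range(len(kept_idx))}
        return len(roots) == 1

    lo_i, hi_i = 0, len(candidates) - 1
    if not ok(candidates[hi_i]):
        return float(candidates[hi_i])
    while lo_i < hi_i:
        mid = (lo_i + hi_i) // 2
        if ok(candidates[mid]):
            hi_i = mid
        else:
            lo_i = mid + 1
    return float(candidates[lo_i])


def alpha_overlap(
    points_a: np.ndarray,
    points_b: np.ndarray,
    alpha: float | None = None,
    min_points: int = 50,
    symmetric: bool = False,
) -> float | dict:
    """Fraction of ``points_a`` inside the 3-D alpha-shape of ``points_b``.

    The alpha-shape keeps Delaunay tetrahedra with circumradius below the
    critical alpha (smallest value yielding one connected region over all
    points) unless ``alpha`` is given.  Degenerate (coplanar) clouds fall
    back to the convex hull of the projected plane, flagged in the result.
    With ``symmetric``, returns a dict with both directions and their mean.
    """
    A = np.asarray(points_a, float)
    B = np.asarray(points_b, float)
    if len(A) < min_points or len(B) < min_points:
        raise ValueError(f"need at least {min_points} points per cloud")

    def one_way(P, Q):
        try:
            tri = Delaunay(Q)
        except Exception:
            return _planar_fallback(P, Q)
        radii = _circumradii(Q, tri.simplices)
        cut = alpha if alpha is not None else _one_region_alpha(tri, radii)
        keep = radii <= cut
        simp = tri.find_simplex(P)
        inside = (simp >= 0) & keep[np.clip(simp, 0, None)]
        # points coincident with shape vertices count as inside (boundary-safe)
        d, _ = cKDTree(Q).query(P)
        inside |= d < 1e-9
        return float(inside.mean())

    ab = one_way(A, B)
    if not symmetric:
        return ab
    ba = one_way(B, A)
    return {"a_in_b": ab, "b_in_a": ba, "mean": (ab + ba) / 2}


def _planar_fallback(P, Q):
    """Coplanar cloud: test membership in the 2-D convex hull on the fitted plane."""
    normal, centroid, _ = planar_fit(Q)
    basis = np.linalg.svd(np.eye(3) - np.outer(normal, normal))[0][:, :2]
    q2 = (Q - centroid) @ basis
    p2 = (P - centroid) @ basis
    tri = Delaunay(q2)
    return float((tri.find_simplex(p2) >= 0).mean())


# ---------------------------------------------------------------------------
# planar multistability
# ---------------------------------------------------------------------------

def planar_fit(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares plane: the unit normal minimizing the summed
    squared dot products with centered points (least eigenvector of the
    scatter matrix).  Sign fixed to positive z (tie: positive y, then x).
    Returns (normal, centroid, rms residual); raises on collinear input."""
    X = np.asarray(points, float)
    if X.shape[0] < 3 or X.shape[1] != 3:
        raise ValueError("need >= 3 points in 3-D")
    centroid = X.mean(axis=0)
    Y = X - centroid
    C = Y.T @ Y
    vals, vecs = np.linalg.eigh(C)
    if vals[1] <= 1e-12 * max(vals[-1], 1e-300):
        raise ValueError("collinear points: plane undefined")
    normal = vecs[:, 0]
    for ax in (2, 1, 0):
        if abs(normal[ax]) > 1e-12:
            if normal[ax] < 0:
                normal = -normal
            break
    residual = float(np.sqrt(((Y @ normal) ** 2).mean()))
    return normal, centroid, residual


def fit_plane_series(points: np.ndarray, window: int = 60, step: int = 1) -> PlanarFitSeries:
    """Sliding-window planar fits of a 3-D sample trajectory."""
    X = np.asarray(points, float)
    n = len(X)
    if n < window:
        raise ValueError("fewer samples than one window")
    starts = range(0, n - window + 1, step)
    normals, cents, resid = [], [], []
    for s in starts:
        try:
            nrm, c, r = planar_fit(X[s:s + window])
        except ValueError:
            nrm, c, r = np.full(3, np.nan), np.full(3, np.nan), np.nan
        normals.append(nrm)
        cents.append(c)
        resid.append(r)
    return PlanarFitSeries(normals=np.array(normals), centroids=np.array(cents),
                           residuals=np.array(resid), window=window, step=step)


def _normal_angles(normals: np.ndarray) -> np.ndarray:
    a, b = normals[:-1], normals[1:]
    cosang = np.abs((a * b).sum(axis=1))
    cosang = np.clip(cosang / (np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)), 0, 1)
    return np.degrees(np.arccos(cosang))  # unsigned, [0, 90]


def plane_dynamics(
    points: np.ndarray,
    window: int = 60,
    step: int = 1,
    rng: np.random.Generator | None = None,
) -> dict:
    """Trajectory dynamics in a 3-D embedding.

    localness: Euclidean distance between temporally adjacent samples.
    smoothness: angle (degrees, [0, 90]) between temporally adjacent
    windowed plane normals.  Chance versions recompute both after shuffling
    the temporal order of the samples.
    """
    X = np.asarray(points, float)
    series = fit_plane_series(X, window, step)
    ok = np.isfinite(series.normals).all(axis=1)
    angles = _normal_angles(series.normals)
    angles[~(ok[:-1] & ok[1:])] = np.nan
    local = np.linalg.norm(np.diff(X, axis=0), axis=1)
    out = {"angles": angles, "localness": local, "smoothness": angles,
           "residuals": series.residuals}
    if rng is not None:
        perm = rng.permutation(len(X))
        shuffled = X[perm]
        s2 = fit_plane_series(shuffled, window, step)
        out["chance_localness"] = np.linalg.norm(np.diff(shuffled, axis=0), axis=1)
        out["chance_smoothness"] = _normal_angles(s2.normals)
    return out


def kuiper_statistic(angles_a: np.ndarray, angles_b: np.ndarray,
                     period: float = 360.0) -> tuple[float, float]:
    """Two-sample Kuiper test on circular data.

    V = D+ + D- between the two empirical CDFs on the circle; invariant to a
    common rotation of both samples.  The p value uses the asymptotic Kuiper
    distribution with the standard effective-size correction.
    """
    a = np.sort(np.asarray(angles_a, float) % period)
    b = np.sort(np.asarray(angles_b, float) % period)
    na, nb = len(a), len(b)
    if na < 1 or nb < 1:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    pooled.sort()
    cdf_a = np.searchsorted(a, pooled, side="right") / na
    cdf_b = np.searchsorted(b, pooled, side="right") / nb
    d = cdf_a - cdf_b
    V = float(d.max() - d.min())
    ne = na * nb / (na + nb)
    lam = (math.sqrt(ne) + 0.155 + 0.24 / math.sqrt(ne)) * V
    if lam < 0.4:
        p = 1.0
    else:
        p = 0.0
        for k in range(1, 101):
            p += (4 * k * k * lam * lam - 1) * math.exp(-2 * k * k * lam * lam)
        p = min(1.0, max(0.0, 2 * p))
    return V, p


# ---------------------------------------------------------------------------
# cell-removal necessity / sufficiency
# ---------------------------------------------------------------------------

def rank_by_participation(m, tau_range: tuple[float, float]) -> np.ndarray:
    """Cells ordered by descending participation in pairs within ``tau_range``."""
    from .coactivity import participation_ranking

    part = participation_ranking(m, tau_range)
    part = np.nan_to_num(part, nan=-1.0)
    return np.argsort(part)[::-1]


def removal_experiment(
    binned_by_recording: list[np.ndarray],
    environments: list[str],
    coactivity_matrix,
    rule: str = "anti",
    fraction: float = 0.3,
    mode: str = "remove",
    method: str = "isomap",
    dims: int = 2,
    seed: int = 0,
    tau_ranges: dict | None = None,
) -> dict:
    """Re-embed after removing (or keeping only) a ranked cell subset and
    recompute the environment discrimination ratio.

    ``rule`` ranks cells by participation in anti-coactive pairs
    (tau <= -0.05), coactive pairs (tau > 0.3), or picks a random subset with
    a recorded seed.  ``mode='keep_only'`` inverts the selection semantics.
    """
    if mode not in ("remove", "keep_only"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    n_cells = binned_by_recording[0].shape[0]
    ranges = tau_ranges or {"anti": (-1.0, -0.05), "coactive": (0.3, 1.0)}
    k = int(round(fraction * n_cells))
    if rule == "random":
        chosen = rng.choice(n_cells, size=k, replace=False)
    elif rule in ranges:
        chosen = rank_by_participation(coactivity_matrix, ranges[rule])[:k]
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if mode == "remove":
        keep = np.setdiff1d(np.arange(n_cells), chosen)
    else:
        keep = np.sort(chosen)
    if len(keep) < 20 and fraction not in (0.0, 1.0):
        raise ValueError("selection leaves fewer than 20 cells")
    if len(keep) == 0:
        raise ValueError("selection removes every cell")
    lengths = [b.shape[1] for b in binned_by_recording]
    concat = np.concatenate([b[keep] for b in binned_by_recording], axis=1)
    emb = embed(concat.T, method=method, dims=dims)
    pieces = np.split(emb.points, np.cumsum(lengths)[:-1])
    ratio = discrimination_ratio(pieces, environments)
    return {"discrimination_ratio": ratio, "kept_cells": keep, "embedding": emb}
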