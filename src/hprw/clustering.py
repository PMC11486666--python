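"""Sub-population structure in (q_bar, a_bar) space.

The semi-unsupervised pipeline: DBSCAN flags low-density outlier cells,
k-means partitions the inliers, clusters are mapped onto named motility
modes by a deterministic geometric rule, and a bootstrap over cells
quantifies the stability of the mode proportions.  Per-step (q_hat, a_hat)
estimates are summarized as highest-density-region contours with marginal
histograms.

Mode tags: ``↑a↑q`` (high activity, high persistence), ``↓a↑q`` (low
activity, high persistence), ``↓a↓q`` (low both).  With k = 4 the two
lowest-activity clusters — one of which is typically the near-immobile
mode — merge into ``↓a↓q``; with k = 3 each cluster maps to one tag.

Both features are z-standardized before DBSCAN and k-means because
persistence is unitless while activity is in µm/min; centroids are reported
back in original units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.cluster import DBSCAN, KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "TAG_HIGH",
    "TAG_MID",
    "TAG_LOW",
    "TAGS",
    "ClusterReport",
    "BootstrapResult",
    "ContourSet",
    "remove_outliers",
    "k_distance",
    "cluster_cells",
    "label_and_merge",
    "bootstrap_proportions",
    "two_proportion_z_test",
    "joint_density_contours",
]

TAG_HIGH = "↑a↑q"
TAG_MID = "↓a↑q"
TAG_LOW = "↓a↓q"
#: fixed reporting order, from the most to the least motile mode
TAGS = (TAG_HIGH, TAG_MID, TAG_LOW)


def _features(summaries: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(summaries, pd.DataFrame):
        return summaries[["q_bar", "a_bar"]].to_numpy(dtype=float)
    arr = np.asarray(summaries, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (q_bar, a_bar)")
    return arr


def _standardize(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mean) / sd


def remove_outliers(
    summaries: pd.DataFrame | np.ndarray, eps: float = 0.5, min_pts: int = 5
) -> np.ndarray:
    """DBSCAN-based outlier mask over z-standardized (q_bar, a_bar).

    Returns a boolean inlier mask aligned with the input order; DBSCAN
    noise points are outliers.  When fewer cells than ``min_pts`` are
    given, all are retained with a warning.
    """
    x = _features(summaries)
    if x.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    if x.shape[0] < min_pts:
        warnings.warn(
            f"only {x.shape[0]} cells (< min_pts={min_pts}); keeping all",
            stacklevel=2,
        )
        return np.ones(x.shape[0], dtype=bool)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(_standardize(x))
    return labels != -1


def k_distance(summaries: pd.DataFrame | np.ndarray, k: int = 5) -> np.ndarray:
    """Sorted distance of every cell to its k-th nearest neighbour
    (z-standardized units) — the elbow of this curve is the usual guide
    for choosing the DBSCAN ``eps``."""
    from sklearn.neighbors import NearestNeighbors

    z = _standardize(_features(summaries))
    if z.shape[0] <= k:
        raise ValueError(f"need more than k={k} cells")
    dist, _ = NearestNeighbors(n_neighbors=k + 1).fit(z).kneighbors(z)
    return np.sort(dist[:, k])


@dataclass
class ClusterReport:
    """k-means partition of inlier cells in (q_bar, a_bar) space."""

    inlier_mask: np.ndarray
    centroids: np.ndarray  # (k, 2) in original units, columns (q, a)
    labels: np.ndarray  # cluster index per inlier cell
    k_used: int
    silhouette_by_k: dict[int, float]
    tags: list[str] | None = None  # per-cluster tag after label_and_merge
    cell_tags: np.ndarray | None = None  # merged tag per inlier cell
    proportions: dict[str, float] | None = None
    notes: list[str] = field(default_factory=list)


def cluster_cells(
    summaries: pd.DataFrame | np.ndarray,
    k: int = 4,
    n_restarts: int = 10,
    seed: int = 0,
    inlier_mask: np.ndarray | None = None,
    silhouette_range: tuple[int, int] = (2, 6),
) -> ClusterReport:
    """k-means over z-standardized inlier features.

    The best of ``n_restarts`` seeded initializations (lowest within-cluster
    sum of squares) is kept; each cell joins the cluster whose centroid is
    nearest in Euclidean distance.  Mean silhouette widths for k in
    ``silhouette_range`` are reported as a diagnostic only — k itself is a
    configuration choice, never auto-selected.
    """
    x_all = _features(summaries)
    if inlier_mask is None:
        inlier_mask = np.ones(x_all.shape[0], dtype=bool)
    x = x_all[inlier_mask]
    if x.shape[0] < k:
        raise ValueError(f"cannot form k={k} clusters from {x.shape[0]} inlier cells")
    mean = x.mean(axis=0)
    sd = np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    z = (x - mean) / sd

    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(z)
    centroids = km.cluster_centers_ * sd + mean

    silhouettes: dict[int, float] = {}
    lo, hi = silhouette_range
    for kk in range(lo, hi + 1):
        if x.shape[0] <= kk:
            continue
        lab = KMeans(n_clusters=kk, n_init=n_restarts, random_state=seed).fit_predict(z)
        if len(np.unique(lab)) < 2:
            continue
        silhouettes[kk] = float(silhouette_score(z, lab))

    return ClusterReport(
        inlier_mask=np.asarray(inlier_mask, dtype=bool),
        centroids=centroids,
        labels=km.labels_.copy(),
        k_used=k,
        silhouette_by_k=silhouettes,
    )


def label_and_merge(report: ClusterReport) -> ClusterReport:
    """Map clusters onto the three motility-mode tags and merge.

    k = 4: the two lowest-activity centroids merge into ``↓a↓q``, the
    highest-activity centroid is ``↑a↑q`` and the remaining one ``↓a↑q``.
    k = 3: highest activity is ``↑a↑q``; of the rest, the higher-persistence
    centroid is ``↓a↑q`` and the other ``↓a↓q``.  Activity ties are broken
    by persistence (lower q merges first) and noted in the report.  The
    mapping depends only on centroid geometry, so it is invariant to
    cluster index permutation and makes bootstrap repetitions comparable.
    """
    k = report.k_used
    if k not in (3, 4):
        raise ValueError(f"tag rule defined for k in {{3, 4}}, got k={k}")
    cent = report.centroids
    a_vals = cent[:, 1]
    q_vals = cent[:, 0]
    if len(np.unique(a_vals)) < k:
        report.notes.append("activity tie between centroids; broken by persistence")
    order = sorted(range(k), key=lambda i: (a_vals[i], q_vals[i]))  # ascending a, tie by q
    tags = [""] * k
    if k == 4:
        tags[order[0]] = TAG_LOW
        tags[order[1]] = TAG_LOW
        tags[order[3]] = TAG_HIGH
        tags[order[2]] = TAG_MID
    else:
        tags[order[2]] = TAG_HIGH
        rest = order[:2]
        hi_q = max(rest, key=lambda i: q_vals[i])
        lo = rest[0] if rest[1] == hi_q else rest[1]
        tags[hi_q] = TAG_MID
        tags[lo] = TAG_LOW

    cell_tags = np.asarray([tags[c] for c in report.labels], dtype=object)
    n = cell_tags.size
    proportions = {tag: float(np.count_nonzero(cell_tags == tag)) / n for tag in TAGS}
    report.tags = tags
    report.cell_tags = cell_tags
    report.proportions = proportions
    return report


@dataclass
class BootstrapResult:
    """Stability of merged-mode proportions under cell resampling."""

    n_reps: int
    mean_proportions: dict[str, float]
    sd_proportions: dict[str, float]
    mean_cumulative: dict[str, float]  # mean of cumulative sums in TAGS order
    sd_cumulative: dict[str, float]
    n_redrawn: int = 0


def _run_once(
    x: np.ndarray, k: int, eps: float, min_pts: int, n_restarts: int, seed: int
) -> dict[str, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        inliers = remove_outliers(x, eps=eps, min_pts=min_pts)
    if inliers.sum() < k:
        raise ValueError("degenerate resample: fewer inliers than clusters")
    report = cluster_cells(x, k=k, n_restarts=n_restarts, seed=seed,
                           inlier_mask=inliers, silhouette_range=(2, 1))
    return label_and_merge(report).proportions


def bootstrap_proportions(
    summaries: pd.DataFrame | np.ndarray,
    k: int = 4,
    eps: float = 0.5,
    min_pts: int = 5,
    n_restarts: int = 10,
    n_reps: int = 100,
    seed: int = 0,
    refit_outliers: bool = True,
) -> BootstrapResult:
    """Bootstrap the clustering pipeline over cells.

    Each repetition resamples the cells with replacement (same n), reruns
    outlier removal, k-means and the tag/merge rule, and records the merged
    proportions; 100 repetitions by default.  Mode identity across
    repetitions comes from the deterministic tag rule.  A degenerate
    repetition (e.g. a resample with fewer inliers than clusters) is
    redrawn and counted.  ``refit_outliers=False`` runs DBSCAN once on the
    full data and resamples only the fixed inlier set — faster on large
    cohorts, at the cost of not propagating outlier-detection variability.
    """
    x = _features(summaries)
    n = x.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} cells, got {n}")
    if not refit_outliers:
        x = x[remove_outliers(x, eps=eps, min_pts=min_pts)]
        n = x.shape[0]
    rng = np.random.default_rng(seed)
    props = []
    redrawn = 0
    while len(props) < n_reps:
        idx = rng.integers(0, n, size=n)
        try:
            props.append(_run_once(x[idx], k, eps, min_pts, n_restarts,
                                   seed=int(rng.integers(0, 2**31 - 1))))
        except ValueError:
            redrawn += 1
            if redrawn > 10 * n_reps:
                raise RuntimeError("bootstrap cannot draw non-degenerate resamples")
    mat = np.array([[p[tag] for tag in TAGS] for p in props])
    cum = np.cumsum(mat, axis=1)
    if n_reps > 1:
        sd, sd_cum = mat.std(axis=0, ddof=1), cum.std(axis=0, ddof=1)
    else:
        sd = sd_cum = np.zeros(len(TAGS))
    return BootstrapResult(
        n_reps=n_reps,
        mean_proportions={tag: float(m) for tag, m in zip(TAGS, mat.mean(axis=0))},
        sd_proportions={tag: float(s) for tag, s in zip(TAGS, sd)},
        mean_cumulative={tag: float(m) for tag, m in zip(TAGS, cum.mean(axis=0))},
        sd_cumulative={tag: float(s) for tag, s in zip(TAGS, sd_cum)},
        n_redrawn=redrawn,
    )


def two_proportion_z_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-population proportion Z test with pooled variance.

    ``z = (p1 - p2) / sqrt(pbar (1 - pbar) (1/n1 + 1/n2))`` with the pooled
    proportion ``pbar = (x1 + x2) / (n1 + n2)``; two-sided p from the
    standard normal.  When the pooled proportion is 0 or 1 the statistic is
    undefined (NaN) and p = 1.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("need 0 <= x <= n for both groups")
    if n1 < 1 or n2 < 1:
        raise ValueError("need n >= 1 in both groups")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return math.nan, 1.0
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = 2.0 * float(norm.sf(abs(z)))
    return z, p


@dataclass
class ContourSet:
    """Highest-density-region summary of a bivariate (q, a) sample.

    ``mass`` is the bin probability-mass array (q rows, a columns).  For
    each level the HDR is built greedily: bins are added in decreasing-mass
    order (ties broken by bin index, deterministically) until the
    accumulated mass first reaches the level, so the region is minimal —
    dropping its lowest-mass bin falls below the level.  ``thresholds``
    holds the mass of the last included bin per level.
    """

    q_edges: np.ndarray
    a_edges: np.ndarray
    mass: np.ndarray
    levels: tuple[float, ...]
    thresholds: dict[float, float]
    masks: dict[float, np.ndarray]
    marginal_q: np.ndarray
    marginal_a: np.ndarray
    n_excluded: int

    def contained_mass(self, level: float) -> float:
        return float(self.mass[self.masks[level]].sum())


def joint_density_contours(
    q: np.ndarray,
    a: np.ndarray,
    q_domain: tuple[float, float] = (0.0, 1.0),
    a_domain: tuple[float, float] = (0.0, 10.0),
    bins: tuple[int, int] = (25, 25),
    levels: tuple[float, ...] = (0.5, 0.8, 0.95),
) -> ContourSet:
    """Bivariate histogram of (q, a) pairs with 50/80/95% HDR levels.

    Pairs outside the domain are excluded and counted.  Marginal histograms
    are the row/column sums of the mass array.
    """
    q = np.asarray(q, dtype=float)
    a = np.asarray(a, dtype=float)
    if q.size == 0 or q.shape != a.shape:
        raise ValueError("need equal-length, non-empty q and a samples")
    inside = (
        (q >= q_domain[0]) & (q <= q_domain[1]) & (a >= a_domain[0]) & (a <= a_domain[1])
    )
    if not np.any(inside):
        raise ValueError("no pairs inside the contour domain")
    counts, q_edges, a_edges = np.histogram2d(
        q[inside], a[inside], bins=bins, range=[q_domain, a_domain]
    )
    mass = counts / counts.sum()

    flat = mass.ravel()
    order = np.argsort(-flat, kind="stable")  # decreasing mass, stable in bin index
    cum = np.cumsum(flat[order])
    masks: dict[float, np.ndarray] = {}
    thresholds: dict[float, float] = {}
    for level in levels:
        stop = int(np.searchsorted(cum, level - 1e-12)) + 1
        sel = order[:stop]
        m = np.zeros(flat.size, dtype=bool)
        m[sel] = True
        masks[level] = m.reshape(mass.shape)
        thresholds[level] = float(flat[sel[-1]])

    return ContourSet(
        q_edges=q_edges,
        a_edges=a_edges,
        mass=mass,
        levels=tuple(levels),
        thresholds=thresholds,
        masks=masks,
        marginal_q=mass.sum(axis=1),
        marginal_a=mass.sum(axis=0),
        n_excluded=int(np.count_nonzero(~inside)),
    )
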