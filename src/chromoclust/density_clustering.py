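"""Density-peak clustering of the 2D embedding.

The 2D t-SNE cloud is turned into morphology clusters by: (1) removing
outliers with the 3-sigma rule on total pairwise distance, (2) Gaussian KDE
(Scott's rule) evaluated on a square grid spanning the data, (3) peak
detection with a 5x5 maximum filter and an XOR against zero cells, and
(4) a watershed-like assignment in which the iso-density contour around each
peak is raised through 100 levels until it encloses only that peak; points
inside the final contour form the peak's cluster.  Clusters below a minimum
size are discarded.  Cluster quality is scored by the silhouette coefficient
of the clustered points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import gaussian_kde

from .embedding import Embedding2D

GRID_SIZE_PAPER = 1000
MIN_CLUSTER_SIZE_PAPER = 100


@dataclass
class DensityGrid:
    x: np.ndarray  # grid coordinates, axis 0 of P
    y: np.ndarray  # grid coordinates, axis 1 of P
    P: np.ndarray  # (n, n) density values, P[i, j] = p(x[i], y[j])
    bandwidth_factor: float


@dataclass
class ClusterAssignment:
    peaks: list  # (i, j) grid indices of surviving peaks, cluster k <-> peaks[k]
    labels: np.ndarray  # per point: cluster index or -1 for unclustered
    sizes: np.ndarray = field(default=None)
    occupancy: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.sizes is None:
            k = len(self.peaks)
            self.sizes = np.array([(self.labels == i).sum() for i in range(k)])
        if self.occupancy is None and self.sizes.sum() > 0:
            self.occupancy = self.sizes / self.sizes.sum()

    @property
    def n_clusters(self) -> int:
        return len(self.peaks)


def remove_outliers(points: Embedding2D) -> tuple[Embedding2D, np.ndarray]:
    """3-sigma rule on the row sums of the pairwise distance matrix.

    Returns the retained embedding and the indices of removed points.
    """
    pts = np.asarray(points.points)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    rowsum = squareform(pdist(pts)).sum(axis=1)
    mu, sd = rowsum.mean(), rowsum.std()
    keep = (rowsum > mu - 3 * sd) & (rowsum < mu + 3 * sd)
    if sd == 0:
        keep = np.ones(len(pts), dtype=bool)
    removed = np.flatnonzero(~keep)
    return (
        Embedding2D(points=pts[keep], method=points.method, seed=points.seed),
        removed,
    )


def kde_density(
    points: Embedding2D, grid_size: int = GRID_SIZE_PAPER, seed: int = 0
) -> DensityGrid:
    """Bivariate Gaussian KDE (Scott's rule) on a grid over axis-wise min/max."""
    pts = np.asarray(points.points, dtype=float)
    if len(np.unique(pts, axis=0)) < 2:
        raise ValueError("need at least 2 distinct points")
    try:
        kde = gaussian_kde(pts.T)
    except np.linalg.LinAlgError:
        warnings.warn("degenerate point configuration; adding tiny jitter", stacklevel=2)
        span = max(pts.max(axis=0) - pts.min(axis=0)) or 1.0
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0, 1e-9 * span, size=pts.shape)
        kde = gaussian_kde(pts.T)
    gx = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid_size)
    gy = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid_size)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid_size, grid_size)
    return DensityGrid(x=gx, y=gy, P=dens, bandwidth_factor=float(kde.factor))


def detect_peaks(
    grid: DensityGrid, filter_size: int = 5, zero_floor: float = 1e-12
) -> list[tuple[int, int]]:
    """Local density maxima: cells equal to their 5x5 maximum filter, XOR zero.

    Cells below ``zero_floor`` times the grid maximum count as zero, so
    far-field numerical ripple of the KDE cannot spawn spurious peaks.
    Plateau ties (adjacent equal-valued maxima) keep only the lexicographically
    smallest index of the plateau.
    """
    p = grid.P.copy()
    p[p < zero_floor * p.max()] = 0.0
    mf = ndimage.maximum_filter(p, size=filter_size, mode="nearest")
    # nonzero cells equal to their window maximum; the zero comparison keeps
    # flat zero regions from being reported as maxima
    q = (p == mf) & (p > 0)
    if not q.any():
        return []
    lab, nlab = ndimage.label(q, structure=np.ones((3, 3), dtype=int))
    peaks = []
    for k in range(1, nlab + 1):
        ii, jj = np.nonzero(lab == k)
        order = np.lexsort((jj, ii))
        peaks.append((int(ii[order[0]]), int(jj[order[0]])))
    peaks.sort()
    return peaks


def _point_cells(points: np.ndarray, grid: DensityGrid) -> tuple[np.ndarray, np.ndarray]:
    """Nearest grid cell of each point."""
    n = len(grid.x)
    sx = (grid.x[-1] - grid.x[0]) / (n - 1) or 1.0
    sy = (grid.y[-1] - grid.y[0]) / (n - 1) or 1.0
    ci = np.clip(np.round((points[:, 0] - grid.x[0]) / sx).astype(int), 0, n - 1)
    cj = np.clip(np.round((points[:, 1] - grid.y[0]) / sy).astype(int), 0, n - 1)
    return ci, cj


def watershed_assign(
    grid: DensityGrid,
    peaks: list[tuple[int, int]],
    points: Embedding2D,
    n_levels: int = 100,
    min_cluster_size: int = MIN_CLUSTER_SIZE_PAPER,
) -> ClusterAssignment:
    """Assign points to peaks by shrinking iso-density contours.

    For each peak the contour level is raised through ``n_levels`` levels from
    0 to the density maximum until the enclosed region (superlevel-set
    component, holes filled) contains only that peak; points whose grid cell
    falls inside that region get the peak's label.  Clusters with fewer than
    ``min_cluster_size`` members are discarded and their points become
    unclustered, as are points outside every final contour.
    """
    if not peaks:
        raise ValueError("need at least one peak")
    p = grid.P
    levels = np.linspace(0.0, p.max(), n_levels)
    peak_arr = np.array(peaks)
    regions: dict[int, np.ndarray] = {}
    pending = set(range(len(peaks)))
    struct = np.ones((3, 3), dtype=int)
    for t in levels[1:]:
        if not pending:
            break
        lab, _ = ndimage.label(p >= t, structure=struct)
        for k in sorted(pending):
            comp = lab[peaks[k]]
            if comp == 0:
                continue  # peak below this level; its region was frozen earlier
            region = ndimage.binary_fill_holes(lab == comp)
            inside = region[peak_arr[:, 0], peak_arr[:, 1]]
            if inside.sum() == 1:
                regions[k] = region
                pending.discard(k)
    for k in pending:  # peak never isolated (identical heights): own cell only
        region = np.zeros_like(p, dtype=bool)
        region[peaks[k]] = True
        regions[k] = region

    pts = np.asarray(points.points)
    ci, cj = _point_cells(pts, grid)
    labels = np.full(len(pts), -1, dtype=int)
    for k in range(len(peaks)):
        mask = regions[k][ci, cj] & (labels == -1)
        labels[mask] = k

    # discard undersized clusters, then reindex surviving ones
    surviving = [k for k in range(len(peaks)) if (labels == k).sum() >= min_cluster_size]
    if not surviving:
        warnings.warn("no cluster meets the minimum size", stacklevel=2)
    new_labels = np.full(len(pts), -1, dtype=int)
    for new_k, k in enumerate(surviving):
        new_labels[labels == k] = new_k
    return ClusterAssignment(peaks=[peaks[k] for k in surviving], labels=new_labels)


def silhouette(points, labels) -> tuple[np.ndarray, float]:
    """Per-point silhouettes and their mean over all clustered points.

    a(i) is the mean distance to the other members of i's cluster, b(i) the
    smallest mean distance to another cluster, s = (b - a)/max(a, b).
    Unclustered points (label -1) are excluded.
    """
    pts = np.asarray(points.points if isinstance(points, Embedding2D) else points)
    labels = np.asarray(labels)
    clusters = [c for c in np.unique(labels) if c != -1]
    if len(clusters) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    mask = labels != -1
    idx = np.flatnonzero(mask)
    d = cdist(pts[idx], pts[idx])
    lab = labels[idx]
    s = np.full(len(labels), np.nan)
    for pos, i in enumerate(idx):
        own = lab == lab[pos]
        n_own = own.sum()
        if n_own < 2:
            s[i] = 0.0
            continue
        a = d[pos, own].sum() / (n_own - 1)
        b = min(d[pos, lab == c].mean() for c in clusters if c != lab[pos])
        s[i] = (b - a) / max(a, b)
    return s, float(np.nanmean(s[mask]))


def per_cluster_silhouette(points, labels) -> dict[int, float]:
    s, _ = silhouette(points, labels)
    labels = np.asarray(labels)
    return {
        int(c): float(np.nanmean(s[labels == c]))
        for c in np.unique(labels)
        if c != -1
    }


def occupancy(assignment: ClusterAssignment) -> np.ndarray:
    """Cluster sizes divided by the total number of clustered structures."""
    if assignment.n_clusters == 0:
        raise ValueError("no clusters")
    return assignment.sizes / assignment.sizes.sum()


def select_intermediates(
    points: Embedding2D,
    assignment: ClusterAssignment,
    grid: DensityGrid,
    peak_pair: tuple[int, int],
    radius_frac: float = 0.05,
) -> np.ndarray:
    """Indices of unclustered points near the midpoint between two cluster centers.

    The search radius defaults to 5% of the larger embedding span.
    """
    ka, kb = peak_pair
    pa = np.array([grid.x[assignment.peaks[ka][0]], grid.y[assignment.peaks[ka][1]]])
    pb = np.array([grid.x[assignment.peaks[kb][0]], grid.y[assignment.peaks[kb][1]]])
    mid = 0.5 * (pa + pb)
    pts = np.asarray(points.points)
    span = max(pts.max(axis=0) - pts.min(axis=0))
    r = radius_frac * span
    dist = np.linalg.norm(pts - mid, axis=1)
    return np.flatnonzero((assignment.labels == -1) & (dist <= r))
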