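"""Per-structure distance matrices: the embedding input and feature substrate.

The clustering pipeline represents every single-cell chromosome structure by a
pairwise bead distance matrix.  Two conventions are used: surface-to-surface
(``||x_i - x_j|| - 2 R_bead``, the autoencoder input after max-normalization)
and center-to-center (feature calculations, min-max normalized before
averaging).  Matrices destined for the autoencoder are resized to a side that
is a multiple of 50 (= 5*5*2, the product of the pooling windows) by bilinear
interpolation.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.distance import pdist, squareform

from .genome_model import BinAnnotation, ChromosomeStructure


def filter_beads(
    s: ChromosomeStructure, ann: BinAnnotation
) -> tuple[ChromosomeStructure, np.ndarray]:
    """Drop unrestrained ("cen": centromere/telomere) beads.

    Returns the filtered structure plus the retained-index map into the
    original bead order, needed to re-expand per-bin profiles to genome
    coordinates later.
    """
    bins = ann.for_chrom(s.chrom)
    if len(bins) != s.n_beads:
        raise ValueError(
            f"annotation has {len(bins)} bins for {s.chrom} but structure has {s.n_beads} beads"
        )
    keep = np.flatnonzero((bins["category"] != "cen").to_numpy())
    if len(keep) == 0:
        warnings.warn(f"all beads of {s.chrom} are 'cen'; empty structure", stacklevel=2)
    out = ChromosomeStructure(
        structure_id=s.structure_id,
        chrom=s.chrom,
        copy=s.copy,
        coords=s.coords[keep] if len(keep) else np.empty((0, 3)),
        r_bead=s.r_bead,
        bin_index=s.bin_index[keep],
    )
    return out, keep


def expand_track(track: np.ndarray, retained_idx: np.ndarray, n_bins: int) -> np.ndarray:
    """Re-expand a filtered-bead track to full bin coordinates (NaN where removed)."""
    out = np.full(n_bins, np.nan)
    out[np.asarray(retained_idx, dtype=int)] = track
    return out


def center_distance_matrix(s: ChromosomeStructure) -> np.ndarray:
    """Euclidean center-to-center distances, zero diagonal."""
    return squareform(pdist(s.coords))


def surface_distance_matrix(s: ChromosomeStructure, clip_negative: bool = True) -> np.ndarray:
    """Surface-to-surface distances: ``||x_i - x_j|| - 2 R_bead`` off-diagonal, 0 on.

    Overlapping beads would give small negative distances; those are clipped to
    zero by default so the max-normalized matrix stays in [0, 1].
    """
    if s.n_beads < 2:
        raise ValueError("need at least 2 beads")
    d = center_distance_matrix(s) - 2.0 * s.r_bead
    np.fill_diagonal(d, 0.0)
    if clip_negative:
        np.clip(d, 0.0, None, out=d)
    return d


def normalize_max(m: np.ndarray) -> np.ndarray:
    """Divide by the maximum entry so the largest distance becomes 1."""
    m = np.asarray(m, dtype=float)
    mx = m.max()
    if mx <= 0:
        raise ValueError("cannot max-normalize an all-zero matrix")
    return m / mx


def normalize_minmax(m: np.ndarray) -> np.ndarray:
    """Affinely map off-diagonal entries to [0, 1]; diagonal stays 0."""
    m = np.asarray(m, dtype=float)
    off = ~np.eye(len(m), dtype=bool)
    lo, hi = m[off].min(), m[off].max()
    if hi <= lo:
        raise ValueError("constant off-diagonal matrix cannot be min-max normalized")
    out = (m - lo) / (hi - lo)
    np.fill_diagonal(out, 0.0)
    return out


def resize_to_multiple_of_50(m: np.ndarray) -> np.ndarray:
    """Resize a square matrix to the nearest multiple of 50 (ties round down)
    by bilinear interpolation, treating the matrix as an image.

    Corner values are preserved exactly (the sampling grid runs from index 0
    to index side-1 in both source and target).
    """
    m = np.asarray(m, dtype=float)
    n = m.shape[0]
    if m.ndim != 2 or m.shape[1] != n:
        raise ValueError("matrix must be square")
    if n < 50:
        raise ValueError("matrix side must be at least 50")
    q, r = divmod(n, 50)
    target = max(q * 50, 50) if r <= 25 else (q + 1) * 50  # ties (r==25) round down
    if target == n:
        return m.copy()
    grid = np.linspace(0.0, n - 1.0, target)
    rows, cols = np.meshgrid(grid, grid, indexing="ij")
    return map_coordinates(m, [rows, cols], order=1, mode="nearest")


def downsample_coverage(
    obj, step: int | None = None, bin_width: int = 200_000,
    positions: np.ndarray | None = None,
):
    """Reduce genomic coverage: one bead per ``step``-bp window, or arbitrary
    retained bin indices (e.g., imaged-locus positions for tracing matching).

    Works on a :class:`ChromosomeStructure` (beads re-selected) or on a square
    matrix (submatrix of retained rows/columns).  Returns ``(reduced,
    retained_idx)``.
    """
    if positions is None:
        if step is None:
            raise ValueError("give either step or positions")
        if step < bin_width or step % bin_width:
            raise ValueError("step must be a positive multiple of the bin width")
        per = step // bin_width
        n = obj.n_beads if isinstance(obj, ChromosomeStructure) else len(obj)
        starts = np.arange(0, n, per)
        # central bin of each window
        idx = np.minimum(starts + per // 2, n - 1)
        idx = np.unique(idx)
    else:
        idx = np.asarray(positions, dtype=int)
    if isinstance(obj, ChromosomeStructure):
        red = ChromosomeStructure(
            structure_id=obj.structure_id,
            chrom=obj.chrom,
            copy=obj.copy,
            coords=obj.coords[idx],
            r_bead=obj.r_bead,
            bin_index=obj.bin_index[idx],
        )
        return red, idx
    m = np.asarray(obj)
    return m[np.ix_(idx, idx)], idx


def structure_matrices(
    structures, ann: BinAnnotation | None = None, resize: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Build the autoencoder input stack for a set of chromosome structures.

    Each structure is cen-filtered (when an annotation is given), converted to
    a max-normalized surface-distance matrix and resized to a multiple of 50.
    Returns ``(stack, retained_idx)`` with stack shape (n, side, side).
    """
    mats = []
    keep = None
    for s in structures:
        if ann is not None:
            s, keep = filter_beads(s, ann)
        else:
            keep = np.arange(s.n_beads)
        m = normalize_max(surface_distance_matrix(s))
        if resize:
            m = resize_to_multiple_of_50(m)
        mats.append(m.astype(np.float32))
    return np.stack(mats), keep
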