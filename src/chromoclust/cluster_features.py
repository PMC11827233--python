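"""Per-cluster averaged matrices and per-bin structural feature tracks.

For every morphology cluster the pipeline builds a contact-frequency matrix
(sum of per-structure binary contact maps, contact iff center distance
<= 3 R_bead) and an average min-max-normalized distance matrix, then derives
per-bin tracks from them: insulation scores (contact and distance variants),
territory-domain boundaries, contact probability P(s), local radius of
gyration, radial position (RAD) and its variability, and A/B compartment
eigenvectors.  Cluster tracks are compared to the ensemble of all clustered
structures through generic log2 ratio tracks (RadRatio, RgRatio, ...).
"""

from __future__ import annotations

import string
import warnings

import numpy as np
from scipy.signal import find_peaks

from .distmat import center_distance_matrix, normalize_minmax
from .genome_model import ChromosomeStructure, NucleusGeometry

CONTACT_FACTOR = 3.0  # contact iff center distance <= 3 R_bead
DISTANCE_BINARIZE_DEFAULT = 0.45  # within the 0.4-0.5 range


def contact_matrix(s: ChromosomeStructure, factor: float = CONTACT_FACTOR) -> np.ndarray:
    """Binary contact map: 1 iff ||x_i - x_j|| <= factor * R_bead (inclusive)."""
    d = center_distance_matrix(s)
    return (d <= factor * s.r_bead).astype(np.int64)


def cluster_contact_matrix(structures, factor: float = CONTACT_FACTOR) -> np.ndarray:
    """Sum of binary contact maps over cluster members (integer counts)."""
    it = iter(structures)
    first = next(it)
    cm = contact_matrix(first, factor)
    for s in it:
        cm += contact_matrix(s, factor)
    return cm


def average_distance_matrix(structures) -> np.ndarray:
    """Mean of per-structure min-max-normalized center-distance matrices."""
    mats = [normalize_minmax(center_distance_matrix(s)) for s in structures]
    if not mats:
        raise ValueError("need at least one structure")
    return np.mean(mats, axis=0)


# ---------------------------------------------------------------------------
# insulation / boundaries / domains
# ---------------------------------------------------------------------------


def insulation_profile(
    m: np.ndarray,
    variant: str = "distance",
    window: int = 30,
    binarize_threshold: float = DISTANCE_BINARIZE_DEFAULT,
) -> np.ndarray:
    """Sliding-window insulation score along the matrix diagonal.

    For bin i the left window covers bins [i-l, i-1] and the right window
    [i, i+l-1] (the right window includes i).  With LM/RM the strict upper
    triangles of the within-window submatrices and M the cross-window block:

    * ``contact`` variant (on a contact-frequency matrix):
      is_i = sum(LM) + sum(RM) - sum(M); maxima mark insulated positions.
    * ``distance`` variant (on an average distance matrix binarized at
      ``binarize_threshold``, 1 where the distance is larger):
      is_i = sum(M) - sum(LM) - sum(RM); maxima mark domain boundaries.

    Bins within one window of the chromosome ends are NaN.
    """
    m = np.asarray(m, dtype=float)
    n = len(m)
    l = int(window)
    if l > n // 2:
        raise ValueError(f"window {l} larger than half the matrix side {n}")
    if variant == "distance":
        m = (m > binarize_threshold).astype(float)
    elif variant != "contact":
        raise ValueError(f"unknown variant {variant!r}")
    out = np.full(n, np.nan)
    iu = np.triu_indices(l, k=1)
    for i in range(l, n - l + 1):
        left = m[i - l : i, i - l : i]
        right = m[i : i + l, i : i + l]
        cross = m[i - l : i, i : i + l]
        within = left[iu].sum() + right[iu].sum()
        if variant == "contact":
            out[i] = within - cross.sum()
        else:
            out[i] = cross.sum() - within
    return out


def call_boundaries(
    dm: np.ndarray,
    coarse_window: int,
    fine_window: int,
    binarize_threshold: float = DISTANCE_BINARIZE_DEFAULT,
    prominence_sd: float = 1.0,
) -> list[int]:
    """Two-pass territory-domain boundary calling on an average distance matrix.

    Windows are in bins.  Local maxima of the coarse-window distance-variant
    insulation profile (minimum prominence: ``prominence_sd`` standard
    deviations of the profile) delimit candidate regions; within each
    candidate region the fine-window profile's maximum gives the boundary bin.
    """
    coarse = insulation_profile(dm, "distance", coarse_window, binarize_threshold)
    fine = insulation_profile(dm, "distance", fine_window, binarize_threshold)
    valid = np.nan_to_num(coarse, nan=-np.inf)
    sd = np.nanstd(coarse)
    if not np.isfinite(sd) or sd == 0:
        return []
    peaks, _ = find_peaks(valid, prominence=prominence_sd * sd)
    bounds = []
    half = max(coarse_window // 2, 1)
    for p in peaks:
        lo, hi = max(0, p - half), min(len(dm), p + half + 1)
        seg = fine[lo:hi]
        if np.all(np.isnan(seg)):
            bounds.append(int(p))
            continue
        bounds.append(int(lo + np.nanargmax(seg)))
    return sorted(set(bounds))


def boundary_zscores(dm: np.ndarray, boundaries, window: int,
                     binarize_threshold: float = DISTANCE_BINARIZE_DEFAULT) -> np.ndarray:
    """Insulation z-score of each called boundary relative to its profile."""
    prof = insulation_profile(dm, "distance", window, binarize_threshold)
    mu, sd = np.nanmean(prof), np.nanstd(prof)
    if sd == 0:
        return np.zeros(len(boundaries))
    return np.array([(prof[b] - mu) / sd for b in boundaries])


def territory_domains(boundaries, n_bins: int, bin_width: int = 200_000) -> list[dict]:
    """Label the intervals between consecutive boundaries (a, b, c, ...)."""
    cuts = [0] + sorted(int(b) for b in boundaries) + [n_bins]
    out = []
    for k, (s, e) in enumerate(zip(cuts[:-1], cuts[1:])):
        if e <= s:
            continue
        out.append(
            {
                "label": string.ascii_lowercase[k % 26],
                "start_bin": s,
                "end_bin": e,
                "start_bp": s * bin_width,
                "end_bp": e * bin_width,
            }
        )
    return out


# ---------------------------------------------------------------------------
# P(s), radius of gyration, radial tracks
# ---------------------------------------------------------------------------


def contact_probability_curve(
    cm: np.ndarray, n_structures: int, band_edges=None
) -> tuple[np.ndarray, np.ndarray]:
    """Mean contact probability per genomic-separation band.

    Returns ``(band_midpoints, probabilities)``; the diagonal (s = 0) is
    excluded and each band is normalized by its pair count and the number of
    structures.  Default bands are logarithmic between 1 and n - 1.
    """
    cm = np.asarray(cm, dtype=float)
    n = len(cm)
    if band_edges is None:
        band_edges = np.unique(np.geomspace(1, n - 1, num=12).astype(int))
        band_edges = np.append(band_edges, n)
    seps = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    mids, probs = [], []
    for lo, hi in zip(band_edges[:-1], band_edges[1:]):
        mask = (seps >= lo) & (seps < hi) & (seps > 0)
        npairs = mask.sum()
        if npairs == 0:
            continue
        mids.append(np.sqrt(lo * (hi - 1)))
        probs.append(cm[mask].sum() / (npairs * n_structures))
    return np.asarray(mids), np.asarray(probs)


def rg_profile(s: ChromosomeStructure, window_bins: int = 5) -> np.ndarray:
    """Local radius of gyration of the window centered at each bin.

    rg_i = sqrt(mean_j d_j^2) over the window beads, d_j the distance to the
    window's center of mass; the default 5 bins span 1 Mb at 200-kb bins.
    Ends (incomplete windows) are NaN.
    """
    half = window_bins // 2
    n = s.n_beads
    out = np.full(n, np.nan)
    for i in range(half, n - half):
        seg = s.coords[i - half : i + half + 1]
        d = seg - seg.mean(axis=0)
        out[i] = np.sqrt((d**2).sum(axis=1).mean())
    return out


def structure_rg(s: ChromosomeStructure) -> float:
    """Whole-structure radius of gyration."""
    return s.radius_of_gyration()


def cluster_rg_profile(structures, window_bins: int = 5) -> np.ndarray:
    return np.nanmean([rg_profile(s, window_bins) for s in structures], axis=0)


def radial_positions(structures, geometry: NucleusGeometry) -> np.ndarray:
    """(n_structures, n_beads) normalized radial positions."""
    return np.stack([geometry.radial_position(s.coords) for s in structures])


def radial_track(structures, geometry: NucleusGeometry) -> np.ndarray:
    """RAD: per-bin mean radial position over the cluster."""
    return radial_positions(structures, geometry).mean(axis=0)


def variability_track(structures, geometry: NucleusGeometry) -> np.ndarray:
    """deltaRAD: log2 of the per-bin radial-position standard deviation over
    its chromosome-wide mean.  Bins with zero variability are NaN."""
    sig = radial_positions(structures, geometry).std(axis=0)
    mean_sig = sig.mean()
    out = np.full_like(sig, np.nan)
    ok = (sig > 0) & (mean_sig > 0)
    out[ok] = np.log2(sig[ok] / mean_sig)
    return out


def log2_ratio_track(cluster_track, ensemble_track) -> np.ndarray:
    """log2(cluster / ensemble) per bin; NaN where either side is not positive."""
    c = np.asarray(cluster_track, dtype=float)
    e = np.asarray(ensemble_track, dtype=float)
    if c.shape != e.shape:
        raise ValueError("track lengths differ")
    out = np.full_like(c, np.nan)
    ok = np.isfinite(c) & np.isfinite(e) & (c > 0) & (e > 0)
    out[ok] = np.log2(c[ok] / e[ok])
    return out


# ---------------------------------------------------------------------------
# A/B compartments
# ---------------------------------------------------------------------------


def ab_compartments(
    cm: np.ndarray, reference_track: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """A/B compartment calling by eigenvector decomposition of the O/E
    correlation matrix of a contact-frequency matrix.

    The observed/expected matrix divides each entry by the mean of its
    |i - j| diagonal band; the Pearson correlation matrix of its rows is then
    eigendecomposed.  Both PC1 and PC2 are returned (either may carry the
    compartment signal).  When a reference track (e.g., gene density) is
    given, each eigenvector's sign is oriented so it correlates positively
    with the reference.  Zero rows are masked and come back as NaN.
    """
    cm = np.asarray(cm, dtype=float)
    n = len(cm)
    nz = cm.sum(axis=1) > 0
    if nz.sum() < 3:
        raise ValueError("contact matrix too sparse for eigendecomposition")
    sub = cm[np.ix_(nz, nz)]
    m = len(sub)
    seps = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    expected = np.zeros(m)
    for s in range(m):
        expected[s] = sub[seps == s].mean()
    exp_mat = expected[seps]
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(exp_mat > 0, sub / exp_mat, 0.0)
    if np.allclose(oe.std(axis=1), 0):
        warnings.warn("uniform matrix: compartment eigenvectors are degenerate", stacklevel=2)
        corr = np.zeros((m, m))
    else:
        corr = np.corrcoef(oe)
        corr = np.nan_to_num(corr)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    tracks = {}
    for rank, name in enumerate(("PC1", "PC2")):
        v = evecs[:, order[rank]]
        full = np.full(n, np.nan)
        full[nz] = v
        if reference_track is not None:
            ref = np.asarray(reference_track, dtype=float)[nz]
            ok = np.isfinite(ref)
            if ok.sum() > 2 and np.corrcoef(v[ok], ref[ok])[0, 1] < 0:
                full = -full
        tracks[name] = full
    tracks["eigenvalues"] = evals[order[:2]]
    return tracks
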