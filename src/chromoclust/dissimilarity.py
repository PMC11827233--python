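"""Intra- vs inter-cluster structural dissimilarity.

Three measures quantify how different two sets of chromosome structures are:
Euclidean distance between flattened pair-distance vectors, a Gaussian overlap
dissimilarity (Eastwood–Wolynes style, width sigma = 8 R_bead), and the mean
1-Wasserstein distance between the per-bead-pair distance distributions of the
two clusters.  Each is reported raw and as the log2 fold ratio over the
intra-cluster value of the row cluster, which is ~0 within clusters and
positive between genuinely distinct morphologies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import wasserstein_distance

from .genome_model import R_BEAD_DEFAULT

SAMPLE_SIZE_DEFAULT = 200  # structures sampled per cluster for pair averaging


@dataclass
class DissimilarityReport:
    measure: str
    inter: float  # s(A, B)
    intra: float  # s(A, A)
    log2_ratio: float  # rs(A, B) = log2(inter / intra)



def _log_ratio(inter: float, intra: float) -> float:
    """log2(inter/intra); NaN when either side is zero/empty (no defined ratio)."""
    if not (inter > 0 and intra > 0):
        return float("nan")
    return float(np.log2(inter / intra))

def _pair_distance_vectors(structures) -> np.ndarray:
    """(n_structures, n_pairs) flattened center-distance vectors."""
    vecs = [pdist(s.coords) for s in structures]
    n = {len(v) for v in vecs}
    if len(n) != 1:
        raise ValueError("structures must share bead count")
    return np.asarray(vecs)


def _subsample(n: int, size: int, rng) -> np.ndarray:
    if n <= size:
        return np.arange(n)
    return rng.choice(n, size=size, replace=False)


def _euclidean_pairs(ra: np.ndarray, rb: np.ndarray, cross: bool) -> float:
    """Mean ||R(a) - R(b)||_2 over all (sampled) structure pairs."""
    if cross:
        from scipy.spatial.distance import cdist

        return float(cdist(ra, rb).mean())
    if len(ra) < 2:
        return float("nan")
    return float(pdist(ra).mean())


def _gaussian_pairs(ra, rb, sigma, cross: bool) -> float:
    vals = []
    for i, va in enumerate(ra):
        jb = rb if cross else rb[i + 1 :]
        if not len(jb):
            continue
        vals.append(1.0 - np.exp(-((jb - va) ** 2) / (2 * sigma**2)).mean(axis=1))
    if not vals:
        return float("nan")
    return float(np.concatenate(vals).mean())


def euclidean_dissimilarity(
    A, B, sample: int = SAMPLE_SIZE_DEFAULT, seed: int = 0
) -> DissimilarityReport:
    """s_e(a,b) = ||R(a) - R(b)||_2 on flattened pair-distance vectors,
    averaged over sampled cross pairs; intra value from disjoint pairs within A."""
    rng = np.random.default_rng(seed)
    ra = _pair_distance_vectors(A)
    rb = _pair_distance_vectors(B)
    if ra.shape[1] != rb.shape[1]:
        raise ValueError("clusters must share bead count")
    ra_s = ra[_subsample(len(ra), sample, rng)]
    rb_s = rb[_subsample(len(rb), sample, rng)]
    inter = _euclidean_pairs(ra_s, rb_s, cross=True)
    intra = _euclidean_pairs(ra_s, ra_s, cross=False)
    return DissimilarityReport("euclidean", inter, intra, _log_ratio(inter, intra))


def gaussian_dissimilarity(
    A, B, sigma: float | None = None, sample: int = SAMPLE_SIZE_DEFAULT, seed: int = 0
) -> DissimilarityReport:
    """s_g(a,b) = 1 - mean_{i<j} exp(-(d_ij(a)-d_ij(b))^2 / (2 sigma^2)),
    sigma defaulting to 8 R_bead."""
    if sigma is None:
        sigma = 8.0 * getattr(A[0], "r_bead", R_BEAD_DEFAULT)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    ra = _pair_distance_vectors(A)
    rb = _pair_distance_vectors(B)
    ra_s = ra[_subsample(len(ra), sample, rng)]
    rb_s = rb[_subsample(len(rb), sample, rng)]
    inter = _gaussian_pairs(ra_s, rb_s, sigma, cross=True)
    intra = _gaussian_pairs(ra_s, ra_s, sigma, cross=False)
    return DissimilarityReport("gaussian", inter, intra, _log_ratio(inter, intra))


def wasserstein_dissimilarity(A, B, seed: int = 0) -> DissimilarityReport:
    """Mean 1-Wasserstein distance between per-pair distance distributions.

    The intra value follows the half-split convention: a sampled half of A
    (indices i) against the reversed complementary half (indices M - i - 1).
    """
    ra = _pair_distance_vectors(A)
    rb = _pair_distance_vectors(B)
    if ra.shape[1] != rb.shape[1]:
        raise ValueError("clusters must share bead count")
    if len(ra) < 2:
        raise ValueError("intra split needs at least 2 structures in A")
    inter = float(
        np.mean([wasserstein_distance(ra[:, p], rb[:, p]) for p in range(ra.shape[1])])
    )
    m = len(ra)
    rng = np.random.default_rng(seed)
    half = rng.choice(m, size=m // 2, replace=False)
    rev = np.array([m - i - 1 for i in half])
    intra = float(
        np.mean(
            [wasserstein_distance(ra[half, p], ra[rev, p]) for p in range(ra.shape[1])]
        )
    )
    return DissimilarityReport("wasserstein", inter, intra, _log_ratio(inter, intra))


_MEASURES = {
    "euclidean": euclidean_dissimilarity,
    "gaussian": gaussian_dissimilarity,
    "wasserstein": wasserstein_dissimilarity,
}


def dissimilarity_matrix(clusters: dict, measure: str, seed: int = 0, **kw) -> np.ndarray:
    """K x K matrix of rs(A, B) = log2(s(A,B) / s(A,A)), row-normalized by the
    row cluster's intra value; zero diagonal."""
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    keys = sorted(clusters)
    if len(keys) < 2:
        raise ValueError("need at least 2 clusters")
    fn = _MEASURES[measure]
    out = np.zeros((len(keys), len(keys)))
    intras = {}
    for ai, ka in enumerate(keys):
        rep = fn(clusters[ka], clusters[ka], seed=seed, **kw)
        intras[ka] = rep.intra
    for ai, ka in enumerate(keys):
        for bi, kb in enumerate(keys):
            if ai == bi:
                continue
            rep = fn(clusters[ka], clusters[kb], seed=seed, **kw)
            out[ai, bi] = np.log2(rep.inter / intras[ka])
    return out
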