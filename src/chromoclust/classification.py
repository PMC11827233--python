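"""Classification of external single-cell data against morphology clusters.

Two experimental modalities are supported.  Sparse single-cell Hi-C contact
maps are first imputed (box-filter convolution, then a random walk with
restart on the row-normalized transition matrix, then per-row binarization at
the 75th percentile) and scored against per-cluster superiority/inferiority
masks derived from the log2 difference between the cluster and population
contact-frequency matrices.  Chromatin-tracing structures are scored by the
Pearson correlation between their min-max-normalized distance vectors and the
cluster average distance matrices downsampled to the imaged loci.  Both
assignments require a margin between the best and second-best score; a
diagonal-preserving shuffle provides the randomized control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.stats import pearsonr

SUPERIORITY_THRESHOLD = 5.0
INFERIORITY_THRESHOLD = -1.0
SCIHIC_MARGIN = 0.01
TRACING_MARGIN = 0.05


@dataclass
class ClusterMasks:
    superiority: np.ndarray  # binary, d >= 5
    inferiority: np.ndarray  # binary, d <= -1
    difference: np.ndarray  # d_ij, NaN where undefined

    def __post_init__(self):
        if (self.superiority * self.inferiority).any():
            raise ValueError("masks must be disjoint")


@dataclass
class AssignmentResult:
    scores: dict  # cluster id -> s^(A)
    assigned: object  # best cluster id or None
    probability: float | None  # p of the winning cluster
    margin: float

    @property
    def probabilities(self) -> dict:
        total = sum(self.scores.values())
        return {k: v / total for k, v in self.scores.items()}


# ---------------------------------------------------------------------------
# sci-Hi-C imputation
# ---------------------------------------------------------------------------


def convolve_contacts(raw: np.ndarray, w: int = 5) -> np.ndarray:
    """Box-filter convolution with a (2w+1)^2 window of ones, zero padding."""
    raw = np.asarray(raw, dtype=float)
    size = 2 * w + 1
    return uniform_filter(raw, size=size, mode="constant", cval=0.0) * size**2


def transition_matrix(conv: np.ndarray) -> np.ndarray:
    """Row-normalize to a stochastic matrix; all-zero rows stay zero."""
    conv = np.asarray(conv, dtype=float)
    rowsum = conv.sum(axis=1, keepdims=True)
    zero = rowsum[:, 0] == 0
    if zero.any():
        warnings.warn(f"{zero.sum()} all-zero rows left unnormalized", stacklevel=2)
    rowsum[rowsum == 0] = 1.0
    return conv / rowsum


def random_walk_with_restart(
    mtrans: np.ndarray,
    restart_p: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Iterate R_t = (1-p) R_{t-1} M + p I from R_0 = I until the Frobenius
    norm of the step falls below ``tol``."""
    n = len(mtrans)
    eye = np.eye(n)
    r = eye.copy()
    for _ in range(max_iter):
        r_next = (1 - restart_p) * (r @ mtrans) + restart_p * eye
        if np.linalg.norm(r_next - r) <= tol:
            return r_next
        r = r_next
    resid = np.linalg.norm(r_next - r)
    raise RuntimeError(f"random walk did not converge; residual {resid:.3e}")


def binarize_by_row_percentile(r: np.ndarray, q: float = 75.0) -> np.ndarray:
    """Keep entries strictly above the q-th percentile of their row."""
    r = np.asarray(r, dtype=float)
    thr = np.percentile(r, q, axis=1, keepdims=True)
    return (r > thr).astype(np.int8)


def impute_scihic(
    raw: np.ndarray,
    w: int = 5,
    restart_p: float = 0.5,
    tol: float = 1e-6,
    percentile: float = 75.0,
) -> np.ndarray:
    """Full sparse-cell imputation: convolve, row-normalize, random walk with
    restart, per-row percentile binarization."""
    conv = convolve_contacts(raw, w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = transition_matrix(conv)
    r = random_walk_with_restart(m, restart_p=restart_p, tol=tol)
    return binarize_by_row_percentile(r, percentile)


# ---------------------------------------------------------------------------
# mask scoring
# ---------------------------------------------------------------------------


def build_masks(
    cluster_cm: np.ndarray,
    population_cm: np.ndarray,
    s_cluster: int,
    s_population: int,
    sup_threshold: float = SUPERIORITY_THRESHOLD,
    inf_threshold: float = INFERIORITY_THRESHOLD,
) -> ClusterMasks:
    """Difference matrix d = log2(S_A m^Pop / (S_Pop m^A)) and its masks.

    Superiority: d >= 5 (population strongly enriched over the cluster);
    inferiority: d <= -1 (cluster enriched).  Entries with a zero numerator
    or denominator are undefined and belong to neither mask.
    """
    a = np.asarray(cluster_cm, dtype=float)
    p = np.asarray(population_cm, dtype=float)
    if a.shape != p.shape:
        raise ValueError("matrices must share shape")
    d = np.full(a.shape, np.nan)
    ok = (a > 0) & (p > 0)
    d[ok] = np.log2((s_cluster * p[ok]) / (s_population * a[ok]))
    sup = np.zeros(a.shape, dtype=np.int8)
    inf = np.zeros(a.shape, dtype=np.int8)
    sup[ok & (np.nan_to_num(d, nan=0.0) >= sup_threshold)] = 1
    inf[ok & (np.nan_to_num(d, nan=0.0) <= inf_threshold)] = 1
    return ClusterMasks(superiority=sup, inferiority=inf, difference=d)


def score_scihic(
    cell: np.ndarray, masks: dict, margin: float = SCIHIC_MARGIN
) -> AssignmentResult:
    """Score an imputed (binarized) cell matrix against every cluster's masks.

    s^(A) = exp(<M, M_inf>/<E, M_inf> - <M, M_sup>/<E, M_sup>); the cell is
    assigned to the argmax cluster iff the top-two margin is at least
    ``margin``, otherwise unassigned.
    """
    cell = np.asarray(cell, dtype=float)
    scores = {}
    for cid, mk in masks.items():
        terms = []
        for m in (mk.inferiority, mk.superiority):
            tot = m.sum()
            if tot == 0:
                warnings.warn(f"cluster {cid}: empty mask treated as 0", stacklevel=2)
                terms.append(0.0)
            else:
                terms.append(float((cell * m).sum()) / tot)
        scores[cid] = float(np.exp(terms[0] - terms[1]))
    ordered = sorted(scores, key=scores.get, reverse=True)
    best = ordered[0]
    gap = scores[best] - (scores[ordered[1]] if len(ordered) > 1 else -np.inf)
    assigned = best if gap >= margin else None
    total = sum(scores.values())
    prob = scores[best] / total if assigned is not None else None
    return AssignmentResult(scores=scores, assigned=assigned, probability=prob, margin=margin)


def randomize_control(raw: np.ndarray, seed: int = 0) -> np.ndarray:
    """Diagonal-preserving shuffle: permute the upper-triangle off-diagonal
    entries uniformly at random and mirror, keeping the total contact count."""
    raw = np.asarray(raw)
    if not np.allclose(raw, raw.T):
        raise ValueError("control shuffling expects a symmetric matrix")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(raw)
    iu = np.triu_indices(len(raw), k=1)
    vals = raw[iu]
    perm = rng.permutation(len(vals))
    out[iu] = vals[perm]
    out = out + out.T
    out[np.diag_indices(len(raw))] = raw.diagonal()
    return out


def symmetrize_min(cm: np.ndarray) -> np.ndarray:
    """Entrywise minimum of (i, j) and (j, i) counts."""
    cm = np.asarray(cm)
    return np.minimum(cm, cm.T)


# ---------------------------------------------------------------------------
# chromatin-tracing classification
# ---------------------------------------------------------------------------


def _minmax_vector(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi <= lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def classify_structure(
    dm: np.ndarray, cluster_dms: dict, margin: float = TRACING_MARGIN
) -> AssignmentResult:
    """Assign a single-cell distance matrix to the best-matching cluster.

    Both the cell matrix and each cluster average matrix (already downsampled
    to the cell's loci) are flattened to their upper triangles, min-max
    normalized, and compared by Pearson correlation; s^(A) = exp(r).  The
    result is scale-invariant in the input coordinates.
    """
    dm = np.asarray(dm, dtype=float)
    n = len(dm)
    if n < 3:
        raise ValueError("need at least 3 loci")
    iu = np.triu_indices(n, k=1)
    v = _minmax_vector(dm[iu])
    scores = {}
    for cid, cdm in cluster_dms.items():
        if len(cdm) != n:
            raise ValueError(f"cluster {cid} matrix side {len(cdm)} != cell side {n}")
        w = _minmax_vector(np.asarray(cdm, dtype=float)[iu])
        r, _ = pearsonr(v, w)
        scores[cid] = float(np.exp(r))
    ordered = sorted(scores, key=scores.get, reverse=True)
    best = ordered[0]
    gap = scores[best] - (scores[ordered[1]] if len(ordered) > 1 else -np.inf)
    assigned = best if gap >= margin else None
    prob = scores[best] / sum(scores.values()) if assigned is not None else None
    return AssignmentResult(scores=scores, assigned=assigned, probability=prob, margin=margin)


def transcription_ratio(trans_on: np.ndarray, labels: np.ndarray, locus: int) -> dict:
    """Per-cluster log2 ratio of mean transcription at a locus over the mean
    across all clustered copies; NaN denominator propagates as NaN."""
    trans_on = np.asarray(trans_on, dtype=float)
    labels = np.asarray(labels)
    clustered = labels != -1
    overall = np.nanmean(trans_on[clustered, locus])
    out = {}
    for c in np.unique(labels[clustered]):
        mu = np.nanmean(trans_on[labels == c, locus])
        if overall > 0 and mu > 0:
            out[int(c)] = float(np.log2(mu / overall))
        else:
            out[int(c)] = np.nan
    return out
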