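"""Nuclear-topography features: speckles, TSA-seq, SAF, proximity maps, IPP.

Nuclear speckles are not modelled explicitly; their locations are predicted
per single cell as the geometric centers of highly connected subgraphs (>3
nodes) of the chromatin interaction network over speckle-associated (A1
subcompartment) beads, partitioned with the Markov Clustering algorithm.
From the predicted speckles the module derives per-bin tracks: mean distance
to the nearest speckle (SpD, bead surface to speckle center), a predicted
SON TSA-seq signal (exponentially decayed distance sum, decay constant 4 per
micrometre), and the speckle association frequency (SAF).  Inter-chromosomal
organisation is summarized by proximity-frequency maps (soft contact radius
2000 nm) and the inter-chromosomal proximity profile (IPP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist, pdist, squareform

from .genome_model import GenomePopulation, R_BEAD_DEFAULT

R_SOFT = 2000.0  # nm, proximity radius
TSA_DECAY = 4.0  # per micrometre
SAF_THRESHOLD_MODEL = 1000.0  # nm
SAF_THRESHOLD_TRACING = 500.0  # nm
SPECKLE_EDGE_FACTOR = 4.0  # edge iff center distance <= 4 R_bead
MIN_SPECKLE_NODES = 3  # subgraphs must be larger than this


@dataclass
class SpeckleSet:
    """Predicted speckles for a set of structures: per structure an array of
    speckle centers (nm) and the member-bead count of each."""

    centers: list  # list of (k_s, 3) arrays
    sizes: list  # list of (k_s,) integer arrays

    def __len__(self):
        return len(self.centers)


def markov_cluster(
    adjacency: np.ndarray,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> list[np.ndarray]:
    """Markov Clustering on a dense adjacency matrix.

    Self-loops are added, columns normalized to a stochastic flow matrix, and
    expansion (matrix power) alternates with inflation (entrywise power +
    renormalization) and pruning until the flow stabilizes.  Clusters are the
    connected components of the converged flow's support.
    """
    a = np.asarray(adjacency, dtype=float)
    n = len(a)
    if n == 0:
        return []
    m = a + np.eye(n)
    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m**inflation
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.abs(m - prev).max() <= tol:
            break
    support = ((m + m.T) > 0).astype(int)
    ncomp, labels = connected_components(support, directed=False)
    return [np.flatnonzero(labels == k) for k in range(ncomp)]


def predict_speckles(
    pop: GenomePopulation,
    edge_factor: float = SPECKLE_EDGE_FACTOR,
    inflation: float = 2.0,
    min_nodes: int = MIN_SPECKLE_NODES,
) -> SpeckleSet:
    """Predict speckle locations in every structure of a population.

    A graph over all A1-subcompartment beads (genome-wide, per cell) connects
    beads closer than ``edge_factor * R_bead``; MCL partitions it and every
    subgraph with more than ``min_nodes`` nodes contributes one speckle at the
    geometric center of its member beads.
    """
    a1 = np.flatnonzero((pop.beads["subcompartment"] == "A1").to_numpy())
    centers, sizes = [], []
    thr = edge_factor * pop.r_bead
    for xyz in pop.coords:
        if len(a1) == 0:
            centers.append(np.empty((0, 3)))
            sizes.append(np.empty(0, dtype=int))
            continue
        pts = xyz[a1]
        adj = (squareform(pdist(pts)) <= thr).astype(float)
        np.fill_diagonal(adj, 0.0)
        groups = markov_cluster(adj, inflation=inflation)
        cs, ss = [], []
        for g in groups:
            if len(g) > min_nodes:
                cs.append(pts[g].mean(axis=0))
                ss.append(len(g))
        centers.append(np.asarray(cs).reshape(-1, 3))
        sizes.append(np.asarray(ss, dtype=int))
    return SpeckleSet(centers=centers, sizes=sizes)


def _nearest_speckle_distances(
    coords_per_structure, speckles: SpeckleSet, r_bead: float, surface: bool
) -> np.ndarray:
    """(n_structures, n_beads) distances to nearest speckle; NaN when a
    structure has no speckles."""
    out = []
    for xyz, cen in zip(coords_per_structure, speckles.centers):
        if len(cen) == 0:
            out.append(np.full(len(xyz), np.nan))
            continue
        d = cdist(xyz, cen).min(axis=1)
        if surface:
            d = d - r_bead
        out.append(d)
    return np.asarray(out)


def speckle_distance_track(
    coords_per_structure,
    speckles: SpeckleSet,
    r_bead: float = R_BEAD_DEFAULT,
    convention: str = "surface",
) -> np.ndarray:
    """SpD: per-bin mean distance to the nearest speckle across structures.

    Structures without any predicted speckle are excluded from the mean.
    """
    d = _nearest_speckle_distances(
        coords_per_structure, speckles, r_bead, surface=(convention == "surface")
    )
    if np.all(np.isnan(d)):
        import warnings

        warnings.warn("no structure has predicted speckles", stacklevel=2)
    return np.nanmean(d, axis=0)


def son_tsaseq_signal(
    coords_per_structure,
    speckles: SpeckleSet,
    k: float = TSA_DECAY,
    r_bead: float = R_BEAD_DEFAULT,
) -> np.ndarray:
    """Raw predicted SON TSA-seq signal per bin: mean over structures of
    sum_l exp(-k d_il), with d the bead-surface-to-speckle distance in um."""
    sig = []
    for xyz, cen in zip(coords_per_structure, speckles.centers):
        if len(cen) == 0:
            sig.append(np.zeros(len(xyz)))
            continue
        d_um = (cdist(xyz, cen) - r_bead) / 1000.0
        sig.append(np.exp(-k * d_um).sum(axis=1))
    return np.mean(sig, axis=0)


def normalize_tsa(sg: np.ndarray, genome_mean: float | None = None) -> np.ndarray:
    """ts_i = log2(sg_i / genome-mean sg); by construction the bin-weighted
    mean of 2**ts is 1 when normalized by the mean of the same track."""
    sg = np.asarray(sg, dtype=float)
    mu = float(np.nanmean(sg)) if genome_mean is None else genome_mean
    out = np.full_like(sg, np.nan)
    ok = sg > 0
    if mu > 0:
        out[ok] = np.log2(sg[ok] / mu)
    return out


def saf_track(
    coords_per_structure,
    speckles: SpeckleSet,
    d_t: float = SAF_THRESHOLD_MODEL,
    r_bead: float = R_BEAD_DEFAULT,
) -> np.ndarray:
    """SAF: fraction of structures whose nearest-speckle (surface) distance
    at each bin is below the association threshold ``d_t``."""
    if d_t <= 0:
        raise ValueError("association threshold must be positive")
    d = _nearest_speckle_distances(coords_per_structure, speckles, r_bead, surface=True)
    return np.nanmean(d < d_t, axis=0)


# ---------------------------------------------------------------------------
# proximity maps and IPP
# ---------------------------------------------------------------------------


def _copy_indices(pop: GenomePopulation, chrom: str):
    beads = pop.beads
    return {
        int(c): np.flatnonzero(
            ((beads["chrom"] == chrom) & (beads["copy"] == c)).to_numpy()
        )
        for c in sorted(set(beads.loc[beads["chrom"] == chrom, "copy"]))
    }


def proximity_map(
    pop: GenomePopulation,
    members,
    chrom: str,
    r_soft: float = R_SOFT,
) -> np.ndarray:
    """Proximity-frequency map of a target chromosome against all beads.

    Entry (i, j): fraction of member structures in which target bin i is
    within ``r_soft`` of bead j.  Inter-chromosomal columns are averaged over
    the two homologous target copies; the intra-chromosomal block comes from
    the matching copy only.
    """
    members = list(members)
    copies = _copy_indices(pop, chrom)
    n_bins = len(next(iter(copies.values())))
    n_beads = pop.coords.shape[1]
    per_copy = {}
    for c, idx in copies.items():
        acc = np.zeros((n_bins, n_beads))
        for s in members:
            xyz = pop.coords[s]
            acc += cdist(xyz[idx], xyz) <= r_soft
        per_copy[c] = acc / len(members)
    out = np.mean([per_copy[c] for c in copies], axis=0)
    for c, idx in copies.items():
        cmask = ((pop.beads["chrom"] == chrom) & (pop.beads["copy"] == c)).to_numpy()
        out[:, cmask] = per_copy[c][:, cmask]
    return out


def ipp_track(
    pop: GenomePopulation,
    members,
    chrom: str,
    scope: str = "genome",
    partner: str | None = None,
    r_soft: float = R_SOFT,
) -> np.ndarray:
    """IPP: mean number of inter-chromosomal proximities per bin per structure.

    For each target bin, the count of beads of other chromosomes (or of one
    ``partner`` chromosome when scope='chromosome') within ``r_soft``, summed
    per structure and divided by the number of structures; averaged over both
    homologous copies of the target.
    """
    members = list(members)
    beads = pop.beads
    if scope == "chromosome":
        if partner is None:
            raise ValueError("chromosome scope needs a partner chromosome")
        pmask = (beads["chrom"] == partner).to_numpy()
    elif scope == "genome":
        pmask = (beads["chrom"] != chrom).to_numpy()
    else:
        raise ValueError(f"unknown scope {scope!r}")
    pidx = np.flatnonzero(pmask)
    copies = _copy_indices(pop, chrom)
    tracks = []
    for c, idx in copies.items():
        acc = np.zeros(len(idx))
        for s in members:
            xyz = pop.coords[s]
            acc += (cdist(xyz[idx], xyz[pidx]) <= r_soft).sum(axis=1)
        tracks.append(acc / len(members))
    return np.mean(tracks, axis=0)


def ipp_ranking(
    pop: GenomePopulation,
    cluster_members,
    ensemble_members,
    chrom: str,
    r_soft: float = R_SOFT,
) -> list[tuple[str, float]]:
    """Partner chromosomes ranked by mean IppRatio with the target chromosome.

    For each partner, the per-bin log2 ratio of cluster IPP over ensemble IPP
    is averaged (bins with zero ensemble IPP excluded) and partners are
    returned sorted by decreasing mean ratio.
    """
    from .cluster_features import log2_ratio_track

    partners = [c for c in pop.chromosomes() if c != chrom]
    out = []
    for p in partners:
        clu = ipp_track(pop, cluster_members, chrom, scope="chromosome", partner=p, r_soft=r_soft)
        ens = ipp_track(pop, ensemble_members, chrom, scope="chromosome", partner=p, r_soft=r_soft)
        ratio = log2_ratio_track(clu, ens)
        out.append((p, float(np.nanmean(ratio)) if np.isfinite(ratio).any() else np.nan))
    out.sort(key=lambda t: (-t[1] if np.isfinite(t[1]) else np.inf))
    return out
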