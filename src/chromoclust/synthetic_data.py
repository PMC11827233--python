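"""Synthetic study conditions: planted morphologies, controls, speckle genomes.

The generators emulate the inputs the pipeline consumes without any external
download:

* reference conformations — confined random-walk backbones whose planted
  territory domains are collapsed around displaced centers, giving
  block-structured distance matrices with boundaries at chosen positions;
* positive controls — structures re-embedded from a reference distance matrix
  by classical multidimensional scaling plus isotropic Gaussian coordinate
  noise whose standard deviation is a chosen fraction (0.1-0.8) of the
  reference radius of gyration, with true labels retained;
* negative controls — confined self-avoiding homopolymers with no planted
  structure;
* diploid multi-chromosome genomes with A1 beads planted in tight blobs
  (ground-truth speckle centers recorded);
* sparse single-cell contact maps Bernoulli-sampled from cluster contact
  probabilities at a target sequencing depth.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .genome_model import (
    BIN_WIDTH_DEFAULT,
    ChromosomeStructure,
    GenomePopulation,
    NucleusGeometry,
    R_BEAD_DEFAULT,
)

SIGMAS_DEFAULT = (0.1, 0.4, 0.8)  # relative coordinate-noise levels


@dataclass
class SimulationConfig:
    n_clusters: int = 4
    n_beads: int = 50
    structures_per_cluster: int = 500
    sigmas: tuple[float, ...] = SIGMAS_DEFAULT
    geometry: NucleusGeometry = field(
        default_factory=lambda: NucleusGeometry(shape="sphere", r_nuc=5000.0)
    )
    boundaries: list | None = None  # per cluster, bin indices strictly inside
    r_bead: float = R_BEAD_DEFAULT
    bin_width: int = BIN_WIDTH_DEFAULT
    domain_collapse: float = 0.45  # contraction of beads toward domain centers
    # 1.0: clusters also differ in territory elongation/compaction (as real
    # morphology clusters do); 0.0: only the planted domain patterns differ
    morphology_variation: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(not (0 < s <= 1) for s in self.sigmas):
            raise ValueError("sigmas must lie in (0, 1]")
        if self.boundaries is None:
            # distinct planted patterns: cluster k gets k+1 boundaries spread
            # over the chromosome at cluster-specific positions
            self.boundaries = []
            for k in range(self.n_clusters):
                nb = (k % 3) + 1
                pos = [
                    int(round((j + 1) * self.n_beads / (nb + 1))) + 2 * (k % 2)
                    for j in range(nb)
                ]
                self.boundaries.append([p for p in pos if 0 < p < self.n_beads])
        for bl in self.boundaries:
            if any(not (0 < b < self.n_beads) for b in bl):
                raise ValueError("boundaries must be strictly inside the chromosome")


def _random_direction(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _confined_walk(rng, n: int, step: float, radius: float) -> np.ndarray:
    """Random walk of fixed step length confined to a sphere around the origin."""
    coords = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(200):
            cand = coords[i - 1] + step * _random_direction(rng)
            if np.linalg.norm(cand) <= radius:
                coords[i] = cand
                break
        else:
            coords[i] = coords[i - 1] * (radius / (np.linalg.norm(coords[i - 1]) + step))
    return coords


def make_reference_conformations(cfg: SimulationConfig) -> list[ChromosomeStructure]:
    """One reference conformation per cluster with planted territory domains.

    A confined random-walk backbone is split at the planted boundaries; each
    domain is contracted around its own displaced center, producing a
    block-structured distance matrix whose insulation maxima sit at the
    boundaries.  Different clusters use different boundary sets and different
    backbones.
    """
    refs = []
    terr_radius = 2.2 * cfg.r_bead * cfg.n_beads ** (1 / 3)
    for k in range(cfg.n_clusters):
        rng = np.random.default_rng((cfg.seed, 1, k))
        coords = _confined_walk(rng, cfg.n_beads, 2.0 * cfg.r_bead, terr_radius)
        cuts = [0] + sorted(cfg.boundaries[k]) + [cfg.n_beads]
        for d, (s, e) in enumerate(zip(cuts[:-1], cuts[1:])):
            center = terr_radius * 0.9 * _random_direction(rng)
            seg = coords[s:e]
            coords[s:e] = center + cfg.domain_collapse * (seg - seg.mean(axis=0))
        # morphologies differ qualitatively across clusters, as real territory
        # states do: territory elongation and overall compaction vary with k
        frac = cfg.morphology_variation * k / max(1, cfg.n_clusters - 1)
        coords = coords - coords.mean(axis=0)
        coords[:, k % 3] *= 1.0 + 0.9 * frac
        coords *= 0.7 * (1 + 6 / 7 * frac) if cfg.morphology_variation else 1.0
        refs.append(
            ChromosomeStructure(
                structure_id=f"ref{k}",
                chrom="chrS",
                copy=0,
                coords=coords,
                r_bead=cfg.r_bead,
            )
        )
    return refs


def classical_mds(d: np.ndarray, n_components: int = 3) -> np.ndarray:
    """Classical MDS (principal coordinates) of a distance matrix.

    Exact (up to rigid motion) for Euclidean distance matrices.
    """
    d = np.asarray(d, dtype=float)
    n = len(d)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:n_components]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)


def positive_control(
    cfg: SimulationConfig, references: list[ChromosomeStructure] | None = None
):
    """Labeled structures sampled around each reference conformation.

    Each structure is the classical-MDS embedding of the reference distance
    matrix plus isotropic Gaussian coordinate noise whose per-bead displacement
    magnitude has root-mean-square sigma * RG(reference) (per-axis standard
    deviation sigma * RG / sqrt(3)); sigma cycles deterministically through
    ``cfg.sigmas``.  Returns (structures, labels, sigmas_used).
    """
    if references is None:
        references = make_reference_conformations(cfg)
    structures, labels, sigmas_used = [], [], []
    for k, ref in enumerate(references):
        rng = np.random.default_rng((cfg.seed, 2, k))
        dm = squareform(pdist(ref.coords))
        base = classical_mds(dm)
        rg = ref.radius_of_gyration()
        for i in range(cfg.structures_per_cluster):
            sigma = cfg.sigmas[i % len(cfg.sigmas)]
            noise = rng.normal(0.0, sigma * rg / np.sqrt(3.0), size=base.shape)
            structures.append(
                ChromosomeStructure(
                    structure_id=f"c{k}_s{i}",
                    chrom="chrS",
                    copy=0,
                    coords=base + noise,
                    r_bead=cfg.r_bead,
                )
            )
            labels.append(k)
            sigmas_used.append(sigma)
    return structures, np.asarray(labels), np.asarray(sigmas_used)


def negative_control(
    cfg: SimulationConfig, n_structures: int | None = None, max_retries: int = 1_000_000
) -> list[ChromosomeStructure]:
    """Confined self-avoiding homopolymers: no planted structure at all.

    Beads overlap-reject below 2 R_bead and stay inside the nucleus; the walk
    restarts on dead ends, up to ``max_retries`` placements per structure.
    """
    if n_structures is None:
        n_structures = cfg.n_clusters * cfg.structures_per_cluster
    geom = cfg.geometry
    radius = geom.r_nuc if geom.shape == "sphere" else min(geom.semiaxes)
    step = 2.0 * cfg.r_bead
    out = []
    rng = np.random.default_rng((cfg.seed, 3))
    for s in range(n_structures):
        budget = max_retries
        while True:
            coords = np.zeros((cfg.n_beads, 3))
            start = (radius - step) * rng.uniform(0, 1) ** (1 / 3) * _random_direction(rng)
            coords[0] = start
            ok = True
            for i in range(1, cfg.n_beads):
                placed = False
                while budget > 0:
                    budget -= 1
                    cand = coords[i - 1] + step * _random_direction(rng)
                    if geom.radial_position(cand) > 1.0:
                        continue
                    if i > 1 and (np.linalg.norm(coords[: i - 1] - cand, axis=1) < step).any():
                        continue
                    coords[i] = cand
                    placed = True
                    break
                if not placed:
                    ok = False
                    break
            if ok:
                out.append(
                    ChromosomeStructure(
                        structure_id=f"n{s}", chrom="chrS", copy=0,
                        coords=coords, r_bead=cfg.r_bead,
                    )
                )
                break
            if budget <= 0:
                raise RuntimeError(
                    "self-avoiding walk failed; try a larger nucleus or fewer beads"
                )
    return out


def synthetic_genome_with_speckles(
    n_structures: int = 20,
    n_chromosomes: int = 2,
    beads_per_chromosome: int = 30,
    n_blobs: int = 3,
    beads_per_blob: int = 5,
    geometry: NucleusGeometry | None = None,
    r_bead: float = R_BEAD_DEFAULT,
    bin_width: int = BIN_WIDTH_DEFAULT,
    seed: int = 0,
):
    """Diploid genome population with A1 beads planted in tight blobs.

    Every structure places ``n_blobs`` blob centers well apart inside the
    nucleus and pulls its A1 beads onto them (within half a bead radius), so
    speckle prediction should recover one speckle per blob at the blob center.
    Returns (population, true_centers) with true_centers a list of (n_blobs,
    3) arrays.
    """
    geometry = geometry or NucleusGeometry(shape="sphere", r_nuc=5000.0)
    rng = np.random.default_rng((seed, 4))
    radius = geometry.r_nuc if geometry.shape == "sphere" else min(geometry.semiaxes)
    rows = []
    for c in range(n_chromosomes):
        for copy in (0, 1):
            for b in range(beads_per_chromosome):
                rows.append((f"chr{c + 1}", copy, b * bin_width, (b + 1) * bin_width))
    beads = pd.DataFrame(rows, columns=["chrom", "copy", "bin_start", "bin_end"])
    beads["category"] = "domain"
    beads["subcompartment"] = "NA"
    # A1 assignment: the first beads_per_blob beads of successive chromosome
    # copies, spread over n_blobs groups
    n_beads = len(beads)
    a1_groups = []
    per_copy = beads_per_chromosome
    for g in range(n_blobs):
        offset = (g * per_copy) % n_beads
        grp = [(offset + i) % n_beads for i in range(beads_per_blob)]
        a1_groups.append(np.asarray(grp))
        beads.loc[grp, "subcompartment"] = "A1"

    coords = np.empty((n_structures, n_beads, 3))
    truth = []
    for s in range(n_structures):
        # scatter all beads as loose confined walks per chromosome copy
        xyz = np.empty((n_beads, 3))
        for (chrom, copy), grp in beads.groupby(["chrom", "copy"], sort=False):
            idx = grp.index.to_numpy()
            center = 0.5 * radius * _random_direction(rng)
            xyz[idx] = center + _confined_walk(rng, len(idx), 2 * r_bead, 0.4 * radius)
        # blob centers mutually far apart
        centers = []
        while len(centers) < n_blobs:
            cand = 0.6 * radius * _random_direction(rng) * rng.uniform(0.4, 1.0)
            if all(np.linalg.norm(cand - c) > 10 * r_bead for c in centers):
                centers.append(cand)
        centers = np.asarray(centers)
        for g, grp in enumerate(a1_groups):
            jitter = rng.normal(0, 0.25 * r_bead, size=(len(grp), 3))
            xyz[grp] = centers[g] + jitter
        coords[s] = xyz
        truth.append(centers)
    pop = GenomePopulation(
        coords=coords, beads=beads, geometry=geometry,
        structure_ids=[f"g{s}" for s in range(n_structures)], r_bead=r_bead,
    )
    return pop, truth


def sample_scihic_cells(
    contact_probabilities: np.ndarray,
    n_cells: int,
    depth: float = 3879.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Bernoulli-sample sparse symmetric single-cell contact matrices.

    Upper-triangle contact probabilities are thinned so the expected total
    number of sampled contacts per cell is ``depth`` (the mean per-cell
    coverage of combinatorially indexed single-cell Hi-C); the result is a
    list of symmetric 0/1 count matrices.
    """
    p = np.asarray(contact_probabilities, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("contact probabilities must lie in [0, 1]")
    n = len(p)
    iu = np.triu_indices(n, k=1)
    pu = p[iu]
    total = pu.sum()
    if total == 0:
        raise ValueError("no contact probability mass to sample from")
    scale = depth / total
    if scale > 1 and (pu * scale).max() > 1:
        warnings.warn("requested depth exceeds available pairs; probabilities capped",
                      stacklevel=2)
    q = np.clip(pu * scale, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    cells = []
    for _ in range(n_cells):
        draws = rng.random(len(q)) < q
        m = np.zeros((n, n))
        m[iu] = draws
        m = m + m.T
        cells.append(m)
    return cells


def write_manifest(path, cfg: SimulationConfig, extra: dict | None = None) -> None:
    """Record the generating conditions (config + seed) next to the outputs."""
    payload = {
        "n_clusters": cfg.n_clusters,
        "n_beads": cfg.n_beads,
        "structures_per_cluster": cfg.structures_per_cluster,
        "sigmas": list(cfg.sigmas),
        "noise_units": "per-axis sd as a fraction of the reference radius of gyration",
        "boundaries": [list(map(int, b)) for b in cfg.boundaries],
        "geometry": cfg.geometry.shape,
        "r_bead": cfg.r_bead,
        "bin_width": cfg.bin_width,
        "seed": cfg.seed,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as f:
        json.dump(payload, f, indent=2)
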