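"""Domain types and I/O for diploid 3D genome structure populations.

Structures come from population-based genome modelling: each cell is a set of
chromosome chains of spherical beads (one bead per fixed-width genomic bin,
typically 200 kb, bead radius 118 nm) confined to a spherical or ellipsoidal
nucleus.  This module holds the containers for those populations, for bin
annotations (bead category, Hi-C subcompartment), and for chromatin-tracing
datasets, together with the plain-text readers/writers the pipeline touches:

* coordinate tables (TSV: structure_id, chrom, copy, bin_start, x, y, z in nm)
  and an equivalent HDF5 layout for large populations,
* BED bin annotations and bedGraph per-bin tracks (0-based half-open),
* dense matrices as (optionally gzipped) TSV or HDF5 groups ``matrices/<name>``.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

R_BEAD_DEFAULT = 118.0  # nm, 200-kb bead radius
BIN_WIDTH_DEFAULT = 200_000  # bp


class ConsistencyError(ValueError):
    """A population violates a structural invariant (bead counts, containment)."""


@dataclass(frozen=True)
class NucleusGeometry:
    """Nuclear envelope: a sphere (``r_nuc``) or an ellipsoid (``semiaxes``)."""

    shape: str
    r_nuc: float | None = None
    semiaxes: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.shape == "sphere":
            if self.r_nuc is None or self.r_nuc <= 0 or self.semiaxes is not None:
                raise ValueError("sphere geometry requires r_nuc > 0 and no semiaxes")
        elif self.shape == "ellipsoid":
            if self.semiaxes is None or any(a <= 0 for a in self.semiaxes) or self.r_nuc is not None:
                raise ValueError("ellipsoid geometry requires positive semiaxes and no r_nuc")
        else:
            raise ValueError(f"unknown nucleus shape {self.shape!r}")

    def radial_position(self, coords: np.ndarray) -> np.ndarray:
        """Normalized radial position of points: 0 at the centre, 1 at the envelope.

        For an ellipsoid the scaled elliptic radius sqrt((x/a)^2+(y/b)^2+(z/c)^2)
        is used so the envelope is again the unit level set.
        """
        coords = np.asarray(coords, dtype=float)
        if self.shape == "sphere":
            return np.linalg.norm(coords, axis=-1) / self.r_nuc
        a, b, c = self.semiaxes
        return np.sqrt(
            (coords[..., 0] / a) ** 2 + (coords[..., 1] / b) ** 2 + (coords[..., 2] / c) ** 2
        )


@dataclass
class BinAnnotation:
    """Fixed-width bin annotation for one or more chromosomes.

    ``bins`` columns: chrom, start, end, category ("domain"/"cen"),
    subcompartment (A1/A2/B1/B2/B3/NA).  Bins per chromosome must be
    contiguous, sorted and non-overlapping.
    """

    bins: pd.DataFrame
    bin_width: int = BIN_WIDTH_DEFAULT

    def __post_init__(self):
        required = {"chrom", "start", "end", "category"}
        if not required.issubset(self.bins.columns):
            raise ValueError(f"annotation must have columns {sorted(required)}")
        if "subcompartment" not in self.bins.columns:
            self.bins = self.bins.assign(subcompartment="NA")
        for chrom, grp in self.bins.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if not np.all(np.diff(starts) > 0):
                raise ValueError(f"bins of {chrom} are not sorted/strictly increasing")
            if not np.all(starts[1:] == ends[:-1]):
                raise ValueError(f"bins of {chrom} are not contiguous")
            widths = ends - starts
            if len(widths) > 1 and not np.all(widths[:-1] == self.bin_width):
                raise ValueError(f"bins of {chrom} do not have width {self.bin_width}")

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        sel = self.bins[self.bins["chrom"] == chrom]
        if sel.empty:
            raise KeyError(f"chromosome {chrom!r} not in annotation")
        return sel.reset_index(drop=True)

    def n_bins(self, chrom: str) -> int:
        return len(self.for_chrom(chrom))


@dataclass
class ChromosomeStructure:
    """Ordered bead coordinates (nm) of one chromosome copy of one cell."""

    structure_id: str
    chrom: str
    copy: int
    coords: np.ndarray  # (n_beads, 3), nm
    r_bead: float = R_BEAD_DEFAULT
    bin_index: np.ndarray | None = None  # annotation row per bead, for back-mapping

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.r_bead <= 0:
            raise ValueError("r_bead must be positive")
        if self.bin_index is None:
            self.bin_index = np.arange(len(self.coords))
        else:
            self.bin_index = np.asarray(self.bin_index, dtype=int)

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    def radius_of_gyration(self) -> float:
        d = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((d**2).sum(axis=1).mean()))


@dataclass
class GenomePopulation:
    """A population of diploid whole-genome structures on a shared bead table.

    ``coords`` has shape (n_structures, n_beads, 3); ``beads`` is a DataFrame
    with one row per bead (chrom, copy, bin_start, bin_end, category,
    subcompartment) shared by every structure.
    """

    coords: np.ndarray
    beads: pd.DataFrame
    geometry: NucleusGeometry | None = None
    structure_ids: list[str] = field(default_factory=list)
    r_bead: float = R_BEAD_DEFAULT

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_structures, n_beads, 3)")
        if self.coords.shape[1] != len(self.beads):
            raise ConsistencyError(
                f"bead table has {len(self.beads)} rows but coords have "
                f"{self.coords.shape[1]} beads"
            )
        if not self.structure_ids:
            self.structure_ids = [f"s{i}" for i in range(len(self.coords))]
        if len(self.structure_ids) != len(self.coords):
            raise ConsistencyError("structure_ids length mismatch")
        if self.geometry is not None and len(self.coords):
            r = self.geometry.radial_position(self.coords.reshape(-1, 3))
            # tolerance of one bead radius beyond the envelope (models may graze it)
            scale = self.geometry.r_nuc if self.geometry.shape == "sphere" else min(self.geometry.semiaxes)
            if np.any(r > 1.0 + self.r_bead / scale):
                warnings.warn(
                    "some beads lie more than one bead radius outside the nucleus",
                    stacklevel=2,
                )

    @property
    def n_structures(self) -> int:
        return len(self.coords)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.beads["chrom"]))


@dataclass
class TracingDataset:
    """Chromatin-tracing (DNA-MERFISH style) per-copy locus coordinates.

    ``table`` columns: copy_id, genomic_pos (bp), x, y, z (nm) and optionally
    speckle_dist (nm) and trans_on (counts).  Missing coordinates are NaN
    before interpolation and absent afterwards.
    """

    table: pd.DataFrame

    def copies(self) -> list:
        return list(dict.fromkeys(self.table["copy_id"]))

    def copy_coords(self, copy_id) -> pd.DataFrame:
        sel = self.table[self.table["copy_id"] == copy_id]
        return sel.sort_values("genomic_pos").reset_index(drop=True)


# ---------------------------------------------------------------------------
# population I/O
# ---------------------------------------------------------------------------

_COORD_COLUMNS = ["structure_id", "chrom", "copy", "bin_start", "x", "y", "z"]


def write_population(pop: GenomePopulation, path) -> None:
    """Write a population as a coordinate TSV (one row per bead per structure)."""
    path = Path(path)
    rows = []
    beads = pop.beads
    for sid, xyz in zip(pop.structure_ids, pop.coords):
        df = pd.DataFrame(
            {
                "structure_id": sid,
                "chrom": beads["chrom"].to_numpy(),
                "copy": beads["copy"].to_numpy(),
                "bin_start": beads["bin_start"].to_numpy(),
                "x": xyz[:, 0],
                "y": xyz[:, 1],
                "z": xyz[:, 2],
            }
        )
        rows.append(df)
    pd.concat(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_population(
    path,
    format: str = "coord-table",
    beads: pd.DataFrame | None = None,
    geometry: NucleusGeometry | None = None,
    r_bead: float = R_BEAD_DEFAULT,
) -> GenomePopulation:
    """Read a population from a coordinate TSV or the HDF5 layout.

    The bead ordering is taken from the companion bead table when given,
    otherwise from the first structure in the file.  Raises a parse error
    naming the offending line for malformed rows and a :class:`ConsistencyError`
    when structures disagree on bead count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "hdf5-population":
        return _read_population_hdf5(path, geometry=geometry, r_bead=r_bead)
    if format != "coord-table":
        raise ValueError(f"unknown population format {format!r}")

    try:
        df = pd.read_csv(path, sep="\t", dtype={"structure_id": str, "chrom": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed coordinate table {path}: {exc}") from None
    missing = set(_COORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"coordinate table {path} lacks columns {sorted(missing)}")
    for col in ("x", "y", "z"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2  # +1 header, +1 one-based
            raise ValueError(f"non-numeric coordinate in {path} at line {line}")

    sids = list(dict.fromkeys(df["structure_id"]))
    groups = {sid: grp for sid, grp in df.groupby("structure_id", sort=False)}
    n0 = len(groups[sids[0]])
    coords = np.empty((len(sids), n0, 3), dtype=float)
    for k, sid in enumerate(sids):
        grp = groups[sid]
        if len(grp) != n0:
            raise ConsistencyError(
                f"structure {sid} has {len(grp)} beads, expected {n0}"
            )
        coords[k] = grp[["x", "y", "z"]].to_numpy()
    if beads is None:
        first = groups[sids[0]]
        beads = pd.DataFrame(
            {
                "chrom": first["chrom"].to_numpy(),
                "copy": first["copy"].to_numpy(),
                "bin_start": first["bin_start"].to_numpy(),
            }
        )
        width = _infer_bin_width(beads)
        beads["bin_end"] = beads["bin_start"] + width
        beads["category"] = "domain"
        beads["subcompartment"] = "NA"
        beads = beads.reset_index(drop=True)
    return GenomePopulation(
        coords=coords, beads=beads, geometry=geometry, structure_ids=sids, r_bead=r_bead
    )


def _infer_bin_width(beads: pd.DataFrame) -> int:
    starts = beads["bin_start"].to_numpy()
    diffs = np.diff(starts)
    diffs = diffs[diffs > 0]
    return int(diffs.min()) if len(diffs) else BIN_WIDTH_DEFAULT


def write_population_hdf5(pop: GenomePopulation, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=pop.coords)
        f.create_dataset(
            "structure_ids", data=np.array(pop.structure_ids, dtype="S")
        )
        g = f.create_group("beads")
        for col in pop.beads.columns:
            vals = pop.beads[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            g.create_dataset(col, data=vals)
        f.attrs["r_bead"] = pop.r_bead


def _read_population_hdf5(path, geometry=None, r_bead=R_BEAD_DEFAULT) -> GenomePopulation:
    with h5py.File(path, "r") as f:
        coords = f["coords"][...]
        sids = [s.decode() for s in f["structure_ids"][...]]
        cols = {}
        for col in f["beads"]:
            vals = f["beads"][col][...]
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            cols[col] = vals
        r_bead = float(f.attrs.get("r_bead", r_bead))
    return GenomePopulation(
        coords=coords,
        beads=pd.DataFrame(cols),
        geometry=geometry,
        structure_ids=sids,
        r_bead=r_bead,
    )


def extract_chromosome_copies(pop: GenomePopulation, chrom: str) -> list[ChromosomeStructure]:
    """Isolate single chromosome copies: one structure per diploid copy per cell.

    For an autosome this yields ``2 * pop.n_structures`` chromosome structures.
    """
    if chrom not in set(pop.beads["chrom"]):
        raise KeyError(f"chromosome {chrom!r} not in population")
    out = []
    for copy in sorted(set(pop.beads.loc[pop.beads["chrom"] == chrom, "copy"])):
        mask = ((pop.beads["chrom"] == chrom) & (pop.beads["copy"] == copy)).to_numpy()
        idx = np.flatnonzero(mask)
        for sid, xyz in zip(pop.structure_ids, pop.coords):
            out.append(
                ChromosomeStructure(
                    structure_id=sid,
                    chrom=chrom,
                    copy=int(copy),
                    coords=xyz[idx],
                    r_bead=pop.r_bead,
                    bin_index=np.arange(len(idx)),
                )
            )
    # order: copy-major was built above; reorder structure-major, copy inner
    ncopies = len(out) // pop.n_structures if pop.n_structures else 0
    if ncopies > 1:
        reordered = []
        for s in range(pop.n_structures):
            for c in range(ncopies):
                reordered.append(out[c * pop.n_structures + s])
        out = reordered
    return out


# ---------------------------------------------------------------------------
# tracing I/O
# ---------------------------------------------------------------------------


def read_tracing(path, interpolate: bool = True, require_speckle: bool = False) -> TracingDataset:
    """Read a chromatin-tracing table, optionally filling internal gaps.

    Missing coordinates (NaN) interior to a copy are filled by per-axis linear
    interpolation on genomic position; copies with no valid coordinates (or no
    valid speckle distance when ``require_speckle``) are dropped, as are copies
    with fewer than two valid loci when interpolating.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"copy_id", "genomic_pos", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"tracing table lacks columns {sorted(required - set(df.columns))}")
    kept = []
    for copy_id, grp in df.groupby("copy_id", sort=False):
        grp = grp.sort_values("genomic_pos").reset_index(drop=True)
        pos = grp["genomic_pos"].to_numpy(dtype=float)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"copy {copy_id}: genomic positions not strictly increasing")
        valid = np.isfinite(grp[["x", "y", "z"]].to_numpy()).all(axis=1)
        if require_speckle:
            if "speckle_dist" not in grp.columns or not np.isfinite(
                grp["speckle_dist"].to_numpy(dtype=float)
            ).any():
                continue
        if not valid.any():
            continue
        if interpolate:
            if valid.sum() < 2:
                warnings.warn(f"copy {copy_id} dropped: fewer than 2 valid loci", stacklevel=2)
                continue
            for ax in ("x", "y", "z"):
                v = grp[ax].to_numpy(dtype=float)
                good = np.isfinite(v)
                grp[ax] = np.interp(pos, pos[good], v[good])
            # only interior gaps are genuinely interpolated; flanks are clamped
            # by np.interp, matching removal-by-fill of missing values
        else:
            grp = grp[valid]
        kept.append(grp)
    if not kept:
        return TracingDataset(table=df.iloc[0:0])
    return TracingDataset(table=pd.concat(kept, ignore_index=True))


def write_tracing(ds: TracingDataset, path) -> None:
    ds.table.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# annotation / track / matrix I/O
# ---------------------------------------------------------------------------


def read_annotation_bed(path, bin_width: int = BIN_WIDTH_DEFAULT) -> BinAnnotation:
    """Read bin categories (and optional subcompartments) from a BED-like file."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "category", "subcompartment"],
        dtype={"chrom": str},
    )
    if df["subcompartment"].isna().all():
        df = df.drop(columns=["subcompartment"])
    return BinAnnotation(bins=df, bin_width=bin_width)


def write_annotation_bed(ann: BinAnnotation, path) -> None:
    ann.bins[["chrom", "start", "end", "category", "subcompartment"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_profile_bedgraph(track, chrom: str, path, bin_width: int = BIN_WIDTH_DEFAULT,
                           start: int = 0) -> None:
    """Write a per-bin track as bedGraph (0-based half-open intervals).

    NaN bins are skipped; an empty track yields a header-only file.
    """
    track = np.asarray(track, dtype=float)
    path = Path(path)
    with open(path, "w") as f:
        f.write(f'track type=bedGraph name="{path.stem}"\n')
        for i, v in enumerate(track):
            if np.isnan(v):
                continue
            s = start + i * bin_width
            f.write(f"{chrom}\t{s}\t{s + bin_width}\t{v:.9g}\n")


def read_profile_bedgraph(path, n_bins: int | None = None,
                          bin_width: int = BIN_WIDTH_DEFAULT) -> np.ndarray:
    """Inverse of :func:`write_profile_bedgraph`; absent bins come back as NaN."""
    rows = []
    with open(path) as f:
        for line in f:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, s, e, v = line.rstrip("\n").split("\t")
            rows.append((int(s), float(v)))
    if n_bins is None:
        n_bins = 0 if not rows else rows[-1][0] // bin_width + 1
    track = np.full(n_bins, np.nan)
    for s, v in rows:
        track[s // bin_width] = v
    return track


def write_matrix(m: np.ndarray, path, name: str = "matrix") -> None:
    """Write a dense matrix: .h5/.hdf5 go to group ``matrices/<name>``,
    anything else becomes (gzipped when .gz) TSV."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "a") as f:
            g = f.require_group("matrices")
            if name in g:
                del g[name]
            g.create_dataset(name, data=np.asarray(m))
        return
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as f:
        np.savetxt(f, np.asarray(m), delimiter="\t", fmt="%.9g")


def read_matrix(path, name: str = "matrix") -> np.ndarray:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return f["matrices"][name][...]
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as f:
        return np.loadtxt(f, delimiter="\t", ndmin=2)


def read_scihic_coo(path, n_bins: int) -> np.ndarray:
    """Read a sparse single-cell contact matrix from COO TSV (bin_i, bin_j, count)."""
    m = np.zeros((n_bins, n_bins), dtype=float)
    df = pd.read_csv(path, sep="\t", header=None, names=["i", "j", "count"], comment="#")
    for i, j, c in df.itertuples(index=False):
        m[int(i), int(j)] += c
        if i != j:
            m[int(j), int(i)] += c
    return m


def write_scihic_coo(m: np.ndarray, path) -> None:
    m = np.asarray(m)
    iu, ju = np.triu_indices(len(m))
    with open(path, "w") as f:
        for i, j in zip(iu, ju):
            if m[i, j]:
                f.write(f"{i}\t{j}\t{m[i, j]:g}\n")
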