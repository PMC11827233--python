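import numpy as np
import pandas as pd
import pytest

from chromoclust.genome_model import (
    BinAnnotation,
    ChromosomeStructure,
    GenomePopulation,
    NucleusGeometry,
)

BIN = 200_000


def make_annotation(n_bins: int, chrom: str = "chr1", cen=()) -> BinAnnotation:
    rows = []
    for i in range(n_bins):
        rows.append(
            {
                "chrom": chrom,
                "start": i * BIN,
                "end": (i + 1) * BIN,
                "category": "cen" if i in cen else "domain",
                "subcompartment": "NA",
            }
        )
    return BinAnnotation(bins=pd.DataFrame(rows))


def make_structure(coords, chrom="chr1", copy=0, sid="s0", r_bead=118.0):
    return ChromosomeStructure(
        structure_id=sid, chrom=chrom, copy=copy, coords=np.asarray(coords, float),
        r_bead=r_bead,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sphere_geometry():
    return NucleusGeometry(shape="sphere", r_nuc=5000.0)


@pytest.fixture
def small_population(rng, sphere_geometry):
    """Two diploid structures, one 10-bin chromosome, coordinates inside the nucleus."""
    rows = []
    for copy in (0, 1):
        for b in range(10):
            rows.append(("chr1", copy, b * BIN, (b + 1) * BIN, "domain", "NA"))
    beads = pd.DataFrame(
        rows, columns=["chrom", "copy", "bin_start", "bin_end", "category", "subcompartment"]
    )
    coords = rng.normal(0, 800, size=(2, 20, 3))
    return GenomePopulation(
        coords=coords, beads=beads, geometry=sphere_geometry,
        structure_ids=["cellA", "cellB"],
    )
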