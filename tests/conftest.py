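import numpy as np
import pytest

from chirpdyn import genome_io as gio
from chirpdyn import synthetic_data as synth


@pytest.fixture(scope="session")
def small_genome():
    """200 genes on two 1.2-Mb chromosomes (deterministic)."""
    return synth.make_genome(n_genes=200, chrom_len=1_200_000, seed=3)


@pytest.fixture(scope="session")
def rnapii_sim(small_genome):
    genes, chrom_sizes = small_genome
    tracks, truth = synth.simulate_rnapii(genes, chrom_sizes, seed=3)
    rpm = {k: gio.to_rpm(v) for k, v in tracks.items()}
    return genes, chrom_sizes, tracks, rpm, truth


@pytest.fixture(scope="session")
def chirp_sim():
    """Full-scale even/odd/input triple: 200 concordant + 200 decoys."""
    chrom_sizes = {"chr1": 600_000, "chr2": 600_000}
    tracks, truth = synth.simulate_chirp(chrom_sizes, seed=7)
    return chrom_sizes, tracks, truth


def uniform_track(chrom_sizes, value, library_size=1e6, norm="rpm"):
    data = {c: np.full(n, float(value)) for c, n in chrom_sizes.items()}
    return gio.CoverageTrack(data, dict(chrom_sizes), library_size, 1, norm)
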