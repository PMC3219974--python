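import numpy as np
import pytest

from cnvhotspots.core import CnvInterval, GenomeModel


@pytest.fixture(scope="session")
def small_genome() -> GenomeModel:
    """A 15 Mb three-chromosome genome with a few assembly gaps."""
    return GenomeModel(
        chromosomes=[("chr1", 6_000_000), ("chr2", 5_000_000), ("chr3", 4_000_000)],
        gaps={"chr1": [(1_000_000, 1_200_000), (3_000_000, 3_050_000)],
              "chr2": [(2_500_000, 2_600_000)]},
    )


def random_cnv_set(rng: np.random.Generator, n: int, species: str,
                   genome_length: int = 2_000_000,
                   size_range: tuple[int, int] = (500, 80_000),
                   chrom: str = "chr1") -> list[CnvInterval]:
    """Uniformly placed intervals with log-uniform sizes on one chromosome."""
    sizes = np.exp(rng.uniform(np.log(size_range[0]), np.log(size_range[1]), n)).astype(int)
    starts = rng.integers(0, genome_length - sizes)
    return [CnvInterval(id=f"{species}_{i}", chrom=chrom, start=int(s), end=int(s + sz),
                        species=species)
            for i, (s, sz) in enumerate(zip(starts, sizes))]
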