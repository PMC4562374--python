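import pytest

from ngsnap.fixtures import SyntheticSpec, generate_synthetic_dataset
from ngsnap.model import GenomicWindow


@pytest.fixture(scope="session")
def window():
    return GenomicWindow("chrS", 2001, 8000)


@pytest.fixture(scope="session")
def mixed_dataset(tmp_path_factory):
    """Single-end + paired + orphan + secondary reads, with annotation."""
    spec = SyntheticSpec(
        chrom_length=10_000,
        read_length=50,
        n_single=60,
        n_pairs=40,
        inner_size=120,
        n_orphans=7,
        n_secondary=5,
        n_feature_ids=6,
        seed=20240917,
    )
    return spec, generate_synthetic_dataset(
        spec, tmp_path_factory.mktemp("mixed")
    )


@pytest.fixture(scope="session")
def single_dataset(tmp_path_factory):
    """Pure single-end dataset."""
    spec = SyntheticSpec(
        chrom_length=5_000,
        read_length=40,
        n_single=50,
        seed=77,
    )
    return spec, generate_synthetic_dataset(
        spec, tmp_path_factory.mktemp("single")
    )
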