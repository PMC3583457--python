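import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rebscan.records import ProteinRecord
from rebscan.simulate import GeneratorConfig, SyntheticDataset, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(pid: str, sequence: str, taxon: str = "T1",
                replicon: str = "chr", index: int = 0,
                is_plasmid: bool = False) -> ProteinRecord:
    return ProteinRecord(
        protein_id=pid, taxon_id=taxon, replicon_id=replicon, index=index,
        start=1 + index * 1000, end=index * 1000 + 3 * len(sequence),
        strand="+", is_plasmid=is_plasmid, sequence=sequence,
    )


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """4 Reb + 4 non-Reb taxa, compact genomes — fast but fully structured."""
    return GeneratorConfig(
        seed=11, n_reb_taxa=4, n_nonreb_taxa=4, divergence=0.2,
        background_genes_per_replicon=12, decoy_family_count=6,
        n_distal_reb_taxa=1,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> SyntheticDataset:
    return generate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
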