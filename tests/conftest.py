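import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

import lineagediv as ld


@pytest.fixture(scope="session")
def toy_codon_alignment():
    """Four gap-free sequences, ten codons, hand-checkable."""
    rows = [
        ("s1", "ATGGCTAAAGGGTTTCCCGATGAACTTTGG"),
        ("s2", "ATGGCTAAAGGGTTTCCCGATGAACTTTGG"),
        ("s3", "ATGGCAAAAGGGTTCCCCGATGAACTTTGG"),
        ("s4", "ATGGCAAAAGGATTCCCCGACGAACTTTGG"),
    ]
    return ld.CodonAlignment(rows)


@pytest.fixture(scope="session")
def simulated_dataset():
    """One seeded default-condition simulation shared across tests."""
    config = ld.SimulationConfig(seed=2024)
    codon_aln, protein_aln, partition, truth = ld.simulate(config)
    return codon_aln, protein_aln, partition, truth


@pytest.fixture()
def fasta_file(tmp_path):
    def _write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
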