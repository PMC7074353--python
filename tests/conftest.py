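from importlib import resources
from pathlib import Path

import pytest

from mitoprofile.io import read_gene_table
from mitoprofile.simulate import GenomeSpec, generate_genome

GENOME_LENGTH = 16646


@pytest.fixture(scope="session")
def paper_table_path(tmp_path_factory):
    """Path to the packaged reference gene-coordinate table."""
    ref = resources.files("mitoprofile.data") / "amara_aulica_gene_table.tsv"
    with resources.as_file(ref) as path:
        yield Path(path)


@pytest.fixture(scope="session")
def paper_table(paper_table_path):
    return read_gene_table(paper_table_path, genome_length=GENOME_LENGTH, circular=True)


@pytest.fixture(scope="session")
def synthetic_genome():
    """Default synthetic genome (record, table), fixed seed."""
    return generate_genome(GenomeSpec(seed=0))
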