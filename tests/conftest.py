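import textwrap

import pytest
from hypothesis import HealthCheck, settings

from seedmark import DigestParams, ProteinRecord

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=list(HealthCheck)
)
settings.load_profile("ci")


@pytest.fixture
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(
        textwrap.dedent(
            """\
            >P00001 toy conlinin-like protein
            MKWVQQAKRDLPGQCGTQPSRAAAK
            >P00002 toy globulin
            MLTALEPTNRKGGGGGK
            """
        )
    )
    return path


@pytest.fixture
def defaults():
    return DigestParams()


def make_record(sequence, accession="P99999", species="testspecies"):
    return ProteinRecord(
        accession=accession,
        description=f"{accession} synthetic test protein",
        species_tag=species,
        sequence=sequence,
    )


@pytest.fixture
def record_factory():
    return make_record
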