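import numpy as np
import pytest

from barcodegeo.alignment_io import AlignedSequenceSet, SpecimenRecord
from barcodegeo.synthetic_data import paper_shaped_fixture


@pytest.fixture(scope="session")
def survey_fixture():
    """Deterministic dataset shaped like the published survey (97 specimens,
    47 haplotypes, real coordinates/bioregions, synthetic sequences)."""
    return paper_shaped_fixture()


@pytest.fixture
def toy_alignment():
    return AlignedSequenceSet.from_records(
        [
            ("s1", "ACGTACGTAC"),
            ("s2", "ACGTACGTAC"),
            ("s3", "ACGTACTTAC"),
            ("s4", "ACGTACGTAT"),
        ]
    )


@pytest.fixture
def toy_metadata():
    return [
        SpecimenRecord("s1", "Toy sp.", 50.0, 7.0, "A"),
        SpecimenRecord("s2", "Toy sp.", 50.1, 7.1, "A"),
        SpecimenRecord("s3", "Toy sp.", 51.0, 8.0, "B"),
        SpecimenRecord("s4", "Toy sp.", 52.0, 9.0, "B"),
    ]


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
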