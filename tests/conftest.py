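import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from exomesieve.fixtures import FixtureSpec, generate_fixture
from exomesieve.genome import Transcript


@pytest.fixture(scope="session")
def toy_transcript() -> Transcript:
    """Two-exon plus-strand transcript used for hand-checkable coordinates:
    exons [100,200) and [300,400), CDS [150,350)."""
    return Transcript(
        transcript_id="TOY1",
        gene_name="TOYGENE",
        contig="chr1",
        strand="+",
        tx_start=100,
        tx_end=400,
        cds_start=150,
        cds_end=350,
        exons=((100, 200), (300, 400)),
    )


SMALL_SNV_COUNTS = {
    "missense": 6, "syn_code": 5, "nonsense": 3, "read_through": 2,
    "splice_site": 3, "intron": 6, "utr5": 3, "utr3": 3, "intergenic": 3,
}
SMALL_INDEL_COUNTS = {
    "frame_shift": 3, "aa_insertion": 2, "aa_deletion": 2, "non_coding": 3,
}


@pytest.fixture(scope="session")
def single_fixture():
    """One-sample study at reduced scale, with panel and catalogue."""
    return generate_fixture(
        FixtureSpec(
            seed=11,
            snv_counts=dict(SMALL_SNV_COUNTS),
            indel_counts=dict(SMALL_INDEL_COUNTS),
        )
    )


@pytest.fixture(scope="session")
def cohort_fixture():
    """Three cases, two controls and a trio, with planted sharing."""
    return generate_fixture(
        FixtureSpec(
            seed=23,
            snv_counts=dict(SMALL_SNV_COUNTS),
            indel_counts=dict(SMALL_INDEL_COUNTS),
            n_cases=3,
            n_controls=2,
            n_shared_cases=6,
            n_shared_partial=4,
            n_shared_with_controls=3,
            trio=True,
        )
    )


@pytest.fixture(scope="session")
def cohort_paths(cohort_fixture, tmp_path_factory):
    return cohort_fixture.write(tmp_path_factory.mktemp("cohort"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
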