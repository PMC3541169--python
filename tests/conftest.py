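import numpy as np
import pytest

from pgtrait.annotation_io import Cohort, GenomeRecord, FAMILIES


def make_record(
    genome_id="G1",
    domain="Bacteria",
    phylum="Proteobacteria",
    counts=None,
    pg_status="present",
    **kwargs,
):
    family_counts = {f: 0 for f in FAMILIES}
    family_counts.update(counts or {})
    return GenomeRecord(
        genome_id=genome_id,
        domain=domain,
        phylum=phylum,
        family_counts=family_counts,
        pg_status=pg_status,
        **kwargs,
    )


@pytest.fixture
def toy_cohort():
    """Three genomes: one with the full set, one GT51-less, one unknown."""
    return Cohort(
        [
            make_record(
                "micromonas_like",
                domain="Eukaryota",
                phylum="Chlorophyta",
                counts={"GT28": 1, "GT51": 1, "GH103": 1},
                pg_status="present",
            ),
            make_record(
                "chlamydia_like",
                counts={"GT28": 27},
                phylum="Chlamydia",
                pg_status="absent",
            ),
            make_record(
                "unknown_like",
                counts={"GT28": 1, "GT51": 1},
                pg_status="unknown",
            ),
        ]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120918)
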