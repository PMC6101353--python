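import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from pepmap.annotation import AnnotationSet, TranscriptModel, parse_gtf
from pepmap.fixtures import Fixture, FixtureSpec, generate
from pepmap.peptide_io import read_pogo_table
from pepmap.sequence_db import ProteinDatabase, ProteinEntry, build_index


@pytest.fixture
def plus_transcript() -> TranscriptModel:
    """Two-exon plus-strand transcript: CDS (1000,1009)+(2000,2021), 30 nt."""
    return TranscriptModel(
        transcript_id="T1",
        gene_id="G1",
        chrom="chr1",
        strand="+",
        cds_segments=((1000, 1009), (2000, 2021)),
    )


@pytest.fixture
def minus_transcript() -> TranscriptModel:
    """Two-exon minus-strand transcript: translation order (3000,3009),(2000,2021)."""
    return TranscriptModel(
        transcript_id="T2",
        gene_id="G2",
        chrom="chr1",
        strand="-",
        cds_segments=((3000, 3009), (2000, 2021)),
    )


@pytest.fixture
def small_annotation(plus_transcript, minus_transcript) -> AnnotationSet:
    annotation = AnnotationSet()
    annotation.add(plus_transcript)
    annotation.add(minus_transcript)
    return annotation


@pytest.fixture
def small_database() -> ProteinDatabase:
    db = ProteinDatabase()
    db.add(ProteinEntry("P1", "MACDEFGHIKR"))
    return db


@pytest.fixture
def small_index(small_database):
    return build_index(small_database, kmer_len=4)


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory) -> Fixture:
    """A medium synthetic dataset shared across test modules."""
    out = tmp_path_factory.mktemp("fixture_ds")
    spec = FixtureSpec(
        seed=11,
        n_genes=12,
        n_peptides=80,
        fraction_junction_spanning=0.25,
        fraction_variant=0.1,
        fraction_modified=0.15,
    )
    return generate(spec, out)


@pytest.fixture(scope="session")
def fixture_reference(fixture_dataset):
    """(annotation, database, index, records) parsed from the shared dataset."""
    from pepmap.sequence_db import load_fasta

    annotation = parse_gtf(fixture_dataset.gtf)
    database = load_fasta(fixture_dataset.protein_fasta)
    index = build_index(database)
    records = read_pogo_table(fixture_dataset.peptide_table)
    return annotation, database, index, records
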