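"""Peptide-to-genome mapping engine.

Orchestrates the search (protein hits with bounded mismatches), the spliced
coordinate transform (protein residues -> genomic blocks via the hit's
transcript), the collapse of per-transcript hits into genomic loci, and the
3-tier uniqueness classification:

* ``unique_transcript`` (red): the peptide's mappings involve exactly one
  transcript of one gene;
* ``unique_gene`` (black): one gene but several transcripts;
* ``multi_gene`` (grey): the peptide maps to more than one gene — less
  reliable for quantifying or calling expression of any single gene.

Uniqueness is a property of a peptide's *complete* mapping set, so every
mapping of a multi-gene peptide is grey.  Two mappings with identical blocks
on opposite strands are distinct genomic events and are never collapsed.

Staged mapping implements the recommended variant workflow: map exactly
first, remove mapped peptides from the input, then remap the remainder with
one (optionally two) allowed mismatches.  This bounds the combinatorial
growth of candidate mappings at higher mismatch allowances.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annotation import AnnotationSet, TranscriptModel, residue_range_to_coding, coding_to_genomic
from .errors import ConfigurationError
from .peptide_io import PeptideRecord, subtract_mapped
from .sequence_db import PeptideIndex, ProteinDatabase, find_peptide

log = logging.getLogger(__name__)

__all__ = [
    "Uniqueness",
    "GenomicMapping",
    "MappingRun",
    "map_all",
    "classify_uniqueness",
    "staged_mapping",
]


class Uniqueness(enum.Enum):
    UNIQUE_TRANSCRIPT = "unique_transcript"
    UNIQUE_GENE = "unique_gene"
    MULTI_GENE = "multi_gene"


@dataclass
class GenomicMapping:
    """One genomic locus of one peptide.

    ``blocks`` are ascending, non-overlapping 0-based half-open intervals;
    the first starts at ``start`` and the last ends at ``end``.  ``records``
    holds every input record sharing this peptide's plain sequence (one per
    sample after aggregation), so sample-level PSMs and quantitation stay
    available to the writers.
    """

    peptide: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    transcript_ids: frozenset[str]
    gene_ids: frozenset[str]
    uniqueness: Uniqueness
    n_mismatches: int = 0
    mismatch_positions: tuple[int, ...] = ()
    records: tuple[PeptideRecord, ...] = ()

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def total_psms(self) -> int:
        return sum(r.psms for r in self.records)

    def locus(self) -> tuple[str, str, tuple[tuple[int, int], ...]]:
        return (self.chrom, self.strand, self.blocks)


@dataclass
class MappingRun:
    """Result of mapping a set of peptide records at one mismatch allowance."""

    max_mismatches: int
    mappings: list[GenomicMapping] = field(default_factory=list)
    unmapped: list[PeptideRecord] = field(default_factory=list)
    records: list[PeptideRecord] = field(default_factory=list)

    @property
    def by_peptide(self) -> dict[str, list[GenomicMapping]]:
        grouped: dict[str, list[GenomicMapping]] = {}
        for m in self.mappings:
            grouped.setdefault(m.peptide, []).append(m)
        return grouped

    @property
    def mapped_plain_sequences(self) -> set[str]:
        return {m.peptide for m in self.mappings}

    @property
    def samples(self) -> list[str]:
        """Sample labels in order of first appearance in the input."""
        seen: list[str] = []
        for rec in self.records:
            if rec.sample not in seen:
                seen.append(rec.sample)
        return seen


def classify_uniqueness(mappings: Sequence[GenomicMapping]) -> Uniqueness:
    """Tier for a peptide's complete mapping set (must be non-empty)."""
    if not mappings:
        raise ValueError("classify_uniqueness requires a non-empty mapping set")
    genes: set[str] = set()
    transcripts: set[str] = set()
    for m in mappings:
        genes |= m.gene_ids
        transcripts |= m.transcript_ids
    if len(genes) > 1:
        return Uniqueness.MULTI_GENE
    if len(transcripts) == 1:
        return Uniqueness.UNIQUE_TRANSCRIPT
    return Uniqueness.UNIQUE_GENE


def _resolve_transcript(
    annotation: AnnotationSet, protein_key: str
) -> TranscriptModel | None:
    return annotation.resolve(protein_key)


def map_all(
    records: Iterable[PeptideRecord],
    database: ProteinDatabase,
    index: PeptideIndex,
    annotation: AnnotationSet,
    max_mismatches: int = 0,
    il_equivalent: bool = False,
) -> MappingRun:
    """Map every record's peptide onto genomic coordinates.

    Records sharing a plain sequence are mapped once and share the resulting
    loci.  A peptide whose protein hits all lack a coding transcript in the
    annotation is counted unmapped (no coordinate basis exists).

    Raises
    ------
    ConfigurationError
        When not a single database key resolves to an annotation transcript —
        the FASTA and GTF are from different releases or the FASTA holds the
        wrong content.
    """
    records = list(records)
    n_resolvable = sum(
        1 for key in database if _resolve_transcript(annotation, key) is not None
    )
    if len(database) and len(annotation) and n_resolvable == 0:
        raise ConfigurationError(
            "no protein FASTA identifier matches any GTF transcript_id; "
            "check that the FASTA and GTF are matching releases of the same "
            "annotation"
        )

    by_plain: dict[str, list[PeptideRecord]] = {}
    for rec in records:
        by_plain.setdefault(rec.plain_sequence, []).append(rec)

    run = MappingRun(max_mismatches=max_mismatches, records=records)
    for plain, group in by_plain.items():
        hits = find_peptide(
            index, database, plain, max_mismatches, il_equivalent=il_equivalent
        )
        # collapse hits with identical (chrom, strand, blocks) into one locus
        loci: dict[tuple, dict] = {}
        for hit in hits:
            transcript = _resolve_transcript(annotation, hit.protein_key)
            if transcript is None:
                log.warning(
                    "peptide %s hits protein %s with no coding transcript in "
                    "the annotation; hit skipped",
                    plain,
                    hit.protein_key,
                )
                continue
            nt_interval = residue_range_to_coding(hit.aa_start, hit.aa_end)
            if nt_interval[1] > transcript.coding_length_nt:
                log.warning(
                    "peptide %s extends past the last full codon of %s; hit "
                    "skipped",
                    plain,
                    transcript.transcript_id,
                )
                continue
            blocks = tuple(coding_to_genomic(transcript, nt_interval))
            key = (transcript.chrom, transcript.strand, blocks)
            entry = loci.setdefault(
                key,
                {
                    "transcripts": set(),
                    "genes": set(),
                    "n_mismatches": hit.n_mismatches,
                    "mismatch_positions": hit.mismatch_positions,
                },
            )
            entry["transcripts"].add(transcript.transcript_id)
            entry["genes"].add(transcript.gene_id)

        if not loci:
            run.unmapped.extend(group)
            continue

        peptide_mappings = [
            GenomicMapping(
                peptide=plain,
                chrom=chrom,
                strand=strand,
                blocks=blocks,
                transcript_ids=frozenset(entry["transcripts"]),
                gene_ids=frozenset(entry["genes"]),
                uniqueness=Uniqueness.MULTI_GENE,  # placeholder, set below
                n_mismatches=entry["n_mismatches"],
                mismatch_positions=entry["mismatch_positions"],
                records=tuple(group),
            )
            for (chrom, strand, blocks), entry in loci.items()
        ]
        tier = classify_uniqueness(peptide_mappings)
        for m in peptide_mappings:
            m.uniqueness = tier
        run.mappings.extend(peptide_mappings)

    run.mappings.sort(key=lambda m: (m.chrom, m.start, m.end, m.peptide, m.strand))
    return run


def staged_mapping(
    records: Iterable[PeptideRecord],
    database: ProteinDatabase,
    index: PeptideIndex,
    annotation: AnnotationSet,
    stages: Sequence[int] = (0, 1),
    il_equivalent: bool = False,
) -> list[tuple[int, MappingRun]]:
    """Run the staged workflow: each stage maps only the peptides left
    unmapped by all previous stages, at that stage's mismatch allowance.

    ``stages`` must be strictly increasing with values <= 2.
    """
    stages = list(stages)
    if any(b <= a for a, b in zip(stages, stages[1:])):
        raise ValueError(f"stages must be strictly increasing, got {stages}")
    if any(s not in (0, 1, 2) for s in stages):
        raise ValueError(f"stage mismatch allowances must be in {{0,1,2}}, got {stages}")

    remaining = list(records)
    results: list[tuple[int, MappingRun]] = []
    for mm in stages:
        run = map_all(
            remaining, database, index, annotation, mm, il_equivalent=il_equivalent
        )
        results.append((mm, run))
        remaining = subtract_mapped(remaining, run.mapped_plain_sequences)
    return results
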