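"""Gene annotation (GTF) parsing and spliced coordinate arithmetic.

A protein-coding transcript is represented by its CDS segments only: the
ordered genomic intervals that, concatenated in translation order (ascending
on the plus strand, descending on the minus strand), spell the coding
sequence.  Peptide positions within a protein are pure codon arithmetic on
this concatenation; mapping them back to the genome is a walk over the
segments that splits blocks at every exon/exon junction crossed.

Coordinate conventions
----------------------
GTF is 1-based inclusive; everything internal (and all BED output downstream)
is 0-based half-open.  The conversion happens exactly once, at parse time.

The CDS ``frame`` field is ignored: the transcript translation sequences
provided alongside the annotation are the residue ground truth and residue 1
is assumed to start at coding phase 0.  Transcripts whose summed CDS length
is not a multiple of three are retained with a warning; residue ranges past
the last full codon are unmappable.  Per GENCODE convention the stop codon is
not part of the CDS, so protein length x 3 equals the coding length.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from .errors import AnnotationError, CoordinateError, GtfParseError

log = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "AnnotationSet",
    "parse_gtf",
    "residue_range_to_coding",
    "coding_to_genomic",
    "spliced_subinterval",
    "strip_version",
]

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')

Interval = tuple[int, int]


def strip_version(identifier: str) -> str:
    """Drop a trailing ``.N`` version suffix (``ENST0001.4`` -> ``ENST0001``)."""
    return re.sub(r"\.\d+$", "", identifier)


@dataclass(frozen=True)
class TranscriptModel:
    """A protein-coding transcript's CDS structure.

    ``cds_segments`` are 0-based half-open genomic intervals in *translation
    order*: ascending genomic position on the plus strand, descending on the
    minus strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    cds_segments: tuple[Interval, ...]
    gene_name: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be + or -, got {self.strand!r}"
            )
        if not self.cds_segments:
            raise AnnotationError(f"transcript {self.transcript_id}: no CDS segments")
        ascending = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(ascending, ascending[1:]):
            if e1 > s2:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping CDS segments "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        expected = tuple(ascending) if self.strand == "+" else tuple(ascending[::-1])
        if tuple(self.cds_segments) != expected:
            raise AnnotationError(
                f"transcript {self.transcript_id}: CDS segments not in translation order"
            )

    @property
    def coding_length_nt(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def protein_length(self) -> int:
        """Number of complete codons (== residues of the translation)."""
        return self.coding_length_nt // 3

    def residues_to_blocks(self, aa_start: int, aa_end: int) -> list[Interval]:
        """Genomic blocks covering residues ``aa_start..aa_end`` (1-based incl.)."""
        return coding_to_genomic(self, residue_range_to_coding(aa_start, aa_end))


@dataclass
class AnnotationSet:
    """All coding transcripts of one annotation, indexed by transcript and gene."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    gene_index: dict[str, set[str]] = field(default_factory=dict)

    def add(self, transcript: TranscriptModel) -> None:
        if transcript.transcript_id in self.transcripts:
            raise AnnotationError(f"duplicate transcript_id {transcript.transcript_id}")
        self.transcripts[transcript.transcript_id] = transcript
        self.gene_index.setdefault(transcript.gene_id, set()).add(transcript.transcript_id)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def resolve(self, identifier: str) -> TranscriptModel | None:
        """Look up a transcript id, tolerating version-suffix differences."""
        hit = self.transcripts.get(identifier)
        if hit is not None:
            return hit
        return self._stripped_index().get(strip_version(identifier))

    def _stripped_index(self) -> dict[str, TranscriptModel]:
        cached = getattr(self, "_stripped", None)
        if cached is None or len(cached) != len(self.transcripts):
            cached = {strip_version(tid): t for tid, t in self.transcripts.items()}
            object.__setattr__(self, "_stripped", cached)
        return cached


def _parse_attributes(attr_field: str) -> dict[str, str]:
    # GENCODE and Ensembl dialects both write `key "value";` pairs but differ in
    # spacing/trailing semicolons; repeated keys keep the first occurrence.
    out: dict[str, str] = {}
    for key, value in _ATTR_RE.findall(attr_field):
        out.setdefault(key, value)
    return out


def _iter_lines(source: Union[str, Path, IO[str], Iterable[str]]) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as handle:
            yield from handle
    else:
        yield from source


def parse_gtf(source: Union[str, Path, IO[str], Iterable[str]]) -> AnnotationSet:
    """Parse a GTF stream into an :class:`AnnotationSet`.

    Only transcripts with at least one ``CDS`` feature are retained — they are
    the only possible mapping targets.  Chromosome names pass through verbatim
    (no ``chr`` normalisation); the caller's GTF and browser assembly must
    match.

    Raises
    ------
    GtfParseError
        On a line with the wrong column count, or a CDS feature without a
        ``transcript_id``/``gene_id`` attribute; the message names the line.
    """
    pending: dict[str, dict] = {}
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
        if feature != "CDS":
            continue
        attributes = _parse_attributes(attrs)
        tid = attributes.get("transcript_id")
        if not tid:
            raise GtfParseError(f"line {lineno}: CDS feature without transcript_id")
        gid = attributes.get("gene_id")
        if not gid:
            raise GtfParseError(f"line {lineno}: CDS feature without gene_id")
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise GtfParseError(f"line {lineno}: non-numeric coordinates") from exc
        if strand not in ("+", "-"):
            raise GtfParseError(f"line {lineno}: strand must be + or -, got {strand!r}")
        entry = pending.setdefault(
            tid,
            {
                "gene_id": gid,
                "gene_name": attributes.get("gene_name"),
                "chrom": chrom,
                "strand": strand,
                "segments": [],
            },
        )
        if entry["chrom"] != chrom or entry["strand"] != strand:
            raise GtfParseError(
                f"line {lineno}: transcript {tid} has CDS on conflicting "
                f"chromosome/strand"
            )
        # GTF 1-based inclusive -> 0-based half-open, once, here.
        entry["segments"].append((start - 1, end))

    annotation = AnnotationSet()
    for tid, entry in pending.items():
        segments = sorted(entry["segments"])
        if entry["strand"] == "-":
            segments = segments[::-1]
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=entry["gene_id"],
            chrom=entry["chrom"],
            strand=entry["strand"],
            cds_segments=tuple(segments),
            gene_name=entry["gene_name"],
        )
        if model.coding_length_nt % 3 != 0:
            log.warning(
                "transcript %s: CDS length %d not divisible by 3; residues past "
                "the last full codon are unmappable",
                tid,
                model.coding_length_nt,
            )
        annotation.add(model)
    return annotation


def residue_range_to_coding(aa_start: int, aa_end: int) -> Interval:
    """Convert a 1-based inclusive residue range to a 0-based half-open
    nucleotide interval within the concatenated coding sequence."""
    if not 1 <= aa_start <= aa_end:
        raise CoordinateError(f"invalid residue range ({aa_start}, {aa_end})")
    return (aa_start - 1) * 3, aa_end * 3


def spliced_subinterval(
    segments: tuple[Interval, ...] | list[Interval],
    strand: str,
    nt_interval: Interval,
) -> list[Interval]:
    """Project a coding-space interval onto genomic blocks.

    ``segments`` must be in translation order.  The returned blocks are sorted
    ascending by genomic start (genome-browser convention) and split at every
    segment boundary crossed; their total length equals the interval length.
    """
    lo, hi = nt_interval
    blocks: list[Interval] = []
    walked = 0
    for gstart, gend in segments:
        seglen = gend - gstart
        a = max(lo, walked)
        b = min(hi, walked + seglen)
        if a < b:
            rel_a, rel_b = a - walked, b - walked
            if strand == "+":
                blocks.append((gstart + rel_a, gstart + rel_b))
            else:
                # translation walks this segment from its genomic end backwards
                blocks.append((gend - rel_b, gend - rel_a))
        walked += seglen
    blocks.sort()
    return blocks


def coding_to_genomic(transcript: TranscriptModel, nt_interval: Interval) -> list[Interval]:
    """Map a coding nucleotide interval of ``transcript`` to genomic blocks.

    Raises :class:`CoordinateError` naming the transcript when the interval
    exceeds the coding length.
    """
    lo, hi = nt_interval
    if lo < 0 or hi < lo or hi > transcript.coding_length_nt:
        raise CoordinateError(
            f"interval ({lo}, {hi}) out of range for transcript "
            f"{transcript.transcript_id} (coding length "
            f"{transcript.coding_length_nt} nt)"
        )
    return spliced_subinterval(transcript.cds_segments, transcript.strand, nt_interval)
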