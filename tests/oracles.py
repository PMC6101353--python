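"""Independent brute-force oracles used to verify the fast implementations.

These deliberately avoid the code paths they check: the coordinate oracle
builds an explicit per-nucleotide mapping table and derives blocks from it;
the search oracle scans every substring of every protein with a vectorised
Hamming comparison.
"""

from __future__ import annotations

import numpy as np

from pepmap.mapper import Uniqueness
from pepmap.sequence_db import AMBIGUOUS, ProteinDatabase


def per_nt_positions(transcript) -> list[int]:
    """Genomic position of each coding nucleotide, in translation order."""
    positions: list[int] = []
    for start, end in transcript.cds_segments:
        if transcript.strand == "+":
            positions.extend(range(start, end))
        else:
            positions.extend(range(end - 1, start - 1, -1))
    return positions


def blocks_from_position_table(positions: list[int], lo: int, hi: int) -> list[tuple[int, int]]:
    """Expected genomic blocks for coding interval [lo, hi) from the table.

    Consecutive genomic positions are grouped into runs; runs are reported
    ascending.  Uses numpy so exhaustive range checks stay cheap.
    """
    span = np.sort(np.asarray(positions[lo:hi], dtype=np.int64))
    if span.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(span) != 1) + 1
    blocks = []
    for chunk in np.split(span, breaks):
        blocks.append((int(chunk[0]), int(chunk[-1]) + 1))
    return blocks


def hamming_scan(
    database: ProteinDatabase, peptide: str, max_mismatches: int
) -> set[tuple[str, int, tuple[int, ...]]]:
    """All (protein_key, aa_start_1based, mismatch_positions) with Hamming
    distance <= max_mismatches; X/B/Z/U in the protein never match."""
    length = len(peptide)
    pep = np.frombuffer(peptide.encode(), dtype=np.uint8)
    ambiguous = np.frombuffer("".join(sorted(AMBIGUOUS)).encode(), dtype=np.uint8)
    hits: set[tuple[str, int, tuple[int, ...]]] = set()
    for key, entry in database.items():
        seq = np.frombuffer(entry.sequence.encode(), dtype=np.uint8)
        if seq.size < length:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(seq, length)
        mism = (windows != pep) | np.isin(windows, ambiguous)
        counts = mism.sum(axis=1)
        for start in np.flatnonzero(counts <= max_mismatches):
            positions = tuple(int(i) + 1 for i in np.flatnonzero(mism[start]))
            hits.add((key, int(start) + 1, positions))
    return hits


def classify_from_sets(gene_ids: set[str], transcript_ids: set[str]) -> Uniqueness:
    """The 3-tier rule, restated independently for cross-checks."""
    if len(gene_ids) > 1:
        return Uniqueness.MULTI_GENE
    if len(transcript_ids) == 1:
        return Uniqueness.UNIQUE_TRANSCRIPT
    return Uniqueness.UNIQUE_GENE


def random_transcript(rng: np.random.Generator, max_segments: int = 10, max_nt: int = 3000):
    """A random valid TranscriptModel for coordinate-oracle testing."""
    from pepmap.annotation import TranscriptModel

    n_segments = int(rng.integers(1, max_segments + 1))
    n_codons = int(rng.integers(n_segments, max(n_segments, max_nt // 3) + 1))
    total = 3 * n_codons
    # split total nt into n_segments parts >= 1
    cuts = np.sort(rng.choice(np.arange(1, total), size=n_segments - 1, replace=False)) if n_segments > 1 else np.array([], dtype=int)
    sizes = np.diff(np.concatenate(([0], cuts, [total])))
    strand = "+" if rng.random() < 0.5 else "-"
    segments = []
    pos = int(rng.integers(0, 1000))
    for size in sizes:
        segments.append((pos, pos + int(size)))
        pos += int(size) + int(rng.integers(1, 500))  # gap >= 1
    if strand == "-":
        segments = segments[::-1]
    return TranscriptModel(
        transcript_id=f"TX{int(rng.integers(0, 10**6)):06d}",
        gene_id="G1",
        chrom="chr1",
        strand=strand,
        cds_segments=tuple(segments),
    )
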