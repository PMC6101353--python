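"""Protein translation database and bounded-mismatch peptide search.

The search problem: find every occurrence of a peptide within a set of
transcript translation sequences at Hamming distance at most ``m`` for
``m`` in {0, 1, 2}.  Candidate generation uses the pigeonhole principle —
split the peptide into ``m + 1`` consecutive parts; any occurrence with at
most ``m`` mismatches must contain at least one part that matches exactly,
so exact k-mer lookups on the parts enumerate a candidate superset which is
then verified by full Hamming comparison.

The mismatch cap is hard-limited to 2: the number of candidate mappings (and
hence memory) grows steeply with the allowance, which is also why staged
mapping (exact first, then remap the remainder) is the recommended workflow
for variant peptides.

Ambiguity conventions: ``X``/``B``/``Z``/``U`` in a protein never match any
peptide residue and always count as a mismatch.  Isoleucine and leucine are
distinct by default (reference translations are matched literally); pass
``il_equivalent=True`` to treat them as equal, since mass spectrometry cannot
distinguish the isobaric pair.
"""

from __future__ import annotations

import gzip
import logging
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Callable, Iterator, Union

from Bio import SeqIO

from .errors import FastaError, SearchInputError

log = logging.getLogger(__name__)

__all__ = [
    "ProteinEntry",
    "ProteinDatabase",
    "PeptideIndex",
    "ProteinHit",
    "load_fasta",
    "build_index",
    "find_peptide",
    "default_header_rule",
]

AA_ALPHABET = frozenset(string.ascii_uppercase)
AMBIGUOUS = frozenset("XBZU")

DEFAULT_KMER_LEN = 4

_ENST_TOKEN = re.compile(r"ENS[A-Z]*T\d+(\.\d+)?")


@dataclass(frozen=True)
class ProteinEntry:
    """One translation sequence keyed by its transcript identifier."""

    protein_key: str
    sequence: str


@dataclass(frozen=True)
class ProteinHit:
    """A peptide occurrence within one protein.

    ``aa_start``/``aa_end`` are 1-based inclusive residue positions in the
    protein; ``mismatch_positions`` are 1-based positions *within the
    peptide*.
    """

    protein_key: str
    aa_start: int
    aa_end: int
    mismatch_positions: tuple[int, ...] = ()

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)


class ProteinDatabase:
    """Mapping of protein key -> :class:`ProteinEntry` with insertion order."""

    def __init__(self, entries: dict[str, ProteinEntry] | None = None):
        self.entries: dict[str, ProteinEntry] = dict(entries or {})

    def add(self, entry: ProteinEntry) -> None:
        if not entry.protein_key:
            raise FastaError("empty protein key")
        if not entry.sequence:
            raise FastaError(f"protein {entry.protein_key}: empty sequence")
        if entry.protein_key in self.entries:
            raise FastaError(f"duplicate protein key: {entry.protein_key}")
        self.entries[entry.protein_key] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __getitem__(self, key: str) -> ProteinEntry:
        return self.entries[key]

    def items(self):
        return self.entries.items()


def default_header_rule(header: str) -> str:
    """Extract the transcript identifier from a protein FASTA header.

    Handles the two common dialects: Ensembl ``pep.all`` headers carry a
    ``transcript:ENST...`` token; GENCODE headers are pipe-delimited with the
    ENST token somewhere in the first word.  Anything else falls back to the
    first whitespace-delimited word.
    """
    header = header.lstrip(">").strip()
    m = re.search(r"transcript:(\S+)", header)
    if m:
        return m.group(1)
    first = header.split()[0] if header.split() else ""
    if "|" in first:
        for token in first.split("|"):
            if _ENST_TOKEN.fullmatch(token):
                return token
        return first.split("|")[0]
    return first


def load_fasta(
    source: Union[str, Path, IO[str]],
    header_rule: Callable[[str], str] = default_header_rule,
) -> ProteinDatabase:
    """Load a protein FASTA (optionally gzip-compressed) into a database.

    Sequences are uppercased and a trailing stop symbol ``*`` is stripped.
    Records with an empty sequence are skipped with a warning; duplicate keys
    raise :class:`FastaError`.
    """
    database = ProteinDatabase()

    def _load(handle: IO[str]) -> None:
        for record in SeqIO.parse(handle, "fasta"):
            key = header_rule(record.description)
            seq = str(record.seq).upper()
            if seq.endswith("*"):
                seq = seq[:-1]
            if not seq:
                log.warning("skipping FASTA record with empty sequence: %s", key)
                continue
            database.add(ProteinEntry(protein_key=key, sequence=seq))

    if isinstance(source, (str, Path)):
        opener = gzip.open if str(source).endswith(".gz") else open
        with opener(source, "rt", encoding="utf-8") as handle:  # type: ignore[operator]
            _load(handle)
    else:
        _load(source)
    return database


@dataclass
class PeptideIndex:
    """Exact k-mer postings over a protein database.

    Proteins shorter than ``kmer_len`` are indexed under their full sequence
    as a degenerate k-mer so they remain findable by the direct-scan path.
    """

    kmer_len: int
    postings: dict[str, list[tuple[str, int]]] = field(default_factory=dict)


def build_index(database: ProteinDatabase, kmer_len: int = DEFAULT_KMER_LEN) -> PeptideIndex:
    if kmer_len < 1:
        raise SearchInputError(f"kmer_len must be >= 1, got {kmer_len}")
    postings: dict[str, list[tuple[str, int]]] = {}
    for key, entry in database.items():
        seq = entry.sequence
        if len(seq) < kmer_len:
            postings.setdefault(seq, []).append((key, 0))
            continue
        for off in range(len(seq) - kmer_len + 1):
            postings.setdefault(seq[off : off + kmer_len], []).append((key, off))
    return PeptideIndex(kmer_len=kmer_len, postings=postings)


def _residues_equal(p: str, q: str, il_equivalent: bool) -> bool:
    if q in AMBIGUOUS:
        return False
    if p == q:
        return True
    return il_equivalent and p in "IL" and q in "IL"


def _hamming_within(
    peptide: str, protein_seq: str, start: int, cap: int, il_equivalent: bool
) -> tuple[int, ...] | None:
    """Mismatch positions (1-based, peptide-relative) if at most ``cap``, else None."""
    positions: list[int] = []
    for i, p in enumerate(peptide):
        if not _residues_equal(p, protein_seq[start + i], il_equivalent):
            positions.append(i + 1)
            if len(positions) > cap:
                return None
    return tuple(positions)


def _pigeonhole_parts(peptide: str, n_parts: int) -> list[tuple[int, str]]:
    """Split into ``n_parts`` consecutive parts, lengths as even as possible."""
    length = len(peptide)
    base, extra = divmod(length, n_parts)
    parts: list[tuple[int, str]] = []
    offset = 0
    for i in range(n_parts):
        size = base + (1 if i < extra else 0)
        parts.append((offset, peptide[offset : offset + size]))
        offset += size
    return parts


def find_peptide(
    index: PeptideIndex,
    database: ProteinDatabase,
    plain_peptide: str,
    max_mismatches: int = 0,
    il_equivalent: bool = False,
) -> list[ProteinHit]:
    """Find every occurrence of ``plain_peptide`` at Hamming distance
    <= ``max_mismatches`` in the database.

    Returns hits sorted by (protein_key, aa_start); duplicates (same protein,
    same offset) are collapsed.  Peptides too short for the pigeonhole parts
    to reach the index k-mer length — and all I/L-equivalent searches, whose
    seeds are no longer exact strings — fall back to a direct scan of every
    protein.
    """
    if max_mismatches not in (0, 1, 2):
        raise SearchInputError(
            f"max_mismatches must be 0, 1 or 2, got {max_mismatches}"
        )
    if not plain_peptide:
        raise SearchInputError("empty peptide")
    bad = set(plain_peptide) - AA_ALPHABET
    if bad:
        raise SearchInputError(
            f"peptide {plain_peptide!r} contains non-amino-acid characters: "
            f"{''.join(sorted(bad))}"
        )

    length = len(plain_peptide)
    parts = _pigeonhole_parts(plain_peptide, max_mismatches + 1)
    use_index = not il_equivalent and all(len(p) >= index.kmer_len for _, p in parts)

    candidates: set[tuple[str, int]] = set()
    if use_index:
        k = index.kmer_len
        for part_offset, part in parts:
            for pkey, ppos in index.postings.get(part[:k], ()):
                start = ppos - part_offset
                if start >= 0:
                    candidates.add((pkey, start))
    else:
        for pkey, entry in database.items():
            for start in range(len(entry.sequence) - length + 1):
                candidates.add((pkey, start))

    hits: list[ProteinHit] = []
    for pkey, start in candidates:
        seq = database[pkey].sequence
        if start + length > len(seq):
            continue
        mismatches = _hamming_within(
            plain_peptide, seq, start, max_mismatches, il_equivalent
        )
        if mismatches is not None:
            hits.append(
                ProteinHit(
                    protein_key=pkey,
                    aa_start=start + 1,
                    aa_end=start + length,
                    mismatch_positions=mismatches,
                )
            )
    hits.sort(key=lambda h: (h.protein_key, h.aa_start))
    return hits
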