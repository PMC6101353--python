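"""Reading and writing peptide identification tables.

The native input is a 4-column tab-separated table (``.txt``/``.tsv``/
``.pogo``) with the header ``Sample  Peptide  PSMs  Quant``: sample
identifier, peptide sequence (optionally carrying inline PTM tags), number of
peptide-spectrum matches, and a quantitative value.  Quantitation semantics
are assay-defined and values pass through untransformed.

Inline PTM dialect
------------------
A parenthesised lowercase tag annotates the residue immediately preceding it:
``GSNK(phospho)R`` marks residue 4 as phosphorylated.  Multiple tags on
distinct residues are allowed.  Canonical tags (phospho, acetyl, oxidation,
methyl, ubi) get dedicated colors in PTM-BED output; unrecognised tags are
preserved verbatim as their own PTM type.  Matching and mapping always use
the plain sequence — modifications are a visualisation layer only.

MaxQuant conversion replicates the spreadsheet unpivot of a ``peptides.txt``:
for each peptide and experiment, one record is emitted only when both the
``Experiment <name>`` count and the ``Ratio H/L normalized <name>`` value are
present for the *same* experiment name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Union

import pandas as pd

from .errors import ModifiedSequenceError, PeptideTableError

log = logging.getLogger(__name__)

__all__ = [
    "PeptideRecord",
    "CANONICAL_PTM_TYPES",
    "parse_modified_sequence",
    "read_pogo_table",
    "write_pogo_table",
    "convert_maxquant",
    "subtract_mapped",
]

CANONICAL_PTM_TYPES = ("phospho", "acetyl", "oxidation", "methyl", "ubi")

_HEADER = ("sample", "peptide", "psms", "quant")
# Fig-2-style files label the first column "Experiment"; accept both spellings.
_SAMPLE_ALIASES = {"sample", "experiment"}


@dataclass(frozen=True)
class PeptideRecord:
    """One input row: a peptide observed in one sample."""

    sample: str
    modified_sequence: str
    plain_sequence: str
    ptms: tuple[tuple[int, str], ...]
    psms: int
    quant: float

    @classmethod
    def from_fields(cls, sample: str, peptide: str, psms: int, quant: float) -> "PeptideRecord":
        plain, ptms = parse_modified_sequence(peptide)
        return cls(
            sample=sample,
            modified_sequence=peptide,
            plain_sequence=plain,
            ptms=ptms,
            psms=psms,
            quant=quant,
        )


def parse_modified_sequence(s: str) -> tuple[str, tuple[tuple[int, str], ...]]:
    """Split an inline-modified sequence into (plain sequence, PTM list).

    PTM positions are 1-based within the plain sequence; types are
    lowercased.  Raises :class:`ModifiedSequenceError` for a tag with no
    preceding residue or unbalanced parentheses.
    """
    plain: list[str] = []
    ptms: list[tuple[int, str]] = []
    i = 0
    while i < len(s):
        c = s[i]
        if c == "(":
            if not plain:
                raise ModifiedSequenceError(
                    f"{s!r}: PTM tag with no preceding residue"
                )
            end = s.find(")", i + 1)
            if end == -1:
                raise ModifiedSequenceError(f"{s!r}: unbalanced parentheses")
            tag = s[i + 1 : end].lower()
            if not tag or not tag.isalnum():
                raise ModifiedSequenceError(f"{s!r}: invalid PTM tag {tag!r}")
            ptms.append((len(plain), tag))
            i = end + 1
        elif c == ")":
            raise ModifiedSequenceError(f"{s!r}: unbalanced parentheses")
        else:
            plain.append(c.upper())
            i += 1
    return "".join(plain), tuple(ptms)


def _open_text(source: Union[str, Path, IO[str]], mode: str = "rt"):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8", newline="")
    return source


def _aggregate(records: list[PeptideRecord]) -> list[PeptideRecord]:
    """Merge records with identical (sample, modified_sequence): PSMs sum,
    Quant keeps the first value (warning on conflict)."""
    merged: dict[tuple[str, str], PeptideRecord] = {}
    for rec in records:
        key = (rec.sample, rec.modified_sequence)
        prev = merged.get(key)
        if prev is None:
            merged[key] = rec
        else:
            if prev.quant != rec.quant:
                log.warning(
                    "conflicting Quant for (%s, %s): keeping %g, ignoring %g",
                    rec.sample,
                    rec.modified_sequence,
                    prev.quant,
                    rec.quant,
                )
            merged[key] = replace(prev, psms=prev.psms + rec.psms)
    return list(merged.values())


def read_pogo_table(source: Union[str, Path, IO[str]]) -> list[PeptideRecord]:
    """Read a 4-column peptide table into records.

    Header order is fixed (Sample, Peptide, PSMs, Quant; case-insensitive);
    blank lines are skipped; duplicate (sample, modified sequence) rows are
    aggregated.  Errors name the offending line number.
    """
    handle = _open_text(source)
    close = isinstance(source, (str, Path))
    try:
        records: list[PeptideRecord] = []
        header_seen = False
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if not header_seen:
                names = tuple(f.strip().lower() for f in fields)
                ok = (
                    len(names) == 4
                    and names[0] in _SAMPLE_ALIASES
                    and names[1:] == _HEADER[1:]
                )
                if not ok:
                    raise PeptideTableError(
                        f"line {lineno}: expected header "
                        "'Sample\\tPeptide\\tPSMs\\tQuant', got "
                        f"{line!r}"
                    )
                header_seen = True
                continue
            if len(fields) != 4:
                raise PeptideTableError(
                    f"line {lineno}: expected 4 tab-separated columns, got "
                    f"{len(fields)}"
                )
            sample, peptide, psms_s, quant_s = (f.strip() for f in fields)
            try:
                psms = int(psms_s)
            except ValueError as exc:
                raise PeptideTableError(
                    f"line {lineno}: PSMs must be an integer, got {psms_s!r}"
                ) from exc
            if psms < 0:
                raise PeptideTableError(f"line {lineno}: PSMs must be >= 0")
            try:
                quant = float(quant_s)
            except ValueError as exc:
                raise PeptideTableError(
                    f"line {lineno}: Quant must be numeric, got {quant_s!r}"
                ) from exc
            records.append(PeptideRecord.from_fields(sample, peptide, psms, quant))
        if not header_seen:
            raise PeptideTableError("missing header line")
        return _aggregate(records)
    finally:
        if close:
            handle.close()


def _format_quant(q: float) -> str:
    return format(q, "g")


def write_pogo_table(records: Iterable[PeptideRecord], dest: Union[str, Path, IO[str]]) -> None:
    """Write records back to the 4-column tab-separated format."""
    handle = _open_text(dest, "wt")
    close = isinstance(dest, (str, Path))
    try:
        handle.write("Sample\tPeptide\tPSMs\tQuant\n")
        for rec in records:
            handle.write(
                f"{rec.sample}\t{rec.modified_sequence}\t{rec.psms}\t"
                f"{_format_quant(rec.quant)}\n"
            )
    finally:
        if close:
            handle.close()


def convert_maxquant(source: Union[str, Path, IO[str]]) -> list[PeptideRecord]:
    """Convert a MaxQuant ``peptides.txt`` into peptide records.

    Emits one record per (peptide, experiment) where both the
    ``Experiment <name>`` count and ``Ratio H/L normalized <name>`` are
    present; unpaired cells are dropped (the experiment-name equality filter
    of the spreadsheet workflow).
    """
    table = pd.read_csv(source, sep="\t", dtype=str)
    if "Sequence" not in table.columns:
        raise PeptideTableError("MaxQuant table is missing the 'Sequence' column")
    exp_cols = {
        col[len("Experiment ") :]: col
        for col in table.columns
        if col.startswith("Experiment ")
    }
    ratio_cols = {
        col[len("Ratio H/L normalized ") :]: col
        for col in table.columns
        if col.startswith("Ratio H/L normalized ")
    }
    if not exp_cols:
        raise PeptideTableError("MaxQuant table has no 'Experiment <name>' columns")

    def _present(value) -> bool:
        return not (pd.isna(value) or str(value).strip() == "")

    records: list[PeptideRecord] = []
    for _, row in table.iterrows():
        peptide = row["Sequence"]
        if not _present(peptide):
            continue
        for name, exp_col in exp_cols.items():
            ratio_col = ratio_cols.get(name)
            if ratio_col is None:
                continue
            count, ratio = row[exp_col], row[ratio_col]
            # both sides of the (count, ratio) pair must exist for this
            # experiment name, mirroring the TRUE-filter on name equality
            if not (_present(count) and _present(ratio)):
                continue
            records.append(
                PeptideRecord.from_fields(
                    sample=name,
                    peptide=str(peptide),
                    psms=int(float(count)),
                    quant=float(ratio),
                )
            )
    return _aggregate(records)


def subtract_mapped(
    records: Iterable[PeptideRecord], mapped_plain_sequences: set[str]
) -> list[PeptideRecord]:
    """Drop records whose plain sequence already produced a mapping,
    preserving input order — the subtraction step of staged mapping."""
    return [r for r in records if r.plain_sequence not in mapped_plain_sequences]
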