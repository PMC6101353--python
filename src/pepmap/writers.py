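"""Serialisation of mapping runs: BED12, PTM-BED, GTF, GCT and track hubs.

All writers are byte-deterministic: identical runs produce identical files.

BED12 encodes each peptide mapping as one line; junction-spanning peptides
get one block per exon part, joined by thin intron lines in a browser.  The
itemRgb column carries the uniqueness tier (red/black/grey).  The score
column encodes spectral support as ``min(1000, PSMs x 200)`` — browsers
expect 0-1000; the factor is a documented, configurable convention of this
package.

PTM-BED splits the output in two: ``*_noptm.bed`` holds peptides observed
without any modification (zero-width thick region), ``*_ptm.bed`` holds one
line per (mapping, PTM type) whose thick region covers the genomic codons
from the first to the last modified residue of that type — a single PTM
highlights exactly its residue's codon.  The thick region of a BED line is a
single interval, so a modification whose codons land on both sides of a
splice junction is drawn as the bounding interval, clipped to the mapping
span; this reflects the single-feature limitation of the format, not
ambiguity in the site localisation.

GCT (v1.2) carries per-sample quantitation; junction peptides are split into
one row per exon part, every part carrying the peptide's quant values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Callable, Union

from .annotation import spliced_subinterval
from .errors import PepmapError, TrackHubError
from .mapper import GenomicMapping, MappingRun, Uniqueness

__all__ = [
    "ColorScheme",
    "TrackSet",
    "write_bed",
    "write_ptm_bed",
    "write_gct",
    "write_gtf",
    "write_track_hub",
]

RGB = tuple[int, int, int]

DEFAULT_UNIQUENESS_RGB: dict[Uniqueness, RGB] = {
    Uniqueness.UNIQUE_TRANSCRIPT: (255, 0, 0),   # red
    Uniqueness.UNIQUE_GENE: (0, 0, 0),           # black
    Uniqueness.MULTI_GENE: (128, 128, 128),      # grey
}

# phospho is red by convention; the rest of the palette is this package's
# documented choice and can be overridden from a config file.
DEFAULT_PTM_RGB: dict[str, RGB] = {
    "phospho": (255, 0, 0),
    "acetyl": (0, 0, 255),
    "oxidation": (0, 128, 0),
    "methyl": (255, 165, 0),
    "ubi": (128, 0, 128),
}
FALLBACK_PTM_RGB: RGB = (0, 150, 150)

BED_SCORE_PER_PSM = 200


def _check_rgb(rgb: RGB, what: str) -> RGB:
    if len(rgb) != 3 or any(not 0 <= c <= 255 for c in rgb):
        raise PepmapError(f"invalid RGB for {what}: {rgb}")
    return rgb


@dataclass
class ColorScheme:
    """Color assignments for uniqueness tiers and PTM types."""

    uniqueness_rgb: dict[Uniqueness, RGB] = field(
        default_factory=lambda: dict(DEFAULT_UNIQUENESS_RGB)
    )
    ptm_rgb: dict[str, RGB] = field(default_factory=lambda: dict(DEFAULT_PTM_RGB))
    fallback_ptm_rgb: RGB = FALLBACK_PTM_RGB
    score_per_psm: int = BED_SCORE_PER_PSM

    def uniqueness_color(self, tier: Uniqueness) -> str:
        r, g, b = _check_rgb(self.uniqueness_rgb[tier], tier.value)
        return f"{r},{g},{b}"

    def ptm_color(self, ptm_type: str) -> str:
        r, g, b = _check_rgb(
            self.ptm_rgb.get(ptm_type, self.fallback_ptm_rgb), ptm_type
        )
        return f"{r},{g},{b}"

    def score(self, psms: int) -> int:
        return min(1000, psms * self.score_per_psm)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ColorScheme":
        """Load overrides from a simple ``key=r,g,b`` text file.

        Keys are ``uniqueness.<tier>`` or ``ptm.<type>``; unknown keys raise.
        """
        scheme = cls()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                key, value = (part.strip() for part in line.split("=", 1))
                rgb = tuple(int(x) for x in value.split(","))
            except ValueError as exc:
                raise PepmapError(
                    f"{path}: line {lineno}: expected 'key=r,g,b'"
                ) from exc
            rgb = _check_rgb(rgb, key)  # type: ignore[arg-type]
            if key.startswith("uniqueness."):
                tier = Uniqueness(key[len("uniqueness.") :])
                scheme.uniqueness_rgb[tier] = rgb  # type: ignore[assignment]
            elif key.startswith("ptm."):
                scheme.ptm_rgb[key[len("ptm.") :]] = rgb  # type: ignore[assignment]
            else:
                raise PepmapError(f"{path}: line {lineno}: unknown key {key!r}")
        return scheme


@dataclass
class TrackSet:
    """Paths of the output artifacts produced for one run."""

    bed: Path | None = None
    ptm_bed: Path | None = None
    noptm_bed: Path | None = None
    gtf: Path | None = None
    gct: Path | None = None
    hub_dir: Path | None = None

    def paths(self) -> list[Path]:
        return [
            p
            for p in (self.bed, self.ptm_bed, self.noptm_bed, self.gtf, self.gct, self.hub_dir)
            if p is not None
        ]


def _open_out(dest: Union[str, Path, IO[str]]):
    if isinstance(dest, (str, Path)):
        return open(dest, "wt", encoding="utf-8", newline=""), True
    return dest, False


def _sorted_mappings(run: MappingRun) -> list[GenomicMapping]:
    return sorted(
        run.mappings, key=lambda m: (m.chrom, m.start, m.end, m.peptide, m.strand)
    )


def _bed12_line(
    m: GenomicMapping,
    rgb: str,
    score: int,
    thick: tuple[int, int] | None = None,
    name: str | None = None,
) -> str:
    start, end = m.start, m.end
    thick_start, thick_end = thick if thick is not None else (start, end)
    sizes = ",".join(str(e - s) for s, e in m.blocks)
    starts = ",".join(str(s - start) for s, _ in m.blocks)
    return "\t".join(
        (
            m.chrom,
            str(start),
            str(end),
            name if name is not None else m.peptide,
            str(score),
            m.strand,
            str(thick_start),
            str(thick_end),
            rgb,
            str(len(m.blocks)),
            sizes,
            starts,
        )
    )


def write_bed(
    run: MappingRun,
    dest: Union[str, Path, IO[str]],
    color_scheme: ColorScheme | None = None,
) -> None:
    """Write one BED12 line per mapping, sorted by (chrom, start)."""
    scheme = color_scheme or ColorScheme()
    handle, close = _open_out(dest)
    try:
        for m in _sorted_mappings(run):
            line = _bed12_line(
                m,
                scheme.uniqueness_color(m.uniqueness),
                scheme.score(m.total_psms),
            )
            handle.write(line + "\n")
    finally:
        if close:
            handle.close()


def _union_ptms(m: GenomicMapping) -> dict[str, list[int]]:
    """PTM positions by type, unioned over all records of the peptide."""
    by_type: dict[str, set[int]] = {}
    for rec in m.records:
        for pos, ptm_type in rec.ptms:
            if pos > len(m.peptide):
                raise PepmapError(
                    f"PTM position {pos} outside peptide {m.peptide}"
                )
            by_type.setdefault(ptm_type, set()).add(pos)
    return {t: sorted(ps) for t, ps in sorted(by_type.items())}


def peptide_nt_to_genomic(
    m: GenomicMapping, nt_lo: int, nt_hi: int
) -> list[tuple[int, int]]:
    """Genomic pieces covering peptide-relative coding nucleotides
    ``[nt_lo, nt_hi)`` within a mapping's blocks."""
    segments = m.blocks if m.strand == "+" else tuple(reversed(m.blocks))
    return spliced_subinterval(segments, m.strand, (nt_lo, nt_hi))


def _thick_for_ptm(m: GenomicMapping, positions: list[int]) -> tuple[int, int]:
    first, last = positions[0], positions[-1]
    pieces = peptide_nt_to_genomic(m, (first - 1) * 3, last * 3)
    thick_start = min(s for s, _ in pieces)
    thick_end = max(e for _, e in pieces)
    # BED cannot express a split thick region; clip the bounding interval
    return max(thick_start, m.start), min(thick_end, m.end)


def write_ptm_bed(
    run: MappingRun,
    ptm_dest: Union[str, Path, IO[str]],
    noptm_dest: Union[str, Path, IO[str]],
    color_scheme: ColorScheme | None = None,
) -> None:
    """Write the PTM-BED pair.

    A peptide observed with at least one PTM (in any sample) goes to the
    ``_ptm`` file with one line per (mapping, PTM type); peptides never seen
    modified go to the ``_noptm`` file.  The two peptide sets partition the
    mapped peptides.
    """
    scheme = color_scheme or ColorScheme()
    ptm_handle, close_ptm = _open_out(ptm_dest)
    noptm_handle, close_noptm = _open_out(noptm_dest)
    try:
        for m in _sorted_mappings(run):
            ptms = _union_ptms(m)
            score = scheme.score(m.total_psms)
            if not ptms:
                line = _bed12_line(
                    m,
                    scheme.uniqueness_color(m.uniqueness),
                    score,
                    thick=(m.start, m.start),
                )
                noptm_handle.write(line + "\n")
                continue
            for ptm_type, positions in ptms.items():
                line = _bed12_line(
                    m,
                    scheme.ptm_color(ptm_type),
                    score,
                    thick=_thick_for_ptm(m, positions),
                )
                ptm_handle.write(line + "\n")
    finally:
        if close_ptm:
            ptm_handle.close()
        if close_noptm:
            noptm_handle.close()


def write_gct(run: MappingRun, dest: Union[str, Path, IO[str]]) -> None:
    """Write per-sample quantitation as GCT v1.2.

    One row per (mapping, block): junction peptides are split into their exon
    parts, each part carrying the peptide's quant value per sample.  Samples
    a peptide was not observed in are left empty.
    """
    samples = run.samples
    mappings = _sorted_mappings(run)

    rows: list[tuple[str, str, list[str]]] = []
    seen_names: dict[str, int] = {}
    for m in mappings:
        quant_by_sample = {rec.sample: rec.quant for rec in m.records}
        values = [
            format(quant_by_sample[s], "g") if s in quant_by_sample else ""
            for s in samples
        ]
        description = ";".join(sorted(m.gene_ids))
        for bstart, bend in m.blocks:
            name = f"{m.peptide}@{m.chrom}:{bstart}-{bend}({m.strand})"
            count = seen_names.get(name, 0)
            seen_names[name] = count + 1
            if count:
                name = f"{name}#{count}"
            rows.append((name, description, values))

    handle, close = _open_out(dest)
    try:
        handle.write("#1.2\n")
        handle.write(f"{len(rows)}\t{len(samples)}\n")
        handle.write("\t".join(["Name", "Description", *samples]) + "\n")
        for name, description, values in rows:
            handle.write("\t".join([name, description, *values]) + "\n")
    finally:
        if close:
            handle.close()


def write_gtf(
    run: MappingRun, dest: Union[str, Path, IO[str]], source: str = "pepmap"
) -> None:
    """Write one ``transcript`` + per-block ``exon`` features per mapping
    (GTF: 1-based inclusive coordinates)."""
    handle, close = _open_out(dest)
    try:
        for m in _sorted_mappings(run):
            attrs = (
                f'peptide "{m.peptide}"; '
                f'gene_ids "{";".join(sorted(m.gene_ids))}"; '
                f'transcript_ids "{";".join(sorted(m.transcript_ids))}"; '
                f'uniqueness "{m.uniqueness.value}"; '
                f'mismatches "{m.n_mismatches}";'
            )
            handle.write(
                "\t".join(
                    (
                        m.chrom,
                        source,
                        "transcript",
                        str(m.start + 1),
                        str(m.end),
                        ".",
                        m.strand,
                        ".",
                        attrs,
                    )
                )
                + "\n"
            )
            for bstart, bend in m.blocks:
                handle.write(
                    "\t".join(
                        (
                            m.chrom,
                            source,
                            "exon",
                            str(bstart + 1),
                            str(bend),
                            ".",
                            m.strand,
                            ".",
                            attrs,
                        )
                    )
                    + "\n"
                )
    finally:
        if close:
            handle.close()


def _sort_bed_file(src: Path, dest: Path) -> None:
    lines = [l for l in src.read_text().splitlines() if l.strip()]

    def key(line: str):
        fields = line.split("\t")
        return (fields[0], int(fields[1]), int(fields[2]))

    lines.sort(key=key)
    dest.write_text("".join(line + "\n" for line in lines))


def write_track_hub(
    bed_dir: Union[str, Path],
    hub_name: str,
    assembly: str,
    email: str,
    out_dir: Union[str, Path],
    bed_to_bigbed: Callable[[Path, Path], None] | None = None,
) -> Path:
    """Write a UCSC track-hub scaffold from a directory of BED files.

    Produces ``hub.txt`` -> ``genomes.txt`` -> ``<assembly>/trackDb.txt``
    with one stanza per BED file; sorted copies of the BED files are placed
    next to the trackDb.  Conversion to bigBed is an optional hook
    (``bed_to_bigbed(sorted_bed, bb_path)``), disabled by default so the
    output has no binary dependency.
    """
    bed_dir = Path(bed_dir)
    out_dir = Path(out_dir)
    if not assembly.isalnum():
        raise TrackHubError(f"invalid assembly name {assembly!r} (must be alphanumeric)")
    bed_files = sorted(bed_dir.glob("*.bed"))
    if not bed_files:
        raise TrackHubError(f"no BED files found in {bed_dir}")

    assembly_dir = out_dir / assembly
    assembly_dir.mkdir(parents=True, exist_ok=True)

    (out_dir / "hub.txt").write_text(
        f"hub {hub_name}\n"
        f"shortLabel {hub_name}\n"
        f"longLabel {hub_name}\n"
        f"genomesFile genomes.txt\n"
        f"email {email}\n"
    )
    (out_dir / "genomes.txt").write_text(
        f"genome {assembly}\ntrackDb {assembly}/trackDb.txt\n"
    )

    stanzas: list[str] = []
    for bed in bed_files:
        stem = bed.stem
        sorted_bed = assembly_dir / f"{stem}.bed"
        _sort_bed_file(bed, sorted_bed)
        data_url = f"{stem}.bed"
        if bed_to_bigbed is not None:
            bb_path = assembly_dir / f"{stem}.bb"
            bed_to_bigbed(sorted_bed, bb_path)
            data_url = f"{stem}.bb"
        stanzas.append(
            f"track {stem}\n"
            f"bigDataUrl {data_url}\n"
            f"shortLabel {stem}\n"
            f"longLabel {stem}\n"
            f"type bigBed 12\n"
            f"itemRgb on\n"
            f"visibility dense\n"
        )
    (assembly_dir / "trackDb.txt").write_text("\n".join(stanzas))
    return out_dir
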