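"""Synthetic genomes, annotations, translation FASTA and peptide tables.

The generator builds a small random gene universe — multi-exon protein-coding
genes on both strands, genes with several transcripts sharing one CDS (to
exercise the single-gene/multi-transcript uniqueness tier) and duplicated
genes (to exercise the multi-gene tier) — then samples peptides from the
translated proteins with planted junction-spanning windows, inline PTM tags
and single-substitution variants.  Everything is reproducible from the seed,
and the expected mapping of every peptide (loci, uniqueness tier, mapping
stage, mismatch positions) is recorded as ground truth computed by an
exhaustive scan that is independent of the mapping engine.

What the fixtures emulate: spliced coding structure, strandedness, shared and
duplicated coding sequence, junction-spanning peptides, amino-acid variants.
What they deliberately do not: identification error, missed cleavages,
realistic codon usage or amino-acid composition, overlapping genes,
selenocysteine.  Intergenic spacing is at least 100 nt so multi-gene hits
only arise where planted (or by rare k-mer coincidence, which the ground
truth, being scan-based, accounts for).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from Bio.Seq import Seq

from .errors import FixtureError
from .mapper import MappingRun, Uniqueness
from .peptide_io import PeptideRecord, write_pogo_table

log = logging.getLogger(__name__)

__all__ = [
    "FixtureSpec",
    "GroundTruthEntry",
    "GroundTruth",
    "Fixture",
    "ValidationReport",
    "generate",
    "validate_against_truth",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = sorted(
    a + b + c for a in _BASES for b in _BASES for c in _BASES if a + b + c not in _STOPS
)
_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

Locus = tuple[str, str, tuple[tuple[int, int], ...]]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset; deterministic given ``seed``."""

    seed: int = 0
    n_genes: int = 10
    transcripts_per_gene: tuple[int, int] = (1, 2)
    exons_per_transcript: tuple[int, int] = (1, 4)
    fraction_minus_strand: float = 0.5
    n_peptides: int = 100
    fraction_junction_spanning: float = 0.2
    fraction_modified: float = 0.1
    fraction_variant: float = 0.1
    samples: tuple[str, ...] = ("S1", "S2")
    peptide_length: tuple[int, int] = (7, 25)
    n_duplicate_genes: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "fraction_minus_strand",
            "fraction_junction_spanning",
            "fraction_modified",
            "fraction_variant",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise FixtureError(f"{name} must be in [0, 1], got {value}")
        if self.n_genes < 1 or self.n_peptides < 0:
            raise FixtureError("n_genes must be >= 1 and n_peptides >= 0")


@dataclass(frozen=True)
class GroundTruthEntry:
    """Expected mapping of one peptide."""

    plain: str
    stage: int
    tier: Uniqueness
    loci: frozenset[Locus]
    locus_mismatches: dict[Locus, tuple[int, ...]] = field(default_factory=dict)


@dataclass
class GroundTruth:
    entries: dict[str, GroundTruthEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class Fixture:
    """Paths and in-memory objects of one generated dataset."""

    spec: FixtureSpec
    genome_fasta: Path
    gtf: Path
    protein_fasta: Path
    peptide_table: Path
    records: list[PeptideRecord]
    truth: GroundTruth


@dataclass
class _Transcript:
    transcript_id: str
    segments_ascending: tuple[tuple[int, int], ...]  # 0-based half-open


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[_Transcript]
    coding: str  # translation-orientation nucleotide string
    protein: str

    @property
    def start(self) -> int:
        return self.transcripts[0].segments_ascending[0][0]


def _translation_positions(gene: _Gene) -> list[int]:
    """Genomic position of every coding nucleotide, in translation order."""
    segs = gene.transcripts[0].segments_ascending
    if gene.strand == "+":
        return [p for s, e in segs for p in range(s, e)]
    return [p for s, e in reversed(segs) for p in range(e - 1, s - 1, -1)]


def _blocks_from_positions(positions: Sequence[int], strand: str) -> tuple[tuple[int, int], ...]:
    ordered = list(positions) if strand == "+" else list(positions)[::-1]
    blocks: list[tuple[int, int]] = []
    run_start = prev = ordered[0]
    for p in ordered[1:]:
        if p != prev + 1:
            blocks.append((run_start, prev + 1))
            run_start = p
        prev = p
    blocks.append((run_start, prev + 1))
    blocks.sort()
    return tuple(blocks)


def _build_genes(spec: FixtureSpec, rng: np.random.Generator) -> list[_Gene]:
    chroms = ("chr1", "chr2")
    cursors = {c: 200 for c in chroms}
    min_len, max_len = spec.peptide_length
    min_codons = max(40, max_len + 5)

    def _make_structure(chrom: str, total_nt: int, n_exons: int) -> tuple[tuple[int, int], ...]:
        # split total_nt into n_exons parts of >= 20 nt each
        remaining = total_nt - 20 * n_exons
        cuts = sorted(rng.integers(0, remaining + 1, size=n_exons - 1)) if n_exons > 1 else []
        parts = []
        prev = 0
        for cut in [*cuts, remaining]:
            parts.append(20 + (cut - prev))
            prev = cut
        segments = []
        pos = cursors[chrom]
        for i, size in enumerate(parts):
            if i:
                pos += int(rng.integers(50, 301))  # intron
            segments.append((pos, pos + size))
            pos = segments[-1][1]
        cursors[chrom] = pos + 100 + int(rng.integers(0, 101))  # intergenic >= 100
        return tuple(segments)

    genes: list[_Gene] = []
    gene_counter = 0

    def _new_gene(coding: str | None, force_single_tx: bool = False) -> _Gene:
        nonlocal gene_counter
        gene_counter += 1
        gid = f"G{gene_counter:04d}"
        chrom = chroms[gene_counter % len(chroms)]
        strand = "-" if rng.random() < spec.fraction_minus_strand else "+"
        n_exons = int(rng.integers(spec.exons_per_transcript[0], spec.exons_per_transcript[1] + 1))
        if coding is None:
            n_codons = int(rng.integers(min_codons, min_codons + 80))
            idx = rng.integers(0, len(_CODONS), size=n_codons)
            coding = "".join(_CODONS[i] for i in idx)
        total_nt = len(coding)
        if total_nt < 20 * n_exons:
            n_exons = max(1, total_nt // 20)
        segments = _make_structure(chrom, total_nt, n_exons)
        n_tx = (
            1
            if force_single_tx
            else int(rng.integers(spec.transcripts_per_gene[0], spec.transcripts_per_gene[1] + 1))
        )
        transcripts = [
            _Transcript(transcript_id=f"T{gene_counter:04d}.{k + 1}", segments_ascending=segments)
            for k in range(n_tx)
        ]
        protein = str(Seq(coding).translate())
        assert "*" not in protein
        return _Gene(gid, chrom, strand, transcripts, coding, protein)

    for _ in range(spec.n_genes):
        genes.append(_new_gene(None))

    n_dup = spec.n_duplicate_genes
    if n_dup is None:
        n_dup = max(1, spec.n_genes // 10)
    if n_dup > spec.n_genes:
        raise FixtureError("n_duplicate_genes exceeds n_genes")
    if n_dup:
        sources = rng.choice(spec.n_genes, size=n_dup, replace=False)
        for src in sorted(int(s) for s in sources):
            genes.append(_new_gene(genes[src].coding, force_single_tx=True))
    return genes


def _write_genome(genes: list[_Gene], rng: np.random.Generator, path: Path) -> None:
    lengths: dict[str, int] = {}
    for gene in genes:
        end = gene.transcripts[0].segments_ascending[-1][1]
        lengths[gene.chrom] = max(lengths.get(gene.chrom, 0), end + 100)
    sequences: dict[str, np.ndarray] = {
        chrom: np.array(list(_BASES))[rng.integers(0, 4, size=n)]
        for chrom, n in sorted(lengths.items())
    }
    for gene in genes:
        positions = _translation_positions(gene)
        coding = gene.coding if gene.strand == "+" else gene.coding.translate(_COMPLEMENT)
        seq = sequences[gene.chrom]
        for i, pos in enumerate(positions):
            seq[pos] = coding[i]
    with open(path, "wt", encoding="utf-8") as handle:
        for chrom in sorted(sequences):
            handle.write(f">{chrom}\n")
            s = "".join(sequences[chrom])
            for off in range(0, len(s), 60):
                handle.write(s[off : off + 60] + "\n")


def _write_gtf(genes: list[_Gene], path: Path) -> None:
    with open(path, "wt", encoding="utf-8") as handle:
        for gene in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            segs = gene.transcripts[0].segments_ascending
            gstart, gend = segs[0][0] + 1, segs[-1][1]
            base_attrs = f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_id}_name";'
            handle.write(
                f"{gene.chrom}\tpepmap_fixture\tgene\t{gstart}\t{gend}\t.\t"
                f"{gene.strand}\t.\t{base_attrs}\n"
            )
            for tx in gene.transcripts:
                tx_attrs = f'{base_attrs} transcript_id "{tx.transcript_id}";'
                handle.write(
                    f"{gene.chrom}\tpepmap_fixture\ttranscript\t{gstart}\t{gend}\t.\t"
                    f"{gene.strand}\t.\t{tx_attrs}\n"
                )
                for s, e in tx.segments_ascending:
                    for feature in ("exon", "CDS"):
                        handle.write(
                            f"{gene.chrom}\tpepmap_fixture\t{feature}\t{s + 1}\t{e}\t.\t"
                            f"{gene.strand}\t0\t{tx_attrs}\n"
                        )


def _write_proteins(genes: list[_Gene], path: Path) -> None:
    with open(path, "wt", encoding="utf-8") as handle:
        for gene in genes:
            for tx in gene.transcripts:
                handle.write(f">{tx.transcript_id} gene:{gene.gene_id}\n")
                seq = gene.protein
                for off in range(0, len(seq), 60):
                    handle.write(seq[off : off + 60] + "\n")


def _exact_occurrences(proteins: dict[str, str], peptide: str) -> list[tuple[str, int]]:
    hits = []
    for key, seq in proteins.items():
        start = seq.find(peptide)
        while start != -1:
            hits.append((key, start))
            start = seq.find(peptide, start + 1)
    return hits


def _hamming_occurrences(
    proteins: dict[str, str], peptide: str, max_mm: int
) -> list[tuple[str, int, tuple[int, ...]]]:
    length = len(peptide)
    hits = []
    for key, seq in proteins.items():
        for start in range(len(seq) - length + 1):
            mism = []
            for i in range(length):
                if seq[start + i] != peptide[i]:
                    mism.append(i + 1)
                    if len(mism) > max_mm:
                        break
            else:
                hits.append((key, start, tuple(mism)))
    return hits


def _truth_for_hits(
    genes: list[_Gene],
    tx_to_gene: dict[str, _Gene],
    hits: list[tuple[str, int, tuple[int, ...]]],
    peptide: str,
    stage: int,
) -> GroundTruthEntry:
    positions_cache: dict[str, list[int]] = {}
    loci: dict[Locus, dict] = {}
    for tid, off, mism in hits:
        gene = tx_to_gene[tid]
        if gene.gene_id not in positions_cache:
            positions_cache[gene.gene_id] = _translation_positions(gene)
        positions = positions_cache[gene.gene_id]
        span = positions[off * 3 : (off + len(peptide)) * 3]
        blocks = _blocks_from_positions(span, gene.strand)
        locus: Locus = (gene.chrom, gene.strand, blocks)
        entry = loci.setdefault(locus, {"transcripts": set(), "genes": set(), "mism": mism})
        entry["transcripts"].add(tid)
        entry["genes"].add(gene.gene_id)
    all_genes = set().union(*(e["genes"] for e in loci.values()))
    all_txs = set().union(*(e["transcripts"] for e in loci.values()))
    if len(all_genes) > 1:
        tier = Uniqueness.MULTI_GENE
    elif len(all_txs) == 1:
        tier = Uniqueness.UNIQUE_TRANSCRIPT
    else:
        tier = Uniqueness.UNIQUE_GENE
    return GroundTruthEntry(
        plain=peptide,
        stage=stage,
        tier=tier,
        loci=frozenset(loci),
        locus_mismatches={locus: e["mism"] for locus, e in loci.items()},
    )


def generate(spec: FixtureSpec, out_dir: Union[str, Path]) -> Fixture:
    """Generate a complete synthetic dataset under ``out_dir``.

    Returns the file paths, the peptide records and the ground truth.  Raises
    :class:`FixtureError` when the spec is infeasible, e.g. junction-spanning
    peptides requested while every transcript is single-exon.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    genes = _build_genes(spec, rng)
    proteins = {
        tx.transcript_id: gene.protein for gene in genes for tx in gene.transcripts
    }
    tx_to_gene = {tx.transcript_id: gene for gene in genes for tx in gene.transcripts}
    all_transcripts = [tx for gene in genes for tx in gene.transcripts]

    n_junction = round(spec.fraction_junction_spanning * spec.n_peptides)
    n_variant = round(spec.fraction_variant * spec.n_peptides)
    if n_junction + n_variant > spec.n_peptides:
        raise FixtureError("junction + variant fractions exceed 1")
    multi_exon = [tx for tx in all_transcripts if len(tx.segments_ascending) > 1]
    if n_junction > 0 and not multi_exon:
        raise FixtureError(
            "junction-spanning peptides requested but every transcript is single-exon"
        )

    min_len, max_len = spec.peptide_length
    used: set[str] = set()
    truth = GroundTruth()
    plan: list[tuple[str, tuple[int, ...]]] = []  # (plain, planted mismatch positions)

    def _sample_window(tx: _Transcript, require_junction: bool) -> str | None:
        gene = tx_to_gene[tx.transcript_id]
        protein = gene.protein
        length = int(rng.integers(min_len, max_len + 1))
        if length > len(protein):
            return None
        if require_junction:
            seg_lengths = [e - s for s, e in tx.segments_ascending]
            if gene.strand == "-":
                seg_lengths = seg_lengths[::-1]
            boundaries = list(np.cumsum(seg_lengths))[:-1]
            boundary = int(boundaries[int(rng.integers(0, len(boundaries)))])
            starts = [
                a
                for a in range(1, len(protein) - length + 2)
                if (a - 1) * 3 < boundary < (a - 1) * 3 + 3 * length
            ]
            if not starts:
                return None
            a = int(starts[int(rng.integers(0, len(starts)))])
        else:
            a = int(rng.integers(1, len(protein) - length + 2))
        return protein[a - 1 : a - 1 + length]

    def _sample_peptide(require_junction: bool) -> str:
        pool = multi_exon if require_junction else all_transcripts
        for _ in range(2000):
            tx = pool[int(rng.integers(0, len(pool)))]
            peptide = _sample_window(tx, require_junction)
            if peptide is None or peptide in used:
                continue
            if set(peptide) - set(_STANDARD_AA):
                continue
            used.add(peptide)
            return peptide
        raise FixtureError("could not sample a fresh peptide; spec too tight")

    for _ in range(n_junction):
        peptide = _sample_peptide(require_junction=True)
        plan.append((peptide, ()))
    for _ in range(n_variant):
        for _ in range(2000):
            base = _sample_peptide(require_junction=False)
            pos = int(rng.integers(0, len(base)))
            alternatives = [a for a in _STANDARD_AA if a != base[pos]]
            residue = alternatives[int(rng.integers(0, len(alternatives)))]
            variant = base[:pos] + residue + base[pos + 1 :]
            if variant in used:
                continue
            if _exact_occurrences(proteins, variant):
                continue  # substitution accidentally recreated a real sequence
            used.discard(base)  # the reference window itself is not an input peptide
            used.add(variant)
            plan.append((variant, (pos + 1,)))
            break
        else:
            raise FixtureError("could not plant a variant peptide")
    for _ in range(spec.n_peptides - n_junction - n_variant):
        plan.append((_sample_peptide(require_junction=False), ()))

    # ground truth by exhaustive scan, independent of the mapping engine
    for plain, planted in plan:
        if planted:
            hits = _hamming_occurrences(proteins, plain, 1)
            entry = _truth_for_hits(genes, tx_to_gene, hits, plain, stage=1)
        else:
            exact = [(tid, off, ()) for tid, off in _exact_occurrences(proteins, plain)]
            entry = _truth_for_hits(genes, tx_to_gene, exact, plain, stage=0)
        truth.entries[plain] = entry

    # peptide table: PTM tags, samples, PSMs, quantitation
    n_modified = round(spec.fraction_modified * spec.n_peptides)
    modified_idx = set(
        int(i) for i in rng.choice(len(plan), size=min(n_modified, len(plan)), replace=False)
    ) if plan else set()
    ptm_pool = ("phospho", "phospho", "acetyl", "oxidation")
    records: list[PeptideRecord] = []
    for i, (plain, _) in enumerate(plan):
        modified_sequence = plain
        if i in modified_idx:
            n_tags = int(rng.integers(1, 3))
            tag_positions = sorted(
                int(p) for p in rng.choice(len(plain), size=min(n_tags, len(plain)), replace=False)
            )
            tag = ptm_pool[int(rng.integers(0, len(ptm_pool)))]
            out = []
            for j, residue in enumerate(plain):
                out.append(residue)
                if j in tag_positions:
                    out.append(f"({tag})")
            modified_sequence = "".join(out)
        n_samples = int(rng.integers(1, min(2, len(spec.samples)) + 1))
        chosen = sorted(
            int(s) for s in rng.choice(len(spec.samples), size=n_samples, replace=False)
        )
        for s in chosen:
            records.append(
                PeptideRecord.from_fields(
                    sample=spec.samples[s],
                    peptide=modified_sequence,
                    psms=int(rng.integers(1, 21)),
                    quant=round(float(rng.uniform(0.1, 10.0)), 4),
                )
            )

    genome_fasta = out_dir / "genome.fa"
    gtf = out_dir / "annotation.gtf"
    protein_fasta = out_dir / "proteins.fa"
    peptide_table = out_dir / "peptides.pogo"
    _write_genome(genes, rng, genome_fasta)
    _write_gtf(genes, gtf)
    _write_proteins(genes, protein_fasta)
    write_pogo_table(records, peptide_table)

    return Fixture(
        spec=spec,
        genome_fasta=genome_fasta,
        gtf=gtf,
        protein_fasta=protein_fasta,
        peptide_table=peptide_table,
        records=records,
        truth=truth,
    )


@dataclass
class ValidationReport:
    """Exact-set comparison of a mapping run against planted ground truth."""

    n_peptides: int
    n_correct: int
    discrepancies: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.discrepancies


def validate_against_truth(
    staged: Union[MappingRun, Sequence[tuple[int, MappingRun]]],
    truth: GroundTruth,
) -> ValidationReport:
    """Compare staged mapping results with the fixture's ground truth.

    Checks, per peptide: the stage at which it mapped, the exact locus set,
    the uniqueness tier of every mapping, and (for variants) the mismatch
    positions per locus.
    """
    if isinstance(staged, MappingRun):
        staged = [(staged.max_mismatches, staged)]
    report = ValidationReport(n_peptides=len(truth.entries), n_correct=0)

    for plain, entry in truth.entries.items():
        problems: list[str] = []
        mapped_stage = None
        mappings = None
        for mm, run in staged:
            if plain in run.mapped_plain_sequences:
                mapped_stage = mm
                mappings = run.by_peptide[plain]
                break
        if mapped_stage is None:
            problems.append(f"{plain}: expected stage {entry.stage}, never mapped")
        else:
            if mapped_stage != entry.stage:
                problems.append(
                    f"{plain}: mapped at stage {mapped_stage}, expected {entry.stage}"
                )
            found = {m.locus() for m in mappings}
            missing = entry.loci - found
            extra = found - entry.loci
            if missing:
                problems.append(f"{plain}: {len(missing)} planted locus/loci not recovered")
            if extra:
                problems.append(f"{plain}: {len(extra)} spurious locus/loci reported")
            tiers = {m.uniqueness for m in mappings}
            if tiers != {entry.tier}:
                problems.append(
                    f"{plain}: tier {sorted(t.value for t in tiers)}, expected {entry.tier.value}"
                )
            for m in mappings:
                expected_mm = entry.locus_mismatches.get(m.locus())
                if expected_mm is not None and tuple(m.mismatch_positions) != expected_mm:
                    problems.append(
                        f"{plain}: mismatch positions {m.mismatch_positions} != planted {expected_mm}"
                    )
        if problems:
            report.discrepancies.extend(problems)
        else:
            report.n_correct += 1
    return report
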