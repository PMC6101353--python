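# Methods

## Coordinate model

All internal coordinates (and all BED output) are 0-based half-open; GTF is
1-based inclusive and is converted exactly once, at parse time. A transcript
is reduced to its CDS segments, kept in *translation order*: ascending
genomic position on the plus strand, descending on the minus strand. Only
transcripts with at least one CDS feature are retained — they are the only
possible mapping targets; exon-only (non-coding) transcripts are dropped.

A peptide at residues $a..b$ of a translation occupies coding nucleotides
$[3(a-1), 3b)$. The projection to the genome walks the CDS segments in
translation order, accumulating lengths, and emits one genomic block per
segment overlapped; blocks are reported ascending by genomic start (browser
convention) regardless of strand. Two invariants hold by construction and
are enforced in tests: total block length equals $3(b-a+1)$, and the blocks
agree with a brute-force per-nucleotide mapping table.

Decisions where the format conventions leave room:

* **CDS frame/phase is ignored.** The translation FASTA is the residue
  ground truth and residue 1 is assumed to start at coding phase 0.
  Transcripts whose summed CDS length is not divisible by 3 (incomplete
  5′/3′ CDS in real annotations) are retained with a warning; residue ranges
  past the last full codon are unmappable and such hits are skipped with a
  warning rather than mapped approximately.
* **Stop codons** are not part of the CDS (GENCODE convention), so protein
  length × 3 equals the coding length; no adjustment is made.
* **Chromosome names pass through verbatim** — no `chr` prefix
  normalization. The GTF, FASTA and browser assembly must be matching
  releases; when no FASTA identifier joins to any GTF `transcript_id` the
  run aborts with a configuration error instead of silently producing empty
  output. Versioned/unversioned identifiers (`ENST… .N`) are reconciled by
  stripping the version suffix on both sides.

## Peptide search

Proteins are indexed by exact k-mers (default k = 4; proteins shorter than k
are indexed under their full sequence). For an allowance of $m$ mismatches
the peptide is split into $m+1$ consecutive parts of near-equal length; by
the pigeonhole principle any occurrence within Hamming distance $m$ contains
at least one part matching exactly, so candidates are generated from exact
index lookups of the parts and verified by full Hamming comparison with
early termination. When the parts would be shorter than k — or under I/L
equivalence, where index seeds are no longer exact strings — the search
falls back to a direct scan of every protein: correctness over speed for
edge inputs. The allowance is hard-capped at 2 because the number of
candidate mappings (and memory) grows steeply beyond; the staged workflow
exists precisely to keep higher allowances confined to the peptides that
need them.

Residue conventions: `X`, `B`, `Z` and `U` in a protein never match any
peptide residue (always a mismatch) — conservative, avoiding spurious
mappings through ambiguity codes. Isoleucine and leucine are distinct by
default so that reference translations are matched literally; an
`il_equivalent` switch treats them as equal for the isobaric-pair case, at
direct-scan cost. The k-mer length and pruning are engineering choices
validated against the exhaustive-scan oracle, not tuned constants.

## Collapse and uniqueness

Per-transcript hits of one peptide whose genomic blocks, chromosome and
strand are identical collapse into a single locus whose transcript/gene sets
are the union — identical blocks on *opposite strands* remain distinct
events. Uniqueness is then a function of the peptide's complete mapping set:
more than one gene across all loci ⇒ `multi_gene` for every mapping of that
peptide; one gene and one transcript ⇒ `unique_transcript`; one gene,
several transcripts ⇒ `unique_gene`. Mismatch-stage mappings are classified
by the same rule; no separate variant tier is introduced, the mismatch count
is carried alongside instead. A peptide whose only protein hits lack a
coding transcript in the annotation is counted unmapped (there is no
coordinate basis), with a warning.

## Staged mapping

`staged_mapping` runs strictly increasing allowances (default `[0, 1]`,
optionally `[0, 1, 2]`); each stage maps only the peptides left unmapped by
all previous stages, via an order-preserving subtraction on plain sequences.
Invariants enforced in tests: mapped and unmapped records partition every
stage's input, and no peptide mapped at stage *i* reappears at any later
stage.

## Output encodings

* **BED12 score** — browsers expect 0–1000; spectral support is encoded as
  `min(1000, PSMs × 200)`, summed over samples. The factor is a convention
  of this package (configurable via `ColorScheme`), not a community
  standard.
* **Colors** — the three uniqueness tiers are red/black/grey as above;
  phospho thick blocks are red by convention. The remaining PTM palette
  (acetyl blue, oxidation green, methyl orange, ubi purple, teal fallback
  for unrecognized tags) is this package's documented choice; all values are
  overridable from a `key=r,g,b` config file.
* **PTM thick blocks** — for each (mapping, PTM type) the thick region
  covers the genomic codons from the first to the last modified residue of
  that type, computed through the same spliced transform. A BED line has a
  single thick interval, so a codon set split by a junction is drawn as its
  bounding interval clipped to the mapping span — a limitation of the
  format, not ambiguity of site localisation. Peptides never observed with a
  modification go to the `_noptm` file with a zero-width thick region; the
  two files partition the mapped peptides (a peptide seen both modified and
  unmodified across samples is treated as modified).
* **GCT v1.2** — one row per (mapping, block), so junction peptides appear
  once per exon part with identical per-sample quant values; sample columns
  follow first appearance in the input; missing (peptide, sample) cells are
  empty; duplicate row names get a `#k` suffix. Row names
  (`peptide@chrom:start-end(strand)`) and the gene-list description are this
  package's convention.
* **Track hub** — minimal valid stanzas (`type bigBed 12`, `itemRgb on`,
  `visibility dense`); sorted BED copies are placed next to the trackDb.
  Conversion to bigBed requires an external binary and is therefore an
  optional callable hook, disabled by default; when enabled the stanzas
  reference the `.bb` files it produces.
* All writers are byte-deterministic: mappings are emitted in
  (chrom, start, end, peptide, strand) order and no unordered container
  reaches the output path.

## Synthetic data generator

The generator emulates the mapping-relevant structure of a real
annotation: multi-exon genes on both strands (exons ≥ 20 nt, introns
50–300 nt, intergenic spacing ≥ 100 nt so multi-gene hits arise only where
planted or by genuine sequence coincidence), genes with two transcripts
sharing one CDS (exercising `unique_gene`), and duplicated genes with
identical coding sequence at a second locus (exercising `multi_gene`).
Coding sequence is drawn uniformly from the 61 sense codons of the standard
table (no selenocysteine), the genome elsewhere is uniform random
nucleotide; translations are written per transcript. Peptides of 7–25
residues are sampled as protein substrings; junction-spanning windows are
forced across a chosen exon boundary; variants substitute one residue and
are re-drawn until the result matches nothing exactly, guaranteeing they map
only at stage 1. PTM tags (mostly phospho, some acetyl/oxidation) are
attached to a configurable fraction of peptides; each peptide is observed in
one or two samples with random PSM counts (1–20) and quantitation
(uniform 0.1–10, 4 decimals).

Ground truth is *not* taken from the sampling bookkeeping: it is recomputed
by an exhaustive scan (exact occurrences for reference peptides, full
Hamming-1 scan for variants) plus an independent per-nucleotide coordinate
table, so accidental extra occurrences are part of the expected answer
rather than a source of flakiness. `validate_against_truth` compares stage,
locus sets, tiers and mismatch positions exactly.

What the generator does not emulate — identification error, missed
cleavages, realistic amino-acid composition, overlapping genes, incomplete
CDS phase — bounds what passing tests show: they demonstrate correctness of
the coordinate arithmetic, search, collapse/classification and serialisation
contracts, not robustness to annotation pathologies beyond those modelled.

## Verification design and problem sizes

The verification harness (tests and `scripts/acceptance.py`) checks the
coordinate transform against the per-nucleotide oracle on 1,000 random
transcripts (≤ 10 segments, ≤ 3 kb): exhaustively over all residue ranges
for transcripts of ≤ 30 codons, and over all single-codon ranges plus 100
random multi-codon ranges per larger transcript — enumerating every range of
every 1,000-codon transcript is quadratic and adds no coverage class beyond
these. The search is checked against an exhaustive Hamming scan on 50
random proteins (100–500 aa) × 500 peptides at allowances 0/1/2. The
end-to-end study uses 20 genes and 200 peptides (20 % junction-spanning,
10 % variants, 10 % modified). These sizes make the whole suite run in
well under a minute per property while exercising every code path; they are
the package's standard verification conditions, all seed-controlled.

## Known limitations

* No direct mapping against genome nucleotide sequence, and no novel-ORF
  discovery: peptides must occur (within the mismatch allowance) in the
  provided translations.
* No enzymatic-digest modeling, spectral matching or FDR — identification
  happens upstream.
* mzTab/mzIdentML ingestion is out of scope; the 4-column table and MaxQuant
  `peptides.txt` are the supported inputs.
* GFF3 is not supported (GTF only), and bigBed generation is delegated to an
  external tool via the optional hook.
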