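# pepmap

Map peptides identified by tandem mass spectrometry — together with their
post-translational modifications (PTMs), spectral counts and quantitation —
onto reference genome coordinates, and emit genome-browser-ready tracks.

Proteogenomics needs a shared coordinate system: transcript abundances,
variants and epigenomic signal live on the genome, while peptide evidence
lives on protein sequences. `pepmap` closes that gap for anyone who wants to
view or share MS evidence in IGV, the UCSC or Ensembl browsers: given a gene
annotation (GTF, GENCODE/Ensembl dialect) and the matching protein-coding
transcript translation sequences (FASTA), it locates each peptide within the
translations and transforms its residue coordinates through the spliced CDS
structure into genomic blocks.

## Method

For a peptide found at residues $a..b$ (1-based) of a transcript's
translation, the coding-nucleotide interval is $[3(a-1),\,3b)$ within the
concatenated CDS. Walking the transcript's CDS segments in translation order
(ascending genomic position on `+`, descending on `-`) projects that
interval onto genomic blocks, split at every exon/exon junction crossed —
so a junction-spanning peptide becomes a multi-block BED feature joined by
thin intron lines.

Peptide search uses an exact k-mer index over the protein database with
pigeonhole candidate generation for mismatches: a peptide within Hamming
distance $m$ of a protein substring must contain at least one of $m{+}1$
consecutive parts matching exactly; candidates from exact part lookups are
verified by full Hamming comparison. The mismatch allowance is capped at 2,
and the recommended workflow for variant peptides is *staged*: map exactly,
remove mapped peptides from the input, remap the remainder at 1 (then
optionally 2) mismatches.

Each peptide's complete mapping set is classified into a 3-tier uniqueness
code, carried as the BED `itemRgb` color:

| tier | meaning | color |
|---|---|---|
| `unique_transcript` | one transcript of one gene | red `255,0,0` |
| `unique_gene` | one gene, several transcripts | black `0,0,0` |
| `multi_gene` | shared between genes | grey `128,128,128` |

Outputs: BED12; a PTM-BED pair (`*_ptm.bed` with thick blocks covering the
genomic codons from the first to the last modified residue per PTM type,
`*_noptm.bed` for peptides never seen modified); GTF; GCT v1.2 with
per-sample quantitation, junction peptides split into one row per exon part;
and a UCSC track-hub scaffold (`hub.txt` → `genomes.txt` → `trackDb.txt`).

## Input format

A tab-separated table with header `Sample  Peptide  PSMs  Quant`
(`.txt`/`.tsv`/`.pogo`). PTMs are written inline as a parenthesised
lowercase tag after the modified residue, e.g. `GSNK(phospho)R`.
`pepmap maxquant-convert` unpivots a MaxQuant `peptides.txt` (pairing
`Experiment <name>` counts with `Ratio H/L normalized <name>` values) into
this format.

## Worked example

The built-in generator creates a complete synthetic study — genome,
annotation, translations and a peptide table with planted junction-spanning,
modified and variant peptides:

```python
from pepmap.fixtures import FixtureSpec, generate
from pepmap.annotation import parse_gtf
from pepmap.sequence_db import load_fasta, build_index
from pepmap.peptide_io import read_pogo_table
from pepmap.mapper import staged_mapping

fx = generate(FixtureSpec(seed=42, n_genes=20, n_peptides=200,
                          fraction_junction_spanning=0.2,
                          fraction_variant=0.1, fraction_modified=0.1), "demo")
annotation = parse_gtf(fx.gtf)
database = load_fasta(fx.protein_fasta)
index = build_index(database)
records = read_pogo_table(fx.peptide_table)
for mm, run in staged_mapping(records, database, index, annotation, [0, 1]):
    print(f"stage mm={mm}: mapped={len(run.mapped_plain_sequences)} "
          f"mappings={len(run.mappings)}")
```

prints

```
stage mm=0: mapped=180 mappings=207
stage mm=1: mapped=20 mappings=25
```

— the 180 reference peptides map exactly at stage 0 (207 genomic loci; some
peptides hit a duplicated gene twice), and the 20 planted single-substitution
variants map only at stage 1. The same run from the shell:

```bash
pepmap staged -gtf demo/annotation.gtf -fasta demo/proteins.fa \
    -in demo/peptides.pogo -format BED,PTMBED,GCT -out demo/out
```

A junction-spanning peptide in the resulting BED looks like

```
chr1  368  749  GALSETVDAEDTE  1000  -  368  749  128,128,128  3  5,33,1  0,207,380
```

three blocks (sizes `5,33,1` nt, 39 nt = 3 × 13 residues) joined across two
introns, grey because this peptide's sequence occurs in two genes.
`pepmap trackhub demo/out myhub hg38 me@lab.org demo/hub` then wraps the BED
files into a browser-loadable track hub.

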