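"""BED12, PTM-BED, GCT, GTF and track-hub serialisation."""

import io

import pytest

from pepmap.errors import PepmapError, TrackHubError
from pepmap.mapper import GenomicMapping, MappingRun, Uniqueness
from pepmap.peptide_io import PeptideRecord
from pepmap.writers import (
    ColorScheme,
    write_bed,
    write_gct,
    write_gtf,
    write_ptm_bed,
    write_track_hub,
)

from validators import (
    bed_names,
    validate_bed12_line,
    validate_gct_file,
    validate_track_hub,
)


def record(plain, modified=None, ptms=(), sample="S1", psms=1, quant=1.5):
    return PeptideRecord(sample, modified or plain, plain, tuple(ptms), psms, quant)


def make_mapping(
    peptide="ACDEFK",
    blocks=((1000, 1018),),
    tier=Uniqueness.UNIQUE_TRANSCRIPT,
    strand="+",
    records=None,
    chrom="chr1",
    n_mismatches=0,
):
    if records is None:
        records = (record(peptide),)
    return GenomicMapping(
        peptide=peptide,
        chrom=chrom,
        strand=strand,
        blocks=tuple(blocks),
        transcript_ids=frozenset({"T1"}),
        gene_ids=frozenset({"G1"}),
        uniqueness=tier,
        n_mismatches=n_mismatches,
        records=tuple(records),
    )


def run_of(*mappings, records=None):
    all_records = list(records or [r for m in mappings for r in m.records])
    return MappingRun(max_mismatches=0, mappings=list(mappings), records=all_records)


def render(writer, run, **kwargs):
    out = io.StringIO()
    writer(run, out, **kwargs)
    return out.getvalue()


class TestWriteBed:
    def test_single_block_unique_transcript_line(self):
        text = render(write_bed, run_of(make_mapping()))
        fields = text.strip().split("\t")
        assert fields == [
            "chr1", "1000", "1018", "ACDEFK", "200", "+", "1000", "1018",
            "255,0,0", "1", "18", "0",
        ]
        assert validate_bed12_line(text.strip()) == []

    def test_junction_mapping_block_bookkeeping(self):
        m = make_mapping(blocks=((1003, 1009), (2000, 2006)), tier=Uniqueness.UNIQUE_GENE)
        fields = render(write_bed, run_of(m)).strip().split("\t")
        assert fields[9:12] == ["2", "6,6", "0,997"]
        assert fields[8] == "0,0,0"

    def test_score_encodes_psms_and_saturates(self):
        m1 = make_mapping(records=(record("ACDEFK", psms=3),))
        m2 = make_mapping(records=(record("ACDEFK", psms=50),))
        assert render(write_bed, run_of(m1)).split("\t")[4] == "600"
        assert render(write_bed, run_of(m2)).split("\t")[4] == "1000"

    def test_multi_gene_grey_and_sorted_output(self):
        m_late = make_mapping(peptide="CCCCC", blocks=((5000, 5015),), tier=Uniqueness.MULTI_GENE)
        m_early = make_mapping(peptide="DDDDD", blocks=((100, 115),), tier=Uniqueness.MULTI_GENE)
        lines = render(write_bed, run_of(m_late, m_early)).splitlines()
        assert [l.split("\t")[3] for l in lines] == ["DDDDD", "CCCCC"]
        assert lines[0].split("\t")[8] == "128,128,128"

    def test_empty_run_empty_file(self):
        assert render(write_bed, run_of()) == ""

    def test_writers_are_deterministic(self, fixture_reference):
        from pepmap.mapper import map_all

        annotation, database, index, records = fixture_reference
        run = map_all(records, database, index, annotation, 0)
        assert render(write_bed, run) == render(write_bed, run)
        assert render(write_gct, run) == render(write_gct, run)


class TestWritePtmBed:
    def render_pair(self, run, scheme=None):
        ptm, noptm = io.StringIO(), io.StringIO()
        write_ptm_bed(run, ptm, noptm, scheme)
        return ptm.getvalue(), noptm.getvalue()

    def test_single_ptm_thick_covers_its_codon(self):
        m = make_mapping(
            peptide="ACDEFGHIKW",
            blocks=((1000, 1030),),
            records=(record("ACDEFGHIKW", ptms=[(4, "phospho")]),),
        )
        ptm, noptm = self.render_pair(run_of(m))
        fields = ptm.strip().split("\t")
        assert (fields[6], fields[7]) == ("1009", "1012")
        assert fields[8] == "255,0,0"
        assert noptm == ""

    def test_multiple_sites_span_first_to_last(self):
        m = make_mapping(
            peptide="ACDEFGHIKW",
            blocks=((1000, 1030),),
            records=(record("ACDEFGHIKW", ptms=[(2, "phospho"), (6, "phospho")]),),
        )
        ptm, _ = self.render_pair(run_of(m))
        lines = ptm.splitlines()
        assert len(lines) == 1
        fields = lines[0].split("\t")
        assert (fields[6], fields[7]) == ("1003", "1018")

    def test_two_ptm_types_two_lines_distinct_colors(self):
        m = make_mapping(
            peptide="ACDEFGHIKW",
            blocks=((1000, 1030),),
            records=(record("ACDEFGHIKW", ptms=[(2, "phospho"), (5, "acetyl")]),),
        )
        ptm, _ = self.render_pair(run_of(m))
        lines = ptm.splitlines()
        assert len(lines) == 2
        colors = {l.split("\t")[8] for l in lines}
        assert colors == {"255,0,0", "0,0,255"}

    def test_unmodified_peptides_get_zero_width_thick(self):
        ptm, noptm = self.render_pair(run_of(make_mapping()))
        assert ptm == ""
        fields = noptm.strip().split("\t")
        assert fields[6] == fields[7] == fields[1]

    def test_peptide_sets_partition(self, tmp_path):
        modified = make_mapping(
            peptide="ACDEFGHIKW",
            blocks=((1000, 1030),),
            records=(record("ACDEFGHIKW", ptms=[(1, "phospho")]),),
        )
        plain = make_mapping(peptide="CCDEFK", blocks=((2000, 2018),))
        ptm_path, noptm_path = tmp_path / "x_ptm.bed", tmp_path / "x_noptm.bed"
        write_ptm_bed(run_of(modified, plain), ptm_path, noptm_path)
        assert bed_names(ptm_path) & bed_names(noptm_path) == set()
        assert bed_names(ptm_path) | bed_names(noptm_path) == {"ACDEFGHIKW", "CCDEFK"}

    def test_junction_spanning_ptm_thick_clipped_to_span(self):
        # residue 3's codon straddles the junction: thick covers the bounding
        # interval, clipped into the mapping span
        m = make_mapping(
            peptide="ACDEFK",
            blocks=((1000, 1007), (2000, 2011)),
            records=(record("ACDEFK", ptms=[(3, "phospho")]),),
        )
        ptm, _ = self.render_pair(run_of(m))
        fields = ptm.strip().split("\t")
        thick_start, thick_end = int(fields[6]), int(fields[7])
        assert int(fields[1]) <= thick_start <= thick_end <= int(fields[2])
        assert thick_start == 1006 and thick_end == 2002
        assert validate_bed12_line(ptm.strip()) == []

    def test_minus_strand_ptm_codon_arithmetic(self):
        # minus strand: residue 1 sits at the genomic end of the span
        m = make_mapping(
            peptide="ACDEFGHIKW",
            blocks=((1000, 1030),),
            strand="-",
            records=(record("ACDEFGHIKW", ptms=[(1, "phospho")]),),
        )
        ptm, _ = self.render_pair(run_of(m))
        fields = ptm.strip().split("\t")
        assert (fields[6], fields[7]) == ("1027", "1030")

    def test_out_of_range_ptm_position_rejected(self):
        m = make_mapping(records=(record("ACDEFK", ptms=[(9, "phospho")]),))
        with pytest.raises(PepmapError, match="outside"):
            self.render_pair(run_of(m))


class TestWriteGct:
    def test_junction_peptide_split_into_exon_parts(self):
        m = make_mapping(
            peptide="ACDEFK",
            blocks=((1003, 1009), (2000, 2012)),
            records=(record("ACDEFK", sample="S1", quant=2.5),
                     record("ACDEFK", sample="S2", quant=0.5)),
        )
        lines = render(write_gct, run_of(m)).splitlines()
        assert lines[0] == "#1.2"
        assert lines[1] == "2\t2"
        assert lines[2] == "Name\tDescription\tS1\tS2"
        assert lines[3] == "ACDEFK@chr1:1003-1009(+)\tG1\t2.5\t0.5"
        assert lines[4] == "ACDEFK@chr1:2000-2012(+)\tG1\t2.5\t0.5"

    def test_missing_sample_left_empty_in_all_parts(self):
        m = make_mapping(
            peptide="ACDEFK",
            blocks=((1003, 1009), (2000, 2012)),
            records=(record("ACDEFK", sample="A", quant=1.0),),
        )
        run = run_of(m, records=[record("ACDEFK", sample="A", quant=1.0),
                                 record("ZZZZZZ", sample="B", quant=9.0)])
        lines = render(write_gct, run).splitlines()
        assert lines[2] == "Name\tDescription\tA\tB"
        assert lines[3].endswith("\t1\t") and lines[4].endswith("\t1\t")

    def test_empty_run_keeps_header(self):
        text = render(write_gct, run_of(records=[record("AAA", sample="S1")]))
        assert text.splitlines() == ["#1.2", "0\t1", "Name\tDescription\tS1"]

    def test_row_count_equals_total_blocks_and_file_validates(self, tmp_path):
        m1 = make_mapping(peptide="AAADDD", blocks=((10, 19), (30, 39)))
        m2 = make_mapping(peptide="CCCEEE", blocks=((100, 118),))
        path = tmp_path / "out.gct"
        write_gct(run_of(m1, m2), path)
        assert validate_gct_file(path) == []
        assert int(path.read_text().splitlines()[1].split("\t")[0]) == 3


class TestWriteGtf:
    def test_two_block_mapping_gives_three_lines(self):
        m = make_mapping(blocks=((1003, 1009), (2000, 2006)))
        lines = render(write_gtf, run_of(m)).splitlines()
        assert [l.split("\t")[2] for l in lines] == ["transcript", "exon", "exon"]

    def test_coordinates_round_trip_through_written_gtf(self):
        m = make_mapping(blocks=((1003, 1009), (2000, 2006)), strand="-")
        lines = render(write_gtf, run_of(m)).splitlines()
        exons = [l.split("\t") for l in lines if l.split("\t")[2] == "exon"]
        blocks = sorted((int(f[3]) - 1, int(f[4])) for f in exons)
        assert tuple(blocks) == m.blocks

    def test_attributes_carry_mapping_metadata(self):
        m = make_mapping(n_mismatches=1)
        attrs = render(write_gtf, run_of(m)).splitlines()[0].split("\t")[8]
        assert 'peptide "ACDEFK"' in attrs
        assert 'uniqueness "unique_transcript"' in attrs
        assert 'mismatches "1"' in attrs

    def test_empty_run_empty_file(self):
        assert render(write_gtf, run_of()) == ""


class TestColorScheme:
    def test_from_file_overrides(self, tmp_path):
        config = tmp_path / "colors.txt"
        config.write_text("uniqueness.multi_gene = 1,2,3\nptm.phospho = 9,9,9\n# comment\n")
        scheme = ColorScheme.from_file(config)
        assert scheme.uniqueness_rgb[Uniqueness.MULTI_GENE] == (1, 2, 3)
        assert scheme.ptm_color("phospho") == "9,9,9"
        assert scheme.uniqueness_rgb[Uniqueness.UNIQUE_TRANSCRIPT] == (255, 0, 0)

    def test_unknown_ptm_gets_fallback_color(self):
        assert ColorScheme().ptm_color("neverheardof") == "0,150,150"

    def test_invalid_rgb_rejected(self, tmp_path):
        config = tmp_path / "colors.txt"
        config.write_text("ptm.phospho = 300,0,0\n")
        with pytest.raises(PepmapError):
            ColorScheme.from_file(config)


class TestWriteTrackHub:
    @pytest.fixture
    def bed_dir(self, tmp_path):
        d = tmp_path / "beds"
        d.mkdir()
        line1 = "chr1\t100\t118\tPEP1\t200\t+\t100\t118\t255,0,0\t1\t18\t0\n"
        line2 = "chr1\t50\t68\tPEP2\t200\t+\t50\t68\t0,0,0\t1\t18\t0\n"
        (d / "proteome.bed").write_text(line1 + line2)
        (d / "phospho.bed").write_text(line1)
        return d

    def test_reference_chain_resolves(self, bed_dir, tmp_path):
        hub = tmp_path / "hub"
        write_track_hub(bed_dir, "myhub", "hg38", "me@lab.org", hub)
        assert validate_track_hub(hub) == []

    def test_one_stanza_per_bed_and_email(self, bed_dir, tmp_path):
        hub = tmp_path / "hub"
        write_track_hub(bed_dir, "myhub", "hg38", "me@lab.org", hub)
        trackdb = (hub / "hg38" / "trackDb.txt").read_text()
        assert trackdb.count("track ") == 2
        assert "email me@lab.org" in (hub / "hub.txt").read_text()

    def test_copied_beds_are_sorted(self, bed_dir, tmp_path):
        hub = tmp_path / "hub"
        write_track_hub(bed_dir, "myhub", "hg38", "me@lab.org", hub)
        starts = [
            int(l.split("\t")[1])
            for l in (hub / "hg38" / "proteome.bed").read_text().splitlines()
        ]
        assert starts == sorted(starts)

    def test_empty_dir_is_error(self, tmp_path):
        empty = tmp_path / "empty"
        empty.mkdir()
        with pytest.raises(TrackHubError, match="no BED"):
            write_track_hub(empty, "h", "hg38", "a@b.c", tmp_path / "hub")

    def test_invalid_assembly_rejected(self, bed_dir, tmp_path):
        with pytest.raises(TrackHubError, match="assembly"):
            write_track_hub(bed_dir, "h", "hg38/../evil", "a@b.c", tmp_path / "hub")

    def test_bigbed_hook_invoked_when_given(self, bed_dir, tmp_path):
        calls = []
        write_track_hub(
            bed_dir, "h", "hg38", "a@b.c", tmp_path / "hub",
            bed_to_bigbed=lambda bed, bb: calls.append((bed.name, bb.name)),
        )
        assert sorted(calls) == [("phospho.bed", "phospho.bb"), ("proteome.bed", "proteome.bb")]
        trackdb = (tmp_path / "hub" / "hg38" / "trackDb.txt").read_text()
        assert "bigDataUrl proteome.bb" in trackdb
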