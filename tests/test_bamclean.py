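"""Junction extraction from CIGARs, alignment cleanup, annotation scoring."""

import numpy as np
import pysam
import pytest

from splicesift.bamclean import (
    CleanupConfig,
    clean_alignments,
    extract_introns_gff,
    extract_junctions_bam,
    filter_annotation,
    score_junctions,
    transcript_junction_report,
)
from splicesift.encode import Genome, Junction


def _header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100_000}]}
    )


def _rec(header, name, pos, cigar, flag=0, nh=1, xs=None, mate_pos=None):
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.reference_id = 0
    rec.reference_start = pos
    rec.mapping_quality = 60
    rec.cigarstring = cigar
    length = sum(n for op, n in rec.cigartuples if op in (0, 1, 4))
    rec.query_sequence = "A" * length
    rec.flag = flag
    rec.set_tag("NH", nh)
    if xs:
        rec.set_tag("XS", xs)
    if mate_pos is not None:
        rec.next_reference_id = 0
        rec.next_reference_start = mate_pos
    return rec


def _write_sam(path, records):
    with pysam.AlignmentFile(str(path), "w", header=_header()) as fh:
        for r in records:
            fh.write(r)
    return path


class TestExtractJunctions:
    def test_cigar_walk(self, tmp_path):
        h = _header()
        sam = _write_sam(tmp_path / "a.sam", [_rec(h, "r1", 1000, "50M200N50M", xs="+")])
        (j,) = extract_junctions_bam(sam)
        assert (j.start, j.end, j.support, j.strand) == (1050, 1250, 1, "+")

    def test_shared_junction_support_two(self, tmp_path):
        h = _header()
        sam = _write_sam(
            tmp_path / "a.sam",
            [_rec(h, "r1", 1000, "50M200N50M", xs="+"),
             _rec(h, "r2", 980, "70M200N30M", xs="+")],
        )
        (j,) = extract_junctions_bam(sam)
        assert j.support == 2

    def test_unspliced_read_yields_nothing(self, tmp_path):
        sam = _write_sam(tmp_path / "a.sam", [_rec(_header(), "r1", 1000, "100M")])
        assert extract_junctions_bam(sam) == []

    def test_multiple_n_ops_in_one_read(self, tmp_path):
        h = _header()
        sam = _write_sam(tmp_path / "a.sam", [_rec(h, "r1", 100, "20M50N30M70N50M")])
        keys = [(j.start, j.end) for j in extract_junctions_bam(sam)]
        assert keys == [(120, 170), (200, 270)]

    def test_strand_from_motif_when_no_xs(self, tmp_path):
        seq = list("A" * 2000)
        seq[1050:1052] = "GT"
        seq[1248:1250] = "AG"
        genome = Genome.from_dict({"chr1": "".join(seq)})
        sam = _write_sam(tmp_path / "a.sam", [_rec(_header(), "r1", 1000, "50M200N50M")])
        (j,) = extract_junctions_bam(sam, genome=genome)
        assert j.strand == "+"

    def test_unknown_motif_is_unstranded(self, tmp_path):
        genome = Genome.from_dict({"chr1": "A" * 2000})
        sam = _write_sam(tmp_path / "a.sam", [_rec(_header(), "r1", 1000, "50M200N50M")])
        (j,) = extract_junctions_bam(sam, genome=genome)
        assert j.strand == "."


class TestScoreJunctions:
    def test_empty_input(self, tiny_model):
        scored, missing = score_junctions(tiny_model, Genome.from_dict({"c": "ACGT" * 500}), [])
        assert scored == [] and missing == []

    def test_unknown_chromosome_is_unscorable(self, tiny_model):
        genome = Genome.from_dict({"c": "ACGT" * 2000})
        junctions = [Junction("c", 2000, 2500, "+"), Junction("zz", 10, 400, "+")]
        scored, missing = score_junctions(tiny_model, genome, junctions)
        assert len(scored) == 1 and len(missing) == 1

    def test_order_invariance_and_determinism(self, tiny_model):
        genome = Genome.from_dict({"c": "ACGT" * 2500})
        junctions = [Junction("c", 2000 + 37 * i, 2400 + 41 * i, "+") for i in range(5)]
        a, _ = score_junctions(tiny_model, genome, junctions)
        b, _ = score_junctions(tiny_model, genome, junctions[::-1])
        by_key = {s.junction.key: (s.donor, s.acceptor) for s in b}
        for s in a:
            assert by_key[s.junction.key] == (s.donor, s.acceptor)
        a2, _ = score_junctions(tiny_model, genome, junctions)
        assert [(s.donor, s.acceptor) for s in a] == [(s.donor, s.acceptor) for s in a2]

    def test_unstranded_scored_both_orientations(self, tiny_model):
        genome = Genome.from_dict({"c": "ACGT" * 2500})
        scored, _ = score_junctions(tiny_model, genome, [Junction("c", 2000, 2500, ".")])
        plus, _ = score_junctions(tiny_model, genome, [Junction("c", 2000, 2500, "+")])
        minus, _ = score_junctions(tiny_model, genome, [Junction("c", 2000, 2500, "-")])
        assert scored[0].junction_score == pytest.approx(
            max(plus[0].junction_score, minus[0].junction_score)
        )


class TestCleanAlignments:
    def _setup(self, tmp_path):
        h = _header()
        records = [
            # paired read whose first mate crosses the spurious junction
            _rec(h, "p1", 1000, "50M200N50M", flag=0x1 | 0x2 | 0x20 | 0x40, xs="+",
                 mate_pos=1400),
            _rec(h, "p1", 1400, "100M", flag=0x1 | 0x2 | 0x10 | 0x80, mate_pos=1000),
            # multimapped read: one of three alignments crosses the junction
            _rec(h, "m1", 1020, "30M200N70M", nh=3, xs="+"),
            _rec(h, "m1", 5000, "100M", flag=0x100, nh=3),
            _rec(h, "m1", 7000, "100M", flag=0x100, nh=3),
            # clean spliced read over a good junction
            _rec(h, "g1", 2000, "40M300N60M", xs="+"),
        ]
        sam = _write_sam(tmp_path / "in.sam", records)
        spurious = {("chr1", 1050, 1250)}
        return sam, spurious

    def test_counts_conserve_and_spurious_removed(self, tmp_path):
        sam, spurious = self._setup(tmp_path)
        report = clean_alignments(sam, spurious, tmp_path / "kept.sam", tmp_path / "disc.sam")
        assert report.kept + report.discarded == 6
        assert report.discarded == 2
        kept_junctions = {j.interval for j in extract_junctions_bam(tmp_path / "kept.sam")}
        assert ("chr1", 1050, 1250) not in kept_junctions
        assert ("chr1", 2040, 2340) in kept_junctions

    def test_mate_is_unpaired(self, tmp_path):
        sam, spurious = self._setup(tmp_path)
        clean_alignments(sam, spurious, tmp_path / "kept.sam", tmp_path / "disc.sam")
        with pysam.AlignmentFile(str(tmp_path / "kept.sam")) as fh:
            mate = next(r for r in fh if r.query_name == "p1")
        assert not mate.is_paired and not mate.is_proper_pair
        assert mate.next_reference_id == -1 and mate.next_reference_start == -1

    def test_nh_decremented_on_survivors(self, tmp_path):
        sam, spurious = self._setup(tmp_path)
        report = clean_alignments(sam, spurious, tmp_path / "kept.sam", tmp_path / "disc.sam")
        with pysam.AlignmentFile(str(tmp_path / "kept.sam")) as fh:
            nh = [r.get_tag("NH") for r in fh if r.query_name == "m1"]
        assert nh == [2, 2]
        assert report.nh_updates == 2

    def test_passing_alignments_unchanged(self, tmp_path):
        sam, spurious = self._setup(tmp_path)
        clean_alignments(sam, spurious, tmp_path / "kept.sam", tmp_path / "disc.sam")
        with pysam.AlignmentFile(str(tmp_path / "kept.sam")) as fh:
            g1 = next(r for r in fh if r.query_name == "g1")
        assert g1.cigarstring == "40M300N60M" and g1.flag == 0 and g1.get_tag("NH") == 1

    def test_discarded_preserved_verbatim(self, tmp_path):
        sam, spurious = self._setup(tmp_path)
        clean_alignments(sam, spurious, tmp_path / "kept.sam", tmp_path / "disc.sam")
        with pysam.AlignmentFile(str(tmp_path / "disc.sam")) as fh:
            recs = list(fh)
        assert sorted(r.query_name for r in recs) == ["m1", "p1"]
        p1 = next(r for r in recs if r.query_name == "p1")
        assert p1.is_paired and p1.cigarstring == "50M200N50M"  # untouched

    def test_kept_output_sorted(self, tmp_path):
        sam, spurious = self._setup(tmp_path)
        clean_alignments(sam, spurious, tmp_path / "kept.sam", tmp_path / "disc.sam")
        with pysam.AlignmentFile(str(tmp_path / "kept.sam")) as fh:
            assert fh.header.to_dict()["HD"]["SO"] == "coordinate"
            pos = [r.reference_start for r in fh]
        assert pos == sorted(pos)

    def test_missing_mate_counted(self, tmp_path):
        h = _header()
        sam = _write_sam(
            tmp_path / "in.sam",
            [_rec(h, "p1", 1000, "50M200N50M", flag=0x1 | 0x40, xs="+", mate_pos=9999)],
        )
        report = clean_alignments(
            sam, {("chr1", 1050, 1250)}, tmp_path / "kept.sam", tmp_path / "disc.sam"
        )
        assert report.discarded == 1 and report.missing_mates == 1


GFF = """##gff-version 3
chr1\tsrc\tgene\t1\t1000\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=t_plus;Parent=g1
chr1\tsrc\texon\t101\t200\t.\t+\t.\tID=t_plus.e1;Parent=t_plus
chr1\tsrc\texon\t301\t400\t.\t+\t.\tID=t_plus.e2;Parent=t_plus
chr1\tsrc\tgene\t1\t1000\t.\t-\t.\tID=g2
chr1\tsrc\tmRNA\t101\t400\t.\t-\t.\tID=t_minus;Parent=g2
chr1\tsrc\texon\t301\t400\t.\t-\t.\tID=t_minus.e1;Parent=t_minus
chr1\tsrc\texon\t101\t200\t.\t-\t.\tID=t_minus.e2;Parent=t_minus
chr1\tsrc\tgene\t1\t2000\t.\t+\t.\tID=g3
chr1\tsrc\tmRNA\t501\t600\t.\t+\t.\tID=t_single;Parent=g3
chr1\tsrc\texon\t501\t600\t.\t+\t.\tID=t_single.e1;Parent=t_single
chr1\tsrc\tmRNA\t701\t1000\t.\t+\t.\tID=t_overlap;Parent=g3
chr1\tsrc\texon\t701\t850\t.\t+\t.\tID=t_overlap.e1;Parent=t_overlap
chr1\tsrc\texon\t800\t1000\t.\t+\t.\tID=t_overlap.e2;Parent=t_overlap
"""


class TestAnnotationSide:
    @pytest.fixture()
    def gff(self, tmp_path):
        path = tmp_path / "ann.gff3"
        path.write_text(GFF)
        return path

    def test_intron_extraction(self, gff):
        with pytest.warns(UserWarning):
            junctions, table = extract_introns_gff(gff)
        by_tx = {j.name: j for j in junctions}
        # 0-based half-open introns between exons [100,200) and [300,400)
        assert (by_tx["t_plus"].start, by_tx["t_plus"].end) == (200, 300)
        assert (by_tx["t_minus"].start, by_tx["t_minus"].end) == (200, 300)
        assert "t_single" not in by_tx          # single-exon: nothing
        assert "t_overlap" not in by_tx         # overlapping exons: filtered
        assert set(table["intron_num"]) == {1}

    def test_minus_strand_intron_numbering(self, tmp_path):
        lines = ["##gff-version 3",
                 "chr1\ts\tgene\t1\t2000\t.\t-\t.\tID=g",
                 "chr1\ts\tmRNA\t101\t1100\t.\t-\t.\tID=t;Parent=g"]
        for i, (s, e) in enumerate([(101, 200), (401, 500), (1001, 1100)]):
            lines.append(f"chr1\ts\texon\t{s}\t{e}\t.\t-\t.\tID=t.e{i};Parent=t")
        path = tmp_path / "m.gff3"
        path.write_text("\n".join(lines) + "\n")
        _, table = extract_introns_gff(path)
        # transcription order on '-' runs right to left: first intron is rightmost
        first = table[table["intron_num"] == 1].iloc[0]
        assert (first["start"], first["end"]) == (500, 1000)

    def test_transcript_report_ratios(self):
        introns = {
            "keep": [Junction("c", i * 100, i * 100 + 50, "+") for i in range(1, 5)],
            "drop": [Junction("c", i * 100, i * 100 + 50, "+") for i in range(11, 15)],
            "single": [],
        }
        scores = {j.interval: 0.9 for j in introns["keep"]}
        scores[introns["keep"][0].interval] = 0.01          # 1 of 4 bad -> ratio 0.25
        scores.update({j.interval: 0.01 for j in introns["drop"][:3]})
        scores[introns["drop"][3].interval] = 0.9           # 3 of 4 bad -> ratio 0.75
        report, kept = transcript_junction_report(introns, scores,
                                                  score_threshold=0.1, bad_ratio_threshold=0.5)
        assert kept == {"keep", "single"}
        rows = report.set_index("transcript_id")
        assert rows.loc["keep", "ratio"] == pytest.approx(0.25)
        assert rows.loc["drop", "ratio"] == pytest.approx(0.75)
        assert rows.loc["single", "ratio"] == 0.0

    def test_filter_annotation_drops_transcript_children(self, gff, tmp_path):
        out = tmp_path / "filtered.gff3"
        filter_annotation(gff, {"t_plus", "t_single", "t_overlap"}, out)
        text = out.read_text()
        assert "ID=t_minus;" not in text and "Parent=t_minus" not in text
        assert "ID=t_plus;" in text and "Parent=t_plus" in text
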