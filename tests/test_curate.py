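"""Dataset curation: selection rules, random negatives, composition stats."""

import numpy as np
import pytest

from splicesift import curate
from splicesift.curate import (
    CurationConfig,
    GeneLocus,
    SimilarityRecord,
    chromosome_split,
    dinucleotide_tally,
    generate_negative_random,
    paralog_filter,
    position_information_content,
    select_negative_1,
    select_novel,
    select_positive,
)
from splicesift.encode import Genome, Junction, extract_window


LOCUS = GeneLocus("chr2", 1000, 9000, "+", "g1")


def _j(start=2000, end=3000, strand="+", support=150, chrom="chr2"):
    return Junction(chrom, start, end, strand, support)


class TestSelectPositive:
    def test_supported_annotated_junction_is_primary(self):
        j = _j(support=150)
        pos, alt = select_positive([j], [_j(support=0)], [], [LOCUS])
        assert [p.key for p in pos] == [j.key] and not alt
        assert pos[0].source == "positive-mane"

    def test_below_threshold_excluded(self):
        pos, alt = select_positive([_j(support=99)], [_j(support=0)], [], [LOCUS])
        assert not pos and not alt

    def test_at_threshold_included(self):
        pos, _ = select_positive([_j(support=100)], [_j(support=0)], [], [LOCUS])
        assert len(pos) == 1

    def test_alt_only_junction_labeled_alt(self):
        j = _j(support=150)
        pos, alt = select_positive([j], [], [_j(support=0)], [LOCUS])
        assert not pos and [a.key for a in alt] == [j.key]
        assert alt[0].source == "positive-alt"

    def test_outside_coding_locus_excluded(self):
        j = _j(start=20000, end=21000)
        pos, alt = select_positive([j], [Junction("chr2", 20000, 21000, "+")], [], [LOCUS])
        assert not pos and not alt

    def test_empty_annotation_warns(self):
        with pytest.warns(UserWarning):
            pos, alt = select_positive([_j()], [], [], [LOCUS])
        assert not pos and not alt


class TestSelectNegative1:
    def test_opposite_strand_single_support_selected(self):
        j = _j(strand="-", support=1)
        out = select_negative_1([j], [LOCUS])
        assert [n.key for n in out] == [j.key]
        assert out[0].source == "negative-1"

    def test_support_two_excluded(self):
        assert not select_negative_1([_j(strand="-", support=2)], [LOCUS])

    def test_same_strand_excluded(self):
        assert not select_negative_1([_j(strand="+", support=1)], [LOCUS])

    def test_disjoint_from_positives(self):
        junctions = [
            _j(start=2000 + 10 * i, strand="-", support=s)
            for i, s in enumerate((1, 1, 50, 150, 200))
        ]
        pos, _ = select_positive(junctions, junctions, [], [LOCUS])
        neg = select_negative_1(junctions, [LOCUS])
        assert pos and neg
        assert not ({p.key for p in pos} & {n.key for n in neg})


@pytest.fixture(scope="module")
def setting():
    rng = np.random.default_rng(3)
    seqs = {"chr2": "".join(rng.choice(list("ACGT"), size=30_000))}
    genome = Genome.from_dict(seqs)
    loci = [GeneLocus("chr2", 2000, 25_000, "+", "g1")]
    cfg = CurationConfig(random_intron_range=(200, 2000), attempts_per_locus=40)
    return genome, loci, cfg


class TestNegativeRandom:

    def test_windows_are_canonical(self, setting):
        genome, loci, cfg = setting
        out = generate_negative_random(genome, loci, cfg, seed=5)
        assert out
        for j in out:
            w = extract_window(genome, j)
            assert w[200:202] == "GT" and w[598:600] == "AG"

    def test_strand_is_opposite_and_length_at_least_200(self, setting):
        genome, loci, cfg = setting
        out = generate_negative_random(genome, loci, cfg, seed=5)
        assert all(j.strand == "-" for j in out)
        assert all(j.length >= 200 for j in out)

    def test_deterministic_given_seed(self, setting):
        genome, loci, cfg = setting
        a = generate_negative_random(genome, loci, cfg, seed=5)
        b = generate_negative_random(genome, loci, cfg, seed=5)
        assert [j.key for j in a] == [j.key for j in b]

    def test_avoids_annotated_sites_exhaustively(self, bundle):
        out = generate_negative_random(
            bundle.genome, bundle.gene_loci,
            CurationConfig(random_intron_range=(200, 2000)),
            seed=6, annotated_junctions=bundle.true_junctions,
        )
        assert out
        donors = {(j.chrom, j.start) for j in bundle.true_junctions}
        acceptors = {(j.chrom, j.end) for j in bundle.true_junctions}
        for j in out:
            assert (j.chrom, j.start) not in donors
            assert (j.chrom, j.end) not in acceptors

    def test_tiny_locus_yields_nothing(self, setting):
        genome, _, cfg = setting
        out = generate_negative_random(genome, [GeneLocus("chr2", 100, 160, "+")], cfg, seed=1)
        assert out == []


class TestNovel:
    ANNOT = [_j(5000, 5500, support=0)]

    def test_matching_support_level_included(self):
        out = select_novel([_j(support=50)], self.ANNOT, level=50)
        assert len(out) == 1 and out[0].source == "novel-50"

    def test_annotated_excluded(self):
        assert not select_novel([_j(5000, 5500, support=50)], self.ANNOT, level=50)

    def test_wrong_level_excluded(self):
        assert not select_novel([_j(support=50)], self.ANNOT, level=100)


class TestSplit:
    def test_holdout_partition_is_exact(self):
        junctions = [_j(chrom=c, support=1) for c in ("chr1", "chr2", "chr9", "chr12")]
        train, test = chromosome_split(junctions, {"chr1", "chr9"})
        assert {j.chrom for j in test} == {"chr1", "chr9"}
        assert {j.chrom for j in train} == {"chr2", "chr12"}
        assert sorted(j.key for j in train + test) == sorted(j.key for j in junctions)


class TestParalogFilter:
    T2J = {"tx1": [_j(2000, 3000)], "tx2": [_j(4000, 4500)]}

    def test_high_identity_high_coverage_removed(self):
        recs = [SimilarityRecord("tx1", "train_tx", 85.0, 60.0)]
        out = paralog_filter([_j(2000, 3000), _j(4000, 4500)], recs, self.T2J)
        assert [j.start for j in out] == [4000]

    def test_low_coverage_kept(self):
        recs = [SimilarityRecord("tx1", "train_tx", 85.0, 40.0)]
        out = paralog_filter([_j(2000, 3000)], recs, self.T2J)
        assert len(out) == 1

    def test_no_records_identity(self):
        inp = [_j(2000, 3000)]
        assert paralog_filter(inp, [], self.T2J) == inp


class TestInformationContent:
    def test_conserved_position_is_two_bits(self):
        ic = position_information_content(["G", "G", "G", "G"])
        assert ic[0] == pytest.approx(2.0)

    def test_uniform_position_is_zero_bits(self):
        ic = position_information_content(["A", "C", "G", "T"])
        assert ic[0] == pytest.approx(0.0)

    def test_two_base_position_is_one_bit(self):
        ic = position_information_content(["AT", "TA", "AT", "TA"])
        np.testing.assert_allclose(ic, 1.0)

    def test_all_n_position_is_missing(self):
        ic = position_information_content(["N", "N"])
        assert np.isnan(ic[0])

    def test_bounded_in_0_2(self):
        rng = np.random.default_rng(4)
        windows = ["".join(rng.choice(list("ACGTN"), size=30)) for _ in range(40)]
        ic = position_information_content(windows)
        ok = ~np.isnan(ic)
        assert (ic[ok] >= -1e-9).all() and (ic[ok] <= 2 + 1e-9).all()

    def test_positive_windows_show_consensus_enrichment(self, bundle):
        """Boundary positions of real junctions carry high information;
        random GT-AG negatives carry none beyond the forced dinucleotides."""
        pos_windows = [extract_window(bundle.genome, j) for j in bundle.true_junctions]
        neg = generate_negative_random(
            bundle.genome, bundle.gene_loci,
            CurationConfig(random_intron_range=(200, 2000)),
            seed=9, annotated_junctions=bundle.true_junctions,
        )
        neg_windows = [extract_window(bundle.genome, j) for j in neg]
        ic_pos = position_information_content(pos_windows)
        ic_neg = position_information_content(neg_windows)
        flank = list(range(80, 180))
        boundary = [200, 201, 598, 599]
        assert ic_pos[boundary].mean() > ic_pos[flank].mean() + 1.0
        # negatives: forced GT/AG aside, no consensus anywhere
        consensus_neighbors = [203, 204, 205, 206]
        assert ic_pos[consensus_neighbors].mean() > 0.25
        assert ic_neg[consensus_neighbors].mean() < 0.15
        assert ic_neg[flank].mean() < 0.1


class TestDinucleotideTally:
    def test_canonical_toy_set(self, bundle):
        tally = dinucleotide_tally(bundle.true_junctions[:10], bundle.genome)
        assert tally["donor"]["GT"] == 10
        assert tally["acceptor"]["AG"] == 10

    def test_noncanonical_donor_counted(self):
        genome = Genome.from_dict({"c": "A" * 300 + "TT" + "A" * 296 + "AG" + "A" * 300})
        tally = dinucleotide_tally([Junction("c", 300, 600, "+")], genome)
        assert tally["donor"]["TT"] == 1
        assert tally["acceptor"]["AG"] == 1

    def test_totals_match_junction_count(self, bundle):
        tally = dinucleotide_tally(bundle.true_junctions, bundle.genome)
        n = len(bundle.true_junctions)
        assert sum(tally["donor"].values()) == n
        assert sum(tally["acceptor"].values()) == n
        assert curate.canonical_fraction(tally) == {"donor": 1.0, "acceptor": 1.0}
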