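"""Curation of positive / negative / novel junction datasets.

Positives are alignment-supported annotated junctions inside protein-coding
loci (>= 100 supporting alignments by default), split into a primary set
(present in the primary annotation) and an alternative set (present only in
the secondary annotation).  Negatives come in two flavors: junctions with a
single supporting alignment on the strand opposite a protein-coding gene
("negative-1"), and random GT-AG pairs searched on the strand opposite a
gene locus ("negative-random").  Novel-k sets collect unannotated junctions
at a given support level and are used for evaluation only.

Also provides the chromosome-holdout train/test split, the paralog filter
applied to held-out junctions, and composition diagnostics (per-position
information content in bits, donor/acceptor dinucleotide tallies).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .encode import Genome, Junction, extract_window, reverse_complement

__all__ = [
    "CurationConfig",
    "GeneLocus",
    "SimilarityRecord",
    "select_positive",
    "select_negative_1",
    "generate_negative_random",
    "select_novel",
    "chromosome_split",
    "paralog_filter",
    "assemble_training_set",
    "position_information_content",
    "dinucleotide_tally",
]


@dataclass
class CurationConfig:
    min_positive_support: int = 100
    negative1_support: int = 1
    novel_levels: list[int] = field(default_factory=lambda: list(range(2, 101)))
    random_intron_range: tuple[int, int] = (200, 20000)
    attempts_per_locus: int = 20
    holdout_chroms: frozenset = frozenset({"chr1", "chr9"})
    paralog_identity: float = 0.80
    paralog_query_coverage: float = 0.50
    positive_negative_ratio: float = 2.0  # negatives per positive in training

    def __post_init__(self):
        if self.min_positive_support < 1:
            raise ValueError("min_positive_support must be >= 1")
        if self.random_intron_range[0] < 2:
            raise ValueError("random intron minimum must be >= 2")
        if self.positive_negative_ratio <= 0:
            raise ValueError("ratio must be positive")


@dataclass(frozen=True)
class GeneLocus:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str = "."

    def contains(self, j: Junction) -> bool:
        return j.chrom == self.chrom and j.start >= self.start and j.end <= self.end

    def overlaps(self, j: Junction) -> bool:
        return j.chrom == self.chrom and j.start < self.end and j.end > self.start


@dataclass(frozen=True)
class SimilarityRecord:
    """One whole-transcript alignment hit (identity/coverage in percent)."""

    query_id: str
    subject_id: str
    identity: float
    query_coverage: float

    def __post_init__(self):
        for v in (self.identity, self.query_coverage):
            if not 0 <= v <= 100:
                raise ValueError("identity and coverage are percentages in [0, 100]")


def _relabel(j: Junction, source: str) -> Junction:
    return Junction(j.chrom, j.start, j.end, j.strand, j.support, source, j.name)


def select_positive(aligned_junctions, primary_introns, alt_introns, gene_loci,
                    config: CurationConfig | None = None):
    """Split well-supported annotated junctions in coding loci into
    (positive-primary, positive-alt)."""
    config = config or CurationConfig()
    primary = {j.key for j in primary_introns}
    alt = {j.key for j in alt_introns}
    if not primary and not alt:
        warnings.warn("empty annotation: no positive junctions can be selected")
        return [], []
    loci_by_chrom: dict[str, list[GeneLocus]] = {}
    for g in gene_loci:
        loci_by_chrom.setdefault(g.chrom, []).append(g)
    pos_primary, pos_alt = [], []
    for j in aligned_junctions:
        if j.support < config.min_positive_support:
            continue
        if not any(g.contains(j) for g in loci_by_chrom.get(j.chrom, ())):
            continue
        if j.key in primary:
            pos_primary.append(_relabel(j, "positive-mane"))
        elif j.key in alt:
            pos_alt.append(_relabel(j, "positive-alt"))
    return pos_primary, pos_alt


def select_negative_1(aligned_junctions, gene_loci, config: CurationConfig | None = None):
    """Single-alignment junctions on the strand opposite an overlapping gene."""
    config = config or CurationConfig()
    loci_by_chrom: dict[str, list[GeneLocus]] = {}
    for g in gene_loci:
        loci_by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for j in aligned_junctions:
        if j.support != config.negative1_support or j.strand not in "+-":
            continue
        opposite = any(
            g.overlaps(j) and g.strand != j.strand for g in loci_by_chrom.get(j.chrom, ())
        )
        if opposite:
            out.append(_relabel(j, "negative-1"))
    return out


def generate_negative_random(genome: Genome, gene_loci, config: CurationConfig | None = None,
                             seed: int = 0, annotated_junctions=None,
                             aligned_junctions=None):
    """Random GT-AG junctions on the strand opposite each gene locus.

    Per locus, up to ``attempts_per_locus`` attempts: pick a random start in
    the locus, scan forward to the first canonical donor dinucleotide (GT on
    the + junction strand, i.e. a literal "GT" when scanning the forward
    genome strand, "CT" when the junction strand is -), jump forward by a
    random intron length drawn from ``random_intron_range``, then scan
    forward to the first acceptor dinucleotide (AG, respectively "AC").
    Failed scans abort the attempt.  Junctions touching an annotated splice
    site, or with any alignment support, are rejected.
    """
    config = config or CurationConfig()
    rng = np.random.default_rng(seed)
    lo, hi = config.random_intron_range

    donor_sites, acceptor_sites = set(), set()
    for j in annotated_junctions or ():
        donor_sites.add((j.chrom, j.start))
        acceptor_sites.add((j.chrom, j.end))
    supported = {j.interval for j in aligned_junctions or ()}

    out = []
    seen = set()
    for locus in gene_loci:
        seq = genome.fetch(locus.chrom, locus.start, locus.end)
        strand = "-" if locus.strand == "+" else "+"
        head, tail = ("GT", "AG") if strand == "+" else ("CT", "AC")
        for _ in range(config.attempts_per_locus):
            pos = int(rng.integers(0, max(len(seq) - 1, 1)))
            d = seq.find(head, pos)
            if d < 0:
                continue
            length = int(rng.integers(lo, hi + 1))
            a = seq.find(tail, d + length)
            if a < 0:
                continue
            start = locus.start + d
            end = locus.start + a + 2
            if (locus.chrom, start) in donor_sites or (locus.chrom, end) in acceptor_sites:
                continue
            if (locus.chrom, start, end) in supported:
                continue
            key = (locus.chrom, start, end, strand)
            if key in seen:
                continue
            seen.add(key)
            out.append(Junction(locus.chrom, start, end, strand, 0, "negative-random"))
    return out


def select_novel(aligned_junctions, annotation_introns, level: int):
    """Unannotated junctions with exactly ``level`` supporting alignments."""
    if level < 2:
        raise ValueError("novel support levels start at 2")
    annotated = {j.key for j in annotation_introns}
    annotated_any = {(c, s, e) for c, s, e, _ in annotated}
    return [
        _relabel(j, f"novel-{level}")
        for j in aligned_junctions
        if j.support == level and j.key not in annotated and j.interval not in annotated_any
    ]


def chromosome_split(junctions, holdout_chroms=frozenset({"chr1", "chr9"})):
    """Exact disjoint partition into (train, test) by chromosome holdout."""
    train = [j for j in junctions if j.chrom not in holdout_chroms]
    test = [j for j in junctions if j.chrom in holdout_chroms]
    return train, test


def paralog_filter(test_junctions, similarity_records, transcript_to_junctions,
                   config: CurationConfig | None = None):
    """Drop held-out junctions whose transcript is near-identical to a
    training-side transcript (> 80% identity and > 50% query coverage)."""
    config = config or CurationConfig()
    bad_transcripts = {
        r.query_id
        for r in similarity_records
        if r.identity > 100 * config.paralog_identity
        and r.query_coverage > 100 * config.paralog_query_coverage
    }
    bad_keys = set()
    for tid in bad_transcripts:
        for j in transcript_to_junctions.get(tid, ()):
            bad_keys.add(j.key if isinstance(j, Junction) else tuple(j))
    return [j for j in test_junctions if j.key not in bad_keys]


def assemble_training_set(positives, negative_1, negative_random,
                          config: CurationConfig | None = None, seed: int = 0):
    """Sample a training set at the configured positive:negative ratio.

    Negatives are drawn equally from the two negative pools; if one pool is
    short, the other tops up the difference.  Sampling is seeded and without
    replacement within each pool.
    """
    config = config or CurationConfig()
    rng = np.random.default_rng(seed)
    positives = list(positives)
    n_neg = int(round(len(positives) * config.positive_negative_ratio))
    pools = [list(negative_1), list(negative_random)]
    want = [n_neg // 2, n_neg - n_neg // 2]
    for i in (0, 1):
        if want[i] > len(pools[i]):
            want[1 - i] += want[i] - len(pools[i])
            want[i] = len(pools[i])
    chosen = []
    for pool, w in zip(pools, want):
        w = min(w, len(pool))
        idx = rng.choice(len(pool), size=w, replace=False) if w else []
        chosen.extend(pool[k] for k in idx)
    return positives, chosen


# ---------------------------------------------------------------------------
# composition diagnostics


def position_information_content(windows) -> np.ndarray:
    """Per-position information content in bits over {A,C,G,T}.

    0 bits = uniform composition, 2 bits = a single base dominates.  N and
    other characters are excluded from the counts; positions with no
    informative observations are reported as NaN.
    """
    windows = list(windows)
    if not windows:
        return np.zeros(0)
    length = len(windows[0])
    if any(len(w) != length for w in windows):
        raise ValueError("windows must have equal length")
    mat = np.frombuffer("".join(windows).encode("ascii"), dtype=np.uint8).reshape(len(windows), length)
    counts = np.zeros((4, length))
    for i, b in enumerate("ACGT"):
        counts[i] = (mat == ord(b)).sum(axis=0)
    total = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / total
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    ic[total == 0] = np.nan
    return ic


def dinucleotide_tally(junctions, genome: Genome) -> dict[str, Counter]:
    """Counts of donor (first two intron bases) and acceptor (last two)
    dinucleotides in transcript orientation."""
    tally = {"donor": Counter(), "acceptor": Counter()}
    for j in junctions:
        if j.strand == "-":
            donor = reverse_complement(genome.fetch(j.chrom, j.end - 2, j.end))
            acceptor = reverse_complement(genome.fetch(j.chrom, j.start, j.start + 2))
        else:
            donor = genome.fetch(j.chrom, j.start, j.start + 2)
            acceptor = genome.fetch(j.chrom, j.end - 2, j.end)
        tally["donor"][donor] += 1
        tally["acceptor"][acceptor] += 1
    return tally


def canonical_fraction(tally: dict[str, Counter]) -> dict[str, float]:
    """Share of canonical GT donors and AG acceptors in a tally."""
    out = {}
    for site, canon in (("donor", "GT"), ("acceptor", "AG")):
        total = sum(tally[site].values())
        out[site] = tally[site][canon] / total if total else float("nan")
    return out
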