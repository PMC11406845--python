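"""Synthetic genome, annotation, and spliced-alignment generator.

Emulates the statistical structure the scorer is trained on: multi-isoform
protein-coding genes whose introns carry canonical GT-AG boundaries with a
position-weight-matrix donor consensus (3 exonic + 6 intronic positions)
and an acceptor consensus (polypyrimidine tract + AG, 20 intronic + 3
exonic positions), against a random background.  Alternative isoforms are
generated by exon skipping, so some junctions are shared between isoforms
and others are isoform specific.

Alignments are emitted directly as SAM records (no sequencing-error model,
no aligner round trip): spliced reads across every annotated junction with
long-tailed support, spurious spliced reads across planted GT-AG junctions
on the strand opposite a gene (support mostly 1, a small fraction higher so
novel-k support strata are populated), optional mates, and duplicate decoy
alignments with NH=2 at intergenic positions to exercise NH repair.
Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .curate import CurationConfig, GeneLocus, generate_negative_random
from .encode import Genome, Junction, reverse_complement

__all__ = ["SynthConfig", "TruthBundle", "default_donor_pwm", "default_acceptor_pwm",
           "generate_genome", "generate_alignments"]

_BASES = np.array(list("ACGT"))


def default_donor_pwm() -> np.ndarray:
    """(4, 9) donor consensus: 3 exonic + 6 intronic positions, GT forced."""
    cols = [
        # A     C     G     T
        [0.35, 0.35, 0.18, 0.12],   # -3
        [0.60, 0.12, 0.14, 0.14],   # -2
        [0.09, 0.05, 0.80, 0.06],   # -1 (exon end)
        [0.00, 0.00, 1.00, 0.00],   # +1 G
        [0.00, 0.00, 0.00, 1.00],   # +2 T
        [0.60, 0.02, 0.35, 0.03],   # +3
        [0.70, 0.08, 0.10, 0.12],   # +4
        [0.07, 0.05, 0.80, 0.08],   # +5
        [0.16, 0.16, 0.18, 0.50],   # +6
    ]
    return np.array(cols).T


def default_acceptor_pwm() -> np.ndarray:
    """(4, 23) acceptor consensus: polypyrimidine tract + AG + 3 exonic."""
    poly = [0.08, 0.35, 0.07, 0.50]
    cols = [poly] * 16 + [
        [0.08, 0.75, 0.02, 0.15],   # -4
        [0.10, 0.30, 0.05, 0.55],   # -3
        [1.00, 0.00, 0.00, 0.00],   # -2 A
        [0.00, 0.00, 1.00, 0.00],   # -1 G
        [0.25, 0.10, 0.50, 0.15],   # +1 (exon start)
        [0.25, 0.25, 0.25, 0.25],
        [0.25, 0.25, 0.25, 0.25],
    ]
    return np.array(cols).T


@dataclass
class SynthConfig:
    n_chroms: int = 9
    chrom_length: int = 100_000
    n_genes: int = 63
    isoforms_per_gene: tuple[int, int] = (2, 3)
    exons_per_transcript: tuple[int, int] = (5, 9)
    exon_length: tuple[int, int] = (80, 200)
    # intron length mixture covering the <200 / 200-400 / >400 encoder branches
    intron_classes: tuple = (((80, 180), 0.25), ((200, 400), 0.25), ((420, 1600), 0.5))
    donor_pwm: np.ndarray = field(default_factory=default_donor_pwm)
    acceptor_pwm: np.ndarray = field(default_factory=default_acceptor_pwm)
    n_noise_reads: int = 300
    spurious_junction_rate: float = 0.5
    spurious_high_support_fraction: float = 0.15
    paired_fraction: float = 0.7
    multimap_fraction: float = 0.05
    read_length: int = 100
    spurious_intron_range: tuple[int, int] = (200, 2000)

    def __post_init__(self):
        for pwm in (self.donor_pwm, self.acceptor_pwm):
            if not np.allclose(pwm.sum(axis=0), 1.0):
                raise ValueError("PWM columns must sum to 1")
        if not 0 <= self.spurious_junction_rate:
            raise ValueError("spurious_junction_rate must be non-negative")


@dataclass
class Transcript:
    transcript_id: str
    exons: list  # genome-coordinate [start, end) pairs, sorted


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list


@dataclass
class TruthBundle:
    config: SynthConfig
    genome: Genome
    seqs: dict
    genes: list
    gene_loci: list
    true_junctions: list       # all annotated introns (dedup), primary/alt labeled
    spurious_junctions: list   # planted false junctions (support = planned reads)

    def write(self, outdir: str | Path) -> dict:
        """Write genome FASTA, GFF3 annotation, and truth BED files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.gff3",
            "positive": outdir / "positive_junctions.bed",
            "spurious": outdir / "spurious_junctions.bed",
        }
        with open(paths["genome"], "w") as fh:
            for name, seq in self.seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(paths["annotation"], "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                fh.write(
                    f"{g.chrom}\tsynth\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id};gene_biotype=protein_coding\n"
                )
                for tr in g.transcripts:
                    t0 = min(s for s, _ in tr.exons)
                    t1 = max(e for _, e in tr.exons)
                    fh.write(
                        f"{g.chrom}\tsynth\tmRNA\t{t0 + 1}\t{t1}\t.\t{g.strand}\t.\t"
                        f"ID={tr.transcript_id};Parent={g.gene_id}\n"
                    )
                    for k, (s, e) in enumerate(sorted(tr.exons)):
                        fh.write(
                            f"{g.chrom}\tsynth\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                            f"ID={tr.transcript_id}.exon{k + 1};Parent={tr.transcript_id}\n"
                        )
        from .encode import write_junction_bed

        write_junction_bed(paths["positive"], self.true_junctions)
        write_junction_bed(paths["spurious"], self.spurious_junctions)
        return paths

    def transcript_junctions(self) -> dict:
        """Map transcript_id -> list of its introns as Junctions."""
        out = {}
        for g in self.genes:
            for tr in g.transcripts:
                exons = sorted(tr.exons)
                out[tr.transcript_id] = [
                    Junction(g.chrom, exons[i][1], exons[i + 1][0], g.strand)
                    for i in range(len(exons) - 1)
                ]
        return out


def _sample_pwm(pwm: np.ndarray, rng: np.random.Generator) -> str:
    idx = [rng.choice(4, p=pwm[:, i]) for i in range(pwm.shape[1])]
    return "".join(_BASES[idx])


def _draw_intron_length(config: SynthConfig, rng) -> int:
    ranges, probs = zip(*config.intron_classes)
    k = rng.choice(len(ranges), p=np.asarray(probs) / np.sum(probs))
    lo, hi = ranges[k]
    return int(rng.integers(lo, hi + 1))


def _build_gene(config: SynthConfig, rng) -> tuple[str, list, list]:
    """Gene in transcript space: (sequence, exon intervals, intron intervals)."""
    n_exons = int(rng.integers(*config.exons_per_transcript, endpoint=True))
    exon_lens = rng.integers(*config.exon_length, size=n_exons, endpoint=True)
    intron_lens = [_draw_intron_length(config, rng) for _ in range(n_exons - 1)]
    parts, exons, introns = [], [], []
    pos = 0
    for i, el in enumerate(exon_lens):
        parts.append("".join(rng.choice(_BASES, size=int(el))))
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < n_exons - 1:
            il = intron_lens[i]
            parts.append("".join(rng.choice(_BASES, size=il)))
            introns.append((pos, pos + il))
            pos += il
    seq = list("".join(parts))
    dlen, alen = config.donor_pwm.shape[1], config.acceptor_pwm.shape[1]
    for a, b in introns:
        seq[a - 3 : a - 3 + dlen] = _sample_pwm(config.donor_pwm, rng)
        seq[b + 3 - alen : b + 3] = _sample_pwm(config.acceptor_pwm, rng)
    return "".join(seq), exons, introns


def generate_genome(config: SynthConfig | None = None, seed: int = 0) -> TruthBundle:
    """Random background + non-overlapping genes on alternating strands."""
    config = config or SynthConfig()
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    seqs = {
        name: list(rng.choice(_BASES, size=config.chrom_length, p=[0.3, 0.2, 0.2, 0.3]))
        for name in chrom_names
    }
    cursor = {name: 1000 for name in chrom_names}  # leave N-free margins for windows
    tail_reserve = 3000                            # intergenic decoy space per chromosome

    genes, loci = [], []
    true_junctions = []
    seen_junctions = set()
    for gi in range(config.n_genes):
        chrom = chrom_names[gi % config.n_chroms]
        strand = "+" if (gi // config.n_chroms) % 2 == 0 else "-"
        gene_seq, exons_t, introns_t = _build_gene(config, rng)
        glen = len(gene_seq)
        g0 = cursor[chrom] + int(rng.integers(1500, 3000))
        if g0 + glen > config.chrom_length - tail_reserve:
            raise ValueError(
                f"chromosome {chrom} too short for gene {gi}: need {g0 + glen}, "
                f"have {config.chrom_length - tail_reserve}"
            )
        cursor[chrom] = g0 + glen
        placed = gene_seq if strand == "+" else reverse_complement(gene_seq)
        seqs[chrom][g0 : g0 + glen] = placed

        def to_genome(span):
            a, b = span
            if strand == "+":
                return (g0 + a, g0 + b)
            return (g0 + glen - b, g0 + glen - a)

        gene_id = f"GENE{gi + 1:03d}"
        n_iso = int(rng.integers(*config.isoforms_per_gene, endpoint=True))
        transcripts = [Transcript(f"{gene_id}.t1", sorted(to_genome(e) for e in exons_t))]
        iso_introns_t = [list(introns_t)]
        skippable = list(range(1, len(exons_t) - 1))
        rng.shuffle(skippable)
        for k in range(n_iso - 1):
            if not skippable:
                break
            skip = skippable.pop()
            exons_alt = [e for i, e in enumerate(exons_t) if i != skip]
            introns_alt = [
                (exons_alt[i][1], exons_alt[i + 1][0]) for i in range(len(exons_alt) - 1)
            ]
            transcripts.append(
                Transcript(f"{gene_id}.t{k + 2}", sorted(to_genome(e) for e in exons_alt))
            )
            iso_introns_t.append(introns_alt)

        primary = {to_genome(i) for i in iso_introns_t[0]}
        for iso in iso_introns_t:
            for span in iso:
                s, e = to_genome(span)
                key = (chrom, s, e, strand)
                if key in seen_junctions:
                    continue
                seen_junctions.add(key)
                source = "positive-mane" if (s, e) in primary else "positive-alt"
                true_junctions.append(Junction(chrom, s, e, strand, 0, source))

        gstart = min(s for t in transcripts for s, _ in t.exons)
        gend = max(e for t in transcripts for _, e in t.exons)
        genes.append(Gene(gene_id, chrom, gstart, gend, strand, transcripts))
        loci.append(GeneLocus(chrom, gstart, gend, strand, gene_id))

    seqs = {k: "".join(v) for k, v in seqs.items()}
    genome = Genome.from_dict(seqs)

    n_spurious = int(round(config.spurious_junction_rate * len(true_junctions)))
    pool = generate_negative_random(
        genome,
        loci,
        CurationConfig(
            random_intron_range=config.spurious_intron_range,
            attempts_per_locus=max(10, 2 * n_spurious // max(len(loci), 1) + 2),
        ),
        seed=seed + 1,
        annotated_junctions=true_junctions,
    )
    spurious = []
    for j in pool[:n_spurious]:
        high = rng.random() < config.spurious_high_support_fraction
        support = int(rng.integers(2, 61)) if high else 1
        spurious.append(Junction(j.chrom, j.start, j.end, j.strand, support, "negative-1"))

    return TruthBundle(config, genome, seqs, genes, loci, true_junctions, spurious)


# ---------------------------------------------------------------------------
# alignments


def _support_draw(rng) -> int:
    """Long-tailed per-junction read support, always >= 1."""
    return int(min(150, 1 + rng.negative_binomial(0.5, 0.08)))


def generate_alignments(bundle: TruthBundle, path: str | Path, seed: int = 0) -> Path:
    """Write coordinate-sorted SAM/BAM with true, spurious, and noise reads."""
    config = bundle.config
    rng = np.random.default_rng(seed)
    rl = config.read_length
    chrom_names = list(bundle.seqs.keys())
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(bundle.seqs[c])} for c in chrom_names],
        }
    )
    tid = {c: i for i, c in enumerate(chrom_names)}
    records = []
    counter = 0

    def spliced_read(j: Junction, a: int):
        nonlocal counter
        b = rl - a
        pos = j.start - a
        seq = bundle.seqs[j.chrom]
        if pos < 0 or j.end + b > len(seq):
            return None
        counter += 1
        rec = pysam.AlignedSegment(header)
        rec.query_name = f"r{counter:07d}"
        rec.reference_id = tid[j.chrom]
        rec.reference_start = pos
        rec.mapping_quality = 60
        rec.cigarstring = f"{a}M{j.length}N{b}M"
        rec.query_sequence = seq[pos : j.start] + seq[j.end : j.end + b]
        rec.query_qualities = pysam.qualitystring_to_array("I" * rl)
        rec.flag = 0
        rec.set_tag("NH", 1)
        if j.strand in "+-":
            rec.set_tag("XS", j.strand)
        return rec

    def plain_read(chrom: str, pos: int, name: str | None = None):
        nonlocal counter
        seq = bundle.seqs[chrom]
        if pos < 0 or pos + rl > len(seq):
            return None
        if name is None:
            counter += 1
            name = f"r{counter:07d}"
        rec = pysam.AlignedSegment(header)
        rec.query_name = name
        rec.reference_id = tid[chrom]
        rec.reference_start = pos
        rec.mapping_quality = 60
        rec.cigarstring = f"{rl}M"
        rec.query_sequence = seq[pos : pos + rl]
        rec.query_qualities = pysam.qualitystring_to_array("I" * rl)
        rec.flag = 0
        rec.set_tag("NH", 1)
        return rec

    def pair_up(rec, j: Junction):
        """Attach a downstream unspliced proper-pair mate."""
        mpos = j.end + int(rng.integers(20, 150))
        mate = plain_read(j.chrom, mpos, name=rec.query_name)
        if mate is None:
            return None
        rec.flag = 0x1 | 0x2 | 0x20 | 0x40       # paired, proper, mate reverse, first
        mate.flag = 0x1 | 0x2 | 0x10 | 0x80      # paired, proper, reverse, second
        rec.next_reference_id = mate.reference_id
        rec.next_reference_start = mate.reference_start
        mate.next_reference_id = rec.reference_id
        mate.next_reference_start = rec.reference_start
        tlen = mate.reference_start + rl - rec.reference_start
        rec.template_length = tlen
        mate.template_length = -tlen
        return mate

    def decoy_copy(rec, chrom: str):
        """Secondary unspliced alignment at an intergenic decoy position."""
        dpos = len(bundle.seqs[chrom]) - 2500 + int(rng.integers(0, 1500))
        decoy = plain_read(chrom, dpos, name=rec.query_name)
        if decoy is None:
            return None
        decoy.flag = 0x100
        decoy.set_tag("NH", 2)
        rec.set_tag("NH", 2)
        return decoy

    def emit(j: Junction, n_reads: int):
        for k in range(n_reads):
            a = 50 if k == 0 else int(rng.integers(30, 71))
            rec = spliced_read(j, a)
            if rec is None:
                continue
            extras = []
            if rng.random() < config.paired_fraction:
                mate = pair_up(rec, j)
                if mate is not None:
                    extras.append(mate)
            if not extras and rng.random() < config.multimap_fraction:
                decoy = decoy_copy(rec, j.chrom)
                if decoy is not None:
                    extras.append(decoy)
            records.append(rec)
            records.extend(extras)

    for j in bundle.true_junctions:
        emit(j, _support_draw(rng))
    for j in bundle.spurious_junctions:
        emit(j, j.support)
    for _ in range(config.n_noise_reads):
        locus = bundle.gene_loci[int(rng.integers(len(bundle.gene_loci)))]
        pos = int(rng.integers(locus.start, max(locus.start + 1, locus.end - rl)))
        rec = plain_read(locus.chrom, pos)
        if rec is not None:
            records.append(rec)

    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name))
    path = Path(path)
    mode = "wb" if path.suffix == ".bam" else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for rec in records:
            out.write(rec)
    if path.suffix == ".bam":
        pysam.index(str(path))
    return path
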