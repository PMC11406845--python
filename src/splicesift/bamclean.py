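"""Spliced-alignment cleanup: extract junctions, score them, drop spurious reads.

The three-stage pipeline mirrors how an RNA-seq workflow would use the
scorer between alignment and assembly:

1. ``extract_junctions_bam`` collects every distinct junction spanned by an
   N CIGAR operation, with its supporting alignment count and strand (XS
   tag when present, else splice-motif orientation, else unstranded).
2. ``score_junctions`` runs the model over each junction's 800-nt window;
   unstranded junctions are scored in both orientations and keep the better
   one.  The junction score is min(donor, acceptor).
3. ``clean_alignments`` removes every alignment containing a spurious
   junction (score below threshold), unpairs the surviving mate of a
   removed paired read, and decrements the NH tag on the remaining
   alignments of reads that lost alignments.  Kept output is coordinate
   sorted; discarded records are preserved verbatim.

``extract_introns_gff`` and ``transcript_junction_report`` apply the same
scoring to annotation/assembly files: introns are pulled from each
transcript's exon chain and transcripts with too high a fraction of
low-scoring junctions can be filtered out.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import encode as enc
from .encode import Genome, Junction

__all__ = [
    "CleanupConfig",
    "CleanReport",
    "ScoredJunction",
    "extract_junctions_bam",
    "score_junctions",
    "clean_alignments",
    "run_cleanup",
    "extract_introns_gff",
    "transcript_junction_report",
    "filter_annotation",
]


@dataclass
class CleanupConfig:
    score_threshold: float = 0.1
    paired_mode: bool = True

    def __post_init__(self):
        if not 0 <= self.score_threshold <= 1:
            raise ValueError("score_threshold must be in [0, 1]")


@dataclass
class CleanReport:
    kept: int = 0
    discarded: int = 0
    unpaired_repairs: int = 0
    nh_updates: int = 0
    missing_mates: int = 0
    junctions_scored: int = 0
    junctions_spurious: int = 0


@dataclass(frozen=True)
class ScoredJunction:
    junction: Junction
    donor: float
    acceptor: float

    @property
    def junction_score(self) -> float:
        return min(self.donor, self.acceptor)


def _junction_spans(rec):
    """(start, end) reference spans of N CIGAR operations of one record."""
    if rec.cigartuples is None:
        return
    pos = rec.reference_start
    for op, length in rec.cigartuples:
        if op == 3:  # N: skipped region
            yield pos, pos + length
            pos += length
        elif op in (0, 2, 7, 8):  # M, D, =, X consume reference
            pos += length


def _open_alignments(alignments):
    if isinstance(alignments, (str, Path)):
        return pysam.AlignmentFile(str(alignments), check_sq=False), True
    return alignments, False


def _motif_strand(genome: Genome, chrom: str, start: int, end: int) -> str:
    head = genome.fetch(chrom, start, start + 2)
    tail = genome.fetch(chrom, end - 2, end)
    if head == "GT" and tail == "AG":
        return "+"
    if head == "CT" and tail == "AC":
        return "-"
    return "."


def extract_junctions_bam(alignments, genome: Genome | None = None) -> list[Junction]:
    """Distinct junctions spanned by spliced alignments, with support counts.

    Strand comes from the XS tag majority when present, else from the GT-AG
    motif orientation when a genome is supplied, else '.'.
    """
    af, close = _open_alignments(alignments)
    support: Counter = Counter()
    strands: dict = defaultdict(Counter)
    try:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            try:
                spans = list(_junction_spans(rec))
            except ValueError:
                warnings.warn(f"skipping record with malformed CIGAR: {rec.query_name}")
                continue
            if not spans:
                continue
            xs = rec.get_tag("XS") if rec.has_tag("XS") else None
            for span in spans:
                key = (rec.reference_name, *span)
                support[key] += 1
                if xs in ("+", "-"):
                    strands[key][xs] += 1
    finally:
        if close:
            af.close()
    out = []
    for (chrom, start, end), n in sorted(support.items()):
        tally = strands.get((chrom, start, end))
        if tally:
            strand = tally.most_common(1)[0][0]
        elif genome is not None and chrom in genome:
            strand = _motif_strand(genome, chrom, start, end)
        else:
            strand = "."
        out.append(Junction(chrom, start, end, strand, n, "unlabeled"))
    return out


def score_junctions(model, genome: Genome, junctions, batch_size: int = 100):
    """(scored, unscorable) junction lists.

    Unstranded junctions are evaluated in both orientations and keep the
    orientation with the larger junction score.  Junctions whose window
    cannot be constructed (unknown chromosome) are returned separately.
    """
    todo, unscorable = [], []
    for j in junctions:
        if j.chrom not in genome:
            unscorable.append(j)
            continue
        if j.strand == ".":
            todo.append((j, Junction(j.chrom, j.start, j.end, "+", j.support, j.source, j.name)))
            todo.append((j, Junction(j.chrom, j.start, j.end, "-", j.support, j.source, j.name)))
        else:
            todo.append((j, j))
    if not todo:
        return [], unscorable
    X = np.stack([enc.one_hot(enc.extract_window(genome, var)) for _, var in todo])
    probs = model.predict(X, batch_size=batch_size)
    donor = probs[:, enc.CLASS_DONOR, enc.DONOR_POS]
    acceptor = probs[:, enc.CLASS_ACCEPTOR, enc.ACCEPTOR_POS]
    best: dict = {}
    for (orig, var), d, a in zip(todo, donor, acceptor):
        sj = ScoredJunction(var, float(d), float(a))
        prev = best.get(id(orig))
        if prev is None or sj.junction_score > prev.junction_score:
            best[id(orig)] = sj
    # keep the input order
    seen = set()
    scored = []
    for orig, _ in todo:
        if id(orig) not in seen:
            seen.add(id(orig))
            scored.append(best[id(orig)])
    return scored, unscorable


def write_scored_bed(path, scored) -> None:
    """BED6 + donor + acceptor columns; the score column is the junction score."""
    lines = []
    for i, sj in enumerate(scored):
        j = sj.junction
        name = j.name if j.name != "." else f"JUNC{i + 1:08d}"
        lines.append(
            f"{j.chrom}\t{j.start}\t{j.end}\t{name}\t{sj.junction_score:.6f}\t{j.strand}"
            f"\t{sj.donor:.6f}\t{sj.acceptor:.6f}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_scored_bed(path) -> list[ScoredJunction]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        j = Junction(f[0], int(f[1]), int(f[2]), f[5], 0, "unlabeled", f[3])
        out.append(ScoredJunction(j, float(f[6]), float(f[7])))
    return out


def clean_alignments(alignments, spurious, kept_path, discarded_path,
                     config: CleanupConfig | None = None) -> CleanReport:
    """Two-pass cleanup of an alignment file.

    ``spurious`` is a set of (chrom, start, end) intervals (strand ignored:
    a read spans the interval regardless of transcription strand).  Pass 1
    finds the alignments to remove, the mates to unpair, and the per-read
    NH decrements; pass 2 rewrites.  Kept output is coordinate sorted.
    """
    config = config or CleanupConfig()
    spurious = {tuple(k)[:3] for k in spurious}
    report = CleanReport()

    def is_spurious(rec):
        return any((rec.reference_name, s, e) in spurious for s, e in _junction_spans(rec))

    def read_key(rec):
        return (rec.query_name, rec.is_read2)

    removed_counts: Counter = Counter()
    unpair_keys = set()
    key_kept = Counter()

    af, close = _open_alignments(alignments)
    path = str(alignments) if isinstance(alignments, (str, Path)) else None
    if path is None:
        raise ValueError("clean_alignments needs a file path (two passes over the input)")
    try:
        header = af.header.to_dict()
        for rec in af.fetch(until_eof=True):
            if not rec.is_unmapped and is_spurious(rec):
                removed_counts[read_key(rec)] += 1
                if rec.is_paired and config.paired_mode:
                    unpair_keys.add((rec.query_name, not rec.is_read2))
            else:
                key_kept[read_key(rec)] += 1
    finally:
        if close:
            af.close()

    header.setdefault("HD", {})["SO"] = "coordinate"
    out_header = pysam.AlignmentHeader.from_dict(header)
    kept_records = []
    kept_path, discarded_path = Path(kept_path), Path(discarded_path)
    disc_mode = "wb" if discarded_path.suffix == ".bam" else "w"
    with pysam.AlignmentFile(str(path), check_sq=False) as af, pysam.AlignmentFile(
        str(discarded_path), disc_mode, header=out_header
    ) as disc:
        for rec in af.fetch(until_eof=True):
            if not rec.is_unmapped and is_spurious(rec):
                report.discarded += 1
                disc.write(rec)
                continue
            key = read_key(rec)
            if key in unpair_keys:
                rec.flag &= ~(0x1 | 0x2 | 0x8 | 0x20)
                rec.next_reference_id = -1
                rec.next_reference_start = -1
                rec.template_length = 0
                report.unpaired_repairs += 1
            drop = removed_counts.get(key, 0)
            if drop and rec.has_tag("NH"):
                rec.set_tag("NH", max(1, rec.get_tag("NH") - drop))
                report.nh_updates += 1
            report.kept += 1
            kept_records.append(rec)
    report.missing_mates = sum(1 for k in unpair_keys if key_kept.get(k, 0) == 0)

    kept_records.sort(key=lambda r: (r.reference_id if r.reference_id >= 0 else 1 << 30,
                                     r.reference_start, r.query_name))
    kept_mode = "wb" if kept_path.suffix == ".bam" else "w"
    with pysam.AlignmentFile(str(kept_path), kept_mode, header=out_header) as out:
        for rec in kept_records:
            out.write(rec)
    if kept_path.suffix == ".bam":
        pysam.index(str(kept_path))
    return report


def run_cleanup(bam_path, model, genome: Genome, outdir,
                config: CleanupConfig | None = None) -> tuple[CleanReport, list]:
    """extract -> score -> clean; returns (report, scored junctions)."""
    config = config or CleanupConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    junctions = extract_junctions_bam(bam_path, genome=genome)
    enc.write_junction_bed(outdir / "junction.bed", junctions)
    scored, unscorable = score_junctions(model, genome, junctions)
    write_scored_bed(outdir / "junction_score.bed", scored)
    spurious = {
        sj.junction.interval for sj in scored if sj.junction_score < config.score_threshold
    }
    suffix = Path(bam_path).suffix
    report = clean_alignments(
        bam_path, spurious, outdir / f"cleaned{suffix}", outdir / f"discarded{suffix}", config
    )
    report.junctions_scored = len(scored)
    report.junctions_spurious = len(spurious)
    return report, scored


# ---------------------------------------------------------------------------
# annotation-side scoring


def extract_introns_gff(path) -> tuple[list[Junction], pd.DataFrame]:
    """Introns of every transcript in a GFF3/GTF file.

    Returns (junctions, table); the table has the six BED columns chrom,
    start, end, junction name, intron number (1-based in transcription
    order), and strand.  Transcripts with incorrectly overlapping exons are
    dropped; single-exon transcripts contribute nothing.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    junctions, rows = [], []
    types = [t for t in ("mRNA", "transcript") if t in set(db.featuretypes())]
    for tr in sorted(
        (t for ft in types for t in db.features_of_type(ft)),
        key=lambda t: (t.seqid, t.start, t.id),
    ):
        exons = sorted(
            (e.start - 1, e.end) for e in db.children(tr, featuretype="exon")
        )
        if len(exons) < 2:
            continue
        if any(exons[i + 1][0] < exons[i][1] for i in range(len(exons) - 1)):
            warnings.warn(f"transcript {tr.id} has overlapping exons; skipped")
            continue
        introns = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
        order = introns if tr.strand == "+" else introns[::-1]
        for num, (s, e) in enumerate(order, start=1):
            j = Junction(tr.seqid, s, e, tr.strand, 0, "unlabeled", name=tr.id)
            junctions.append(j)
            rows.append(
                {"chrom": tr.seqid, "start": s, "end": e, "name": tr.id,
                 "intron_num": num, "strand": tr.strand}
            )
    return junctions, pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                                  "intron_num", "strand"])


def transcript_junction_report(transcript_introns: dict, scores: dict,
                               score_threshold: float = 0.1,
                               bad_ratio_threshold: float = 0.5):
    """Per-transcript bad-junction counts and the surviving transcript set.

    ``transcript_introns`` maps transcript id -> its introns (Junctions);
    ``scores`` maps (chrom, start, end) -> junction score.  A junction is
    bad when its score is below ``score_threshold``; transcripts whose
    bad-junction ratio exceeds ``bad_ratio_threshold`` are dropped.
    Intronless transcripts have ratio 0 and are kept.
    """
    rows = []
    kept = set()
    for tid, introns in transcript_introns.items():
        n = len(introns)
        n_bad = sum(1 for j in introns if scores.get(j.interval, 0.0) < score_threshold)
        ratio = n_bad / n if n else 0.0
        keep = ratio <= bad_ratio_threshold
        if keep:
            kept.add(tid)
        rows.append({"transcript_id": tid, "n_introns": n, "n_bad": n_bad,
                     "ratio": ratio, "kept": keep})
    return pd.DataFrame(rows), kept


def filter_annotation(path_in, kept_ids, path_out) -> None:
    """Copy a GFF3 file, dropping transcripts (and their children) not kept."""
    kept_ids = set(kept_ids)
    dropped = set()
    out_lines = []
    for line in Path(path_in).read_text().splitlines():
        if not line or line.startswith("#"):
            out_lines.append(line)
            continue
        fields = line.split("\t")
        attrs = dict(
            kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
        ) if len(fields) > 8 else {}
        ftype = fields[2] if len(fields) > 2 else ""
        if ftype in ("mRNA", "transcript"):
            tid = attrs.get("ID", "")
            if tid not in kept_ids:
                dropped.add(tid)
                continue
        elif attrs.get("Parent", "") in dropped:
            continue
        out_lines.append(line)
    Path(path_out).write_text("\n".join(out_lines) + "\n")
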