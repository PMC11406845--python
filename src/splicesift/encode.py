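"""Window extraction and one-hot encoding for splice junctions.

A junction is an intron in 0-based half-open coordinates ``[start, end)``:
``start`` is the first intron base (the G of the canonical GT donor) and
``end - 1`` the last intron base (the G of the canonical AG acceptor).  The
model input is the concatenation of a 400-nt window centered on the donor
and a 400-nt window centered on the acceptor, in transcript orientation, so
GT sits at offsets [200:202] and AG at [598:600] of the 800-nt window.

Short introns follow two special rules: between 200 and 400 nt the two
intronic flanks may overlap (identical at exactly 200 nt); below 200 nt the
flanks are truncated at the intron boundary and N-padded back to 200 nt.
Positions beyond a chromosome end are N-padded as well, so the window is
always exactly 800 nt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Junction",
    "EncodedExample",
    "SiteScores",
    "Genome",
    "WINDOW_LENGTH",
    "DONOR_POS",
    "ACCEPTOR_POS",
    "CLASS_NEITHER",
    "CLASS_ACCEPTOR",
    "CLASS_DONOR",
    "extract_window",
    "reverse_complement",
    "one_hot",
    "encode_labels",
    "encode_junction",
    "encode_batch",
    "site_scores",
    "read_junction_bed",
    "write_junction_bed",
]

WINDOW_LENGTH = 800
FLANK = 200
DONOR_POS = 200      # 0-based window offset of the donor site (first intron base)
ACCEPTOR_POS = 600   # 0-based window offset of the acceptor site (first base after the intron)

# label/probability channel convention
CLASS_NEITHER = 0
CLASS_ACCEPTOR = 1
CLASS_DONOR = 2

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class Junction:
    """A candidate intron: 0-based half-open [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str
    support: int = 0
    source: str = "unlabeled"
    name: str = "."

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"junction end must exceed start ({self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.support < 0:
            raise ValueError("support must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def interval(self) -> tuple:
        return (self.chrom, self.start, self.end)


@dataclass
class EncodedExample:
    sequence: str
    onehot: np.ndarray          # (4, 800)
    labels: np.ndarray          # (3, 800)
    junction: Junction


@dataclass(frozen=True)
class SiteScores:
    donor: float
    acceptor: float

    @property
    def junction_score(self) -> float:
        return min(self.donor, self.acceptor)


class Genome:
    """Uppercase, N-padded random access to chromosome sequence.

    Wraps either a plain ``{name: sequence}`` dict or an indexed FASTA file
    (via pyfaidx).  ``fetch`` returns exactly ``end - start`` characters,
    padding with N outside the chromosome.
    """

    def __init__(self, seqs):
        self._seqs = seqs

    @classmethod
    def from_dict(cls, seqs: dict) -> "Genome":
        return cls({k: str(v).upper() for k, v in seqs.items()})

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        from pyfaidx import Fasta

        return cls(_FaidxAdapter(Fasta(str(path), sequence_always_upper=True)))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chroms(self):
        return list(self._seqs.keys())

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown sequence {chrom!r}")
        n = self.length(chrom)
        lo, hi = max(start, 0), min(end, n)
        core = str(self._seqs[chrom][lo:hi]) if hi > lo else ""
        return "N" * (lo - start) + core.upper() + "N" * (end - hi)


class _FaidxAdapter:
    def __init__(self, fasta):
        self._fasta = fasta

    def __contains__(self, chrom):
        return chrom in self._fasta

    def keys(self):
        return self._fasta.keys()

    def __getitem__(self, chrom):
        return _FaidxSeq(self._fasta[chrom])


class _FaidxSeq:
    def __init__(self, rec):
        self._rec = rec

    def __len__(self):
        return len(self._rec)

    def __getitem__(self, sl):
        return str(self._rec[sl])


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_window(genome: Genome, junction: Junction) -> str:
    """800-nt window pair around the donor and acceptor, transcript orientation."""
    j = junction
    half = min(j.length, FLANK)
    pad = "N" * (FLANK - half)
    if j.strand == "-":
        # transcript orientation = reverse complement; the donor is at `end`
        exon_d = reverse_complement(genome.fetch(j.chrom, j.end, j.end + FLANK))
        intron_d = reverse_complement(genome.fetch(j.chrom, j.end - half, j.end)) + pad
        intron_a = pad + reverse_complement(genome.fetch(j.chrom, j.start, j.start + half))
        exon_a = reverse_complement(genome.fetch(j.chrom, j.start - FLANK, j.start))
    else:
        exon_d = genome.fetch(j.chrom, j.start - FLANK, j.start)
        intron_d = genome.fetch(j.chrom, j.start, j.start + half) + pad
        intron_a = pad + genome.fetch(j.chrom, j.end - half, j.end)
        exon_a = genome.fetch(j.chrom, j.end, j.end + FLANK)
    window = exon_d + intron_d + intron_a + exon_a
    assert len(window) == WINDOW_LENGTH
    return window


_ONEHOT_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ONEHOT_INDEX[ord(_b)] = _i
    _ONEHOT_INDEX[ord(_b.lower())] = _i
_ONEHOT_INDEX[ord("N")] = -2
_ONEHOT_INDEX[ord("n")] = -2


def one_hot(sequence: str) -> np.ndarray:
    """(4, L) one-hot over A/C/G/T; N (and unknown characters) encode as zeros."""
    codes = _ONEHOT_INDEX[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (codes == -1).any():
        warnings.warn("sequence contains characters outside {A,C,G,T,N}; treated as N")
    out = np.zeros((4, len(sequence)), dtype=np.float32)
    valid = codes >= 0
    out[codes[valid], np.nonzero(valid)[0]] = 1.0
    return out


def encode_labels(is_junction: bool, length: int = WINDOW_LENGTH) -> np.ndarray:
    """(3, L) per-position class labels (channels: neither/acceptor/donor).

    A real junction labels the donor at offset 200 and the acceptor at
    offset 600; everything else (and every position of a negative example)
    is the neither class.
    """
    labels = np.zeros((3, length), dtype=np.float32)
    labels[CLASS_NEITHER] = 1.0
    if is_junction:
        labels[:, DONOR_POS] = 0.0
        labels[CLASS_DONOR, DONOR_POS] = 1.0
        labels[:, ACCEPTOR_POS] = 0.0
        labels[CLASS_ACCEPTOR, ACCEPTOR_POS] = 1.0
    return labels


def encode_junction(genome: Genome, junction: Junction, is_positive: bool) -> EncodedExample:
    seq = extract_window(genome, junction)
    return EncodedExample(seq, one_hot(seq), encode_labels(is_positive), junction)


def encode_batch(genome: Genome, junctions, labels=None):
    """Encode many junctions into stacked (N,4,800) inputs and (N,3,800) labels.

    ``labels`` is an iterable of booleans (is-real-junction); defaults to all
    True.
    """
    junctions = list(junctions)
    if labels is None:
        labels = [True] * len(junctions)
    X = np.zeros((len(junctions), 4, WINDOW_LENGTH), dtype=np.float32)
    Y = np.zeros((len(junctions), 3, WINDOW_LENGTH), dtype=np.float32)
    for i, (j, pos) in enumerate(zip(junctions, labels)):
        X[i] = one_hot(extract_window(genome, j))
        Y[i] = encode_labels(bool(pos))
    return X, Y


def site_scores(prob_map: np.ndarray) -> SiteScores:
    """Donor/acceptor probabilities at window offsets 200 and 600."""
    prob_map = np.asarray(prob_map)
    if prob_map.shape[-2:] != (3, WINDOW_LENGTH) and prob_map.shape != (3, WINDOW_LENGTH):
        raise ValueError(f"expected a (3, {WINDOW_LENGTH}) probability map, got {prob_map.shape}")
    return SiteScores(
        donor=float(prob_map[CLASS_DONOR, DONOR_POS]),
        acceptor=float(prob_map[CLASS_ACCEPTOR, ACCEPTOR_POS]),
    )


# ---------------------------------------------------------------------------
# 6-column BED IO (chrom, start, end, name, score, strand)


def read_junction_bed(path: str | Path, source: str = "unlabeled") -> list[Junction]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        name = f[3] if len(f) > 3 else "."
        score = int(float(f[4])) if len(f) > 4 and f[4] != "." else 0
        strand = f[5] if len(f) > 5 else "."
        out.append(
            Junction(f[0], int(f[1]), int(f[2]), strand, support=max(score, 0),
                     source=source, name=name)
        )
    return out


def write_junction_bed(path: str | Path, junctions, scores=None) -> None:
    """Write junctions as BED6 (score column = support, or the given scores)."""
    lines = []
    for i, j in enumerate(junctions):
        score = scores[i] if scores is not None else j.support
        name = j.name if j.name != "." else f"JUNC{i + 1:08d}"
        lines.append(f"{j.chrom}\t{j.start}\t{j.end}\t{name}\t{score}\t{j.strand}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
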