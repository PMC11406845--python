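# splicesift

Splice-junction recognition and spliced-alignment cleanup.

RNA-seq aligners report splice junctions wherever a read maps across a gap,
and a sizable fraction of those junctions are artifacts of alignment error
or transcriptional noise. Downstream transcript assembly inherits every
one of them. `splicesift` addresses this with a sequence-level scorer: a
deep residual convolutional network that looks at a candidate intron the
way the spliceosome does — donor and acceptor together — and the pipeline
machinery to act on its scores: curate training data from alignments and
annotation, train the scorer, and remove spliced alignments that cross
junctions the model rejects, with correct pair-flag and NH-tag repair.

It is aimed at people who process RNA-seq alignments (BAM) or annotation
files (GFF3/GTF) and want junction-level quality control between alignment
and assembly.

## The model

A candidate intron on chromosome c is the 0-based half-open interval
[start, end): `start` is the first intron base (the G of the canonical GT)
and `end − 1` the last (the G of AG). The input is an 800-nt window pair —
400 nt centered on the donor, 400 nt centered on the acceptor, in
transcript orientation — one-hot encoded over {A, C, G, T}. The network
(F = 64 filters; 20 residual units in 5 groups of 4; per-group kernel
widths W = [11, 11, 11, 21, 21] and dilations D = [1, 5, 10, 15, 20];
grouped convolutions with G = 4; pointwise skip connections; 651,715
parameters; receptive span S = Σ 2·D·(W − 1) = 6,880 nt) outputs
per-position probabilities P(neither), P(acceptor), P(donor) for all 800
positions. The scores that matter are

    donor score    = P(donor)    at window offset 200
    acceptor score = P(acceptor) at window offset 600
    junction score = min(donor score, acceptor score)

Training minimizes focal loss, −Σ I·(1 − P)^γ·log P with γ = 2, over all
positions, with AdamW under a linear-warmup + cosine-decay schedule. The
network, backpropagation, and optimizer are implemented in numpy (no deep
learning framework); training is deterministic for a fixed seed. See
`docs/methods.md` for the full model and training account.

## Worked example

Everything below runs from scratch on synthetic data — no downloads.
Generate a genome with annotated multi-isoform genes and an alignment file
containing both real and spurious spliced reads, then train a scorer on it:

```
$ splicesift synth -o demo --seed 7
475 true / 238 spurious junctions; genome -> demo/genome.fa, alignments -> demo/alignments.sam

$ splicesift train -o demo/model --data demo --positives 300 --seed 7
trained on 300 pos / 600 neg; per-epoch loss: 99.7759, 2.3391, 0.1726; 651715 parameters -> demo/model.npz
```

(Training prints one loss per epoch; 27 optimizer steps here, roughly ten
minutes on one CPU.) Now the three-step cleanup:

```
$ splicesift extract -P -o demo/out demo/alignments.sam
713 junctions -> demo/out/junction.bed

$ splicesift score -G demo/genome.fa -m demo/model -o demo/out demo/out/junction.bed
713 junctions scored -> demo/out/junction_score.bed

$ splicesift clean -o demo/out -t 0.1
kept 6672, discarded 600, unpaired 419, NH updates 3
```

`extract` found all 713 distinct junctions (the 475 real plus the 238
spurious); `score` wrote donor/acceptor/junction scores for each; `clean`
removed the 600 alignments whose junction scored below 0.1, cleared the
pairing flags of their 419 surviving mates, repaired 3 NH tags, and wrote
a coordinate-sorted `cleaned.sam` plus the discarded records. Comparing
the junction sets against the truth annotation shows the intended effect:

```python
from splicesift.encode import read_junction_bed
from splicesift.bamclean import extract_junctions_bam
from splicesift import metrics

truth = read_junction_bed("demo/positive_junctions.bed")
before = extract_junctions_bam("demo/alignments.sam")
after = extract_junctions_bam("demo/out/cleaned.sam")
p0, r0, _ = metrics.intron_precision_recall(before, truth)
p1, r1, _ = metrics.intron_precision_recall(after, truth)
print(f"intron precision {p0:.3f} -> {p1:.3f}; recall {r0:.3f} -> {r1:.3f}")
```

```
intron precision 0.666 -> 0.800; recall 1.000 -> 1.000
```

Junctions with real splice-site consensus score near 1 and survive; random
GT-AG junctions score near 0 and are removed — intron precision rises with
no recall loss.

The same three commands accept an annotation instead of an alignment file
(`splicesift extract -o out annotation.gff3`), in which case `clean`
filters transcripts by their fraction of low-scoring introns.

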