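"""Shared fixtures: synthetic bundles, curated datasets, trained models.

The expensive fixtures (full-architecture training runs) are session scoped
and shared between the training tests and the cleanup pipeline tests.
Problem sizes are the package's desk-scale defaults; all seeds are fixed so
every run of the suite sees identical data and identical training
trajectories.
"""

from __future__ import annotations

import numpy as np
import pytest

from splicesift import curate, train as train_mod
from splicesift.curate import CurationConfig
from splicesift.encode import encode_batch
from splicesift.model import ModelConfig, build_model
from splicesift.synth import SynthConfig, generate_alignments, generate_genome
from splicesift.bamclean import extract_junctions_bam

HOLDOUT = frozenset({"chr1", "chr9"})
N_TRAIN_POS = 300       # training positives (negatives at the 1:2 ratio)
TRAIN_EPOCHS = 3
BATCH_SIZE = 100


@pytest.fixture(scope="session")
def bundle():
    """Primary synthetic bundle: genome, annotation, truth junctions."""
    return generate_genome(seed=11)


@pytest.fixture(scope="session")
def bundle_sam(bundle, tmp_path_factory):
    path = tmp_path_factory.mktemp("synth") / "alignments.sam"
    generate_alignments(bundle, path, seed=12)
    return path


@pytest.fixture(scope="session")
def tiny_model():
    """A small but complete network for fast functional tests."""
    config = ModelConfig(
        n_channels=8, group_window=[5], group_dilation=[2], ru_groups=2,
        rus_per_group=2, n_groups=1,
    )
    return build_model(config, seed=3)


@pytest.fixture(scope="session")
def curated(bundle, bundle_sam):
    """Curated train/held-out datasets from the primary bundle."""
    genome = bundle.genome
    extracted = extract_junctions_bam(bundle_sam, genome=genome)
    neg1 = curate.select_negative_1(extracted, bundle.gene_loci)
    pos_train, pos_test = curate.chromosome_split(bundle.true_junctions, HOLDOUT)
    neg1_train, neg1_test = curate.chromosome_split(neg1, HOLDOUT)
    cfg = CurationConfig(random_intron_range=(200, 2000))
    loci_train = [g for g in bundle.gene_loci if g.chrom not in HOLDOUT]
    loci_test = [g for g in bundle.gene_loci if g.chrom in HOLDOUT]
    negr_train = curate.generate_negative_random(
        genome, loci_train, cfg, seed=101,
        annotated_junctions=bundle.true_junctions, aligned_junctions=extracted,
    )
    negr_test = curate.generate_negative_random(
        genome, loci_test, cfg, seed=102,
        annotated_junctions=bundle.true_junctions, aligned_junctions=extracted,
    )
    rng = np.random.default_rng(103)
    pos_sel = [pos_train[i] for i in rng.permutation(len(pos_train))[:N_TRAIN_POS]]
    pos_sel, neg_sel = curate.assemble_training_set(pos_sel, neg1_train, negr_train, seed=104)
    # held-out evaluation set at a 1:3 positive:negative ratio
    neg_test = neg1_test + negr_test
    neg_test = [neg_test[i] for i in rng.permutation(len(neg_test))[: 3 * len(pos_test)]]
    return {
        "extracted": extracted,
        "train_junctions": pos_sel + neg_sel,
        "train_labels": [True] * len(pos_sel) + [False] * len(neg_sel),
        "test_junctions": pos_test + neg_test,
        "test_labels": [True] * len(pos_test) + [False] * len(neg_test),
    }


@pytest.fixture(scope="session")
def encoded_sets(bundle, curated):
    Xtr, Ytr = encode_batch(bundle.genome, curated["train_junctions"], curated["train_labels"])
    Xte, _ = encode_batch(bundle.genome, curated["test_junctions"], curated["test_labels"])
    yte = np.array(curated["test_labels"], dtype=int)
    return Xtr, Ytr, Xte, yte


def _train_config(n_examples: int, seed: int) -> train_mod.TrainConfig:
    # desk-scale schedule: the published peak LR (0.03) and 1000-step warmup
    # assume a ~100k-step horizon; at ~30 steps the peak scales down and the
    # warmup becomes a fraction of the run
    steps = int(np.ceil(n_examples / BATCH_SIZE)) * TRAIN_EPOCHS
    return train_mod.TrainConfig(
        batch_size=BATCH_SIZE, epochs=TRAIN_EPOCHS, peak_lr=0.005,
        warmup_steps=max(1, round(0.2 * steps)), seed=seed,
    )


@pytest.fixture(scope="session")
def trained(encoded_sets):
    """Full-architecture model trained on the synthetic training set."""
    Xtr, Ytr, Xte, yte = encoded_sets
    model = build_model(seed=13)
    history, _ = train_mod.train(model, Xtr, Ytr, _train_config(len(Xtr), seed=13))
    donor, acceptor, junction = train_mod.score_examples(model, Xte)
    return {
        "model": model, "history": history,
        "donor": donor, "acceptor": acceptor, "junction": junction, "labels": yte,
    }


@pytest.fixture(scope="session")
def shuffled_trained(encoded_sets):
    """Leakage control: identical training with example labels shuffled."""
    Xtr, Ytr, Xte, yte = encoded_sets
    rng = np.random.default_rng(105)
    Yshuf = Ytr[rng.permutation(len(Ytr))]
    model = build_model(seed=13)
    train_mod.train(model, Xtr, Yshuf, _train_config(len(Xtr), seed=13))
    _, _, junction = train_mod.score_examples(model, Xte)
    return {"model": model, "junction": junction, "labels": yte}


@pytest.fixture(scope="session")
def cleanup_bundle():
    """Second, smaller bundle for the alignment-cleanup pipeline."""
    config = SynthConfig(n_chroms=4, n_genes=28)
    return generate_genome(config, seed=21)


@pytest.fixture(scope="session")
def cleanup_bam(cleanup_bundle, tmp_path_factory):
    path = tmp_path_factory.mktemp("cleanup") / "alignments.bam"
    generate_alignments(cleanup_bundle, path, seed=22)
    return path
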