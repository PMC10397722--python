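import numpy as np
import pytest

from orthoclass.classify import ModelSpec, SplitSpec, make_dataset, split_dataset, train_model
from orthoclass.datamodel import ExpressionMatrix, GeneAnnotation, SampleLabels
from orthoclass.normalize import counts_to_tpm, log10_transform
from orthoclass.orthology import (
    build_feature_space,
    filter_one_to_one,
    filter_protein_coding,
    project_to_feature_space,
)
from orthoclass.simulate import (
    SPECIES_A,
    SPECIES_B,
    SimulationConfig,
    generate_cohort,
    generate_ortholog_table,
)

#: small CNN interior used throughout the tests (same contract, desk scale)
SMALL_CNN = dict(
    kind="cnn1d",
    conv_filters=(8, 16),
    kernel_size=8,
    pool_size=4,
    dense_units=32,
    epochs=30,
    patience=5,
)


@pytest.fixture
def toy_counts():
    """5 genes × 4 samples of counts with a matching annotation."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(5)]
    matrix = ExpressionMatrix(
        gene_ids=genes,
        sample_ids=["s1", "s2", "s3", "s4"],
        values=rng.integers(1, 500, size=(5, 4)).astype(float),
        unit="counts",
        species="human",
    )
    annotation = GeneAnnotation(
        gene_ids=genes,
        length_bp=np.array([500, 1000, 1500, 2000, 3000]),
        biotype=["protein_coding"] * 4 + ["lncRNA"],
    )
    return matrix, annotation


@pytest.fixture(scope="session")
def separable():
    """The K=4, F=1000, effect-2.0, n=60/class conserved-signature experiment.

    Expensive (one CNN fit), so built once per session and shared between the
    classifier tests and the transfer acceptance criteria.
    """
    classes = ("T1", "T2", "T3", "T4")
    config = SimulationConfig(
        class_names=classes,
        samples_per_class_a={c: 60 for c in classes},
        samples_per_class_b={c: 30 for c in classes},
        n_genes_one_to_one=1000,
        fraction_protein_coding=1.0,
        n_signature_genes_per_class=30,
        signature_log2fc=2.0,
        conserved_fraction=1.0,
        seed=11,
    )
    table, ann_a, ann_b = generate_ortholog_table(config)
    matrix_a, labels_a, truth = generate_cohort(config, SPECIES_A)
    matrix_b, labels_b, _ = generate_cohort(config, SPECIES_B)
    fspace = build_feature_space(filter_protein_coding(filter_one_to_one(table), ann_a))
    log_a = project_to_feature_space(
        log10_transform(counts_to_tpm(matrix_a, ann_a)), fspace
    )
    log_b = log10_transform(counts_to_tpm(matrix_b, ann_b))
    dataset = make_dataset(log_a, labels_a)
    train, val, test = split_dataset(dataset, SplitSpec(seed=11))
    cnn = train_model(ModelSpec(**SMALL_CNN, seed=11), train, val)
    lr = train_model(ModelSpec(kind="logistic_regression", seed=11), train, val)
    return {
        "config": config,
        "truth": truth,
        "feature_space": fspace,
        "train": train,
        "val": val,
        "test": test,
        "cnn": cnn,
        "lr": lr,
        "log_b": log_b,
        "labels_b": labels_b,
    }
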