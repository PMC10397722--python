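"""Synthetic two-species cohort and ortholog-table generator.

Stands in for the real human/canine downloads and provides ground truth for
every downstream stage. Counts are drawn from a gamma-Poisson (negative
binomial) model whose log2 mean decomposes into a per-gene baseline shared
between orthologous genes, a per-(gene, species) batch shift, and class
signature effects. A configurable fraction of each class's signature genes
is conserved across species; the rest are species-private, which is what
makes cross-species transfer degrade as ``conserved_fraction`` drops.
Columns are rescaled to log-normal library sizes so the TPM normalization is
never a no-op.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from orthoclass.datamodel import (
    ExpressionMatrix,
    GeneAnnotation,
    SampleLabels,
)
from orthoclass.normalize import counts_to_fpkm_uq  # noqa: F401  (re-export; used by this module's CLI)
from orthoclass.orthology import OrthologTable

SPECIES_A = "synthetic-A"  # human-side role
SPECIES_B = "synthetic-B"  # canine-side role


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-species experiment."""

    class_names: tuple = ("T1", "T2", "T3", "normal")
    samples_per_class_a: dict = field(default_factory=dict)
    samples_per_class_b: dict = field(default_factory=dict)
    n_genes_one_to_one: int = 600
    n_genes_one_to_many: int = 30
    n_genes_species_specific_a: int = 30
    n_genes_species_specific_b: int = 30
    fraction_protein_coding: float = 0.9
    n_signature_genes_per_class: int = 25
    signature_log2fc: float = 2.0
    conserved_fraction: float = 1.0
    species_batch_log2fc: float = 0.5
    nb_dispersion: float = 0.1
    gene_length_range: tuple = (300, 20000)
    grade_pair: tuple | None = None
    grade_delta_log2fc: float = 0.25
    n_grade_genes: int = 10
    normal_class: str = "normal"
    library_size: float = 1.0e6
    library_size_sigma: float = 0.3
    baseline_log2_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_names = tuple(self.class_names)
        if len(set(self.class_names)) != len(self.class_names):
            raise SimulationError("class names must be unique")
        if len(self.class_names) < 2:
            raise SimulationError("need at least 2 classes")
        if self.n_genes_one_to_one <= 0:
            raise SimulationError(
                "n_genes_one_to_one must be > 0: the pipeline requires a "
                "nonempty feature space"
            )
        if not (0.0 < self.fraction_protein_coding <= 1.0):
            raise SimulationError("fraction_protein_coding must be in (0, 1]")
        if not (0.0 <= self.conserved_fraction <= 1.0):
            raise SimulationError("conserved_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be > 0")
        for d in (self.samples_per_class_a, self.samples_per_class_b):
            for c, n in d.items():
                if c not in self.class_names:
                    raise SimulationError(f"samples for unknown class {c!r}")
                if n < 0:
                    raise SimulationError("samples_per_class must be >= 0")
        if self.grade_pair is not None:
            self.grade_pair = tuple(self.grade_pair)
            if len(self.grade_pair) != 2 or not set(self.grade_pair) <= set(
                self.class_names
            ):
                raise SimulationError("grade_pair must be two known class names")

    @property
    def signature_classes(self) -> tuple:
        return tuple(c for c in self.class_names if c != self.normal_class)


@dataclass
class GroundTruth:
    """What the simulator actually planted; the oracle for downstream tests."""

    signature_genes_a: dict  # class -> set of species-A gene ids
    signature_genes_b: dict  # class -> set of species-B gene ids
    ortholog_pairs: dict  # homology_type -> list of (a_gene, b_gene)
    deg_sets_a: dict  # class -> set of species-A gene ids (class vs normal)
    deg_sets_b: dict
    labels_a: dict  # sample id -> class
    labels_b: dict
    grade_genes_a: set = field(default_factory=set)
    grade_genes_b: set = field(default_factory=set)

    def to_json(self) -> str:
        def enc(d):
            return {k: sorted(v) for k, v in d.items()}

        return json.dumps(
            {
                "signature_genes_a": enc(self.signature_genes_a),
                "signature_genes_b": enc(self.signature_genes_b),
                "ortholog_pairs": {
                    k: [list(p) for p in v] for k, v in self.ortholog_pairs.items()
                },
                "deg_sets_a": enc(self.deg_sets_a),
                "deg_sets_b": enc(self.deg_sets_b),
                "labels_a": self.labels_a,
                "labels_b": self.labels_b,
                "grade_genes_a": sorted(self.grade_genes_a),
                "grade_genes_b": sorted(self.grade_genes_b),
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# deterministic structure shared by the ortholog table and both cohorts
# ---------------------------------------------------------------------------

def _structure(config: SimulationConfig) -> dict:
    """Everything derived from the seed alone, before any cohort sampling.

    Both ``generate_ortholog_table`` and ``generate_cohort`` rebuild this
    from the config so that separate calls agree on gene identities,
    baselines, batch shifts and signatures.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xA11]))
    n11 = config.n_genes_one_to_one
    w = len(str(max(n11, 1)))

    a_one = [f"GA1{i:0{w}d}" for i in range(n11)]
    b_one = [f"GB1{i:0{w}d}" for i in range(n11)]
    a_many = [f"GA2{i:04d}" for i in range(config.n_genes_one_to_many)]
    b_many = [
        f"GB2{i:04d}{suffix}"
        for i in range(config.n_genes_one_to_many)
        for suffix in ("X", "Y")
    ]
    a_only = [f"GA9{i:04d}" for i in range(config.n_genes_species_specific_a)]
    b_only = [f"GB9{i:04d}" for i in range(config.n_genes_species_specific_b)]

    n_pc = int(round(n11 * config.fraction_protein_coding))
    pc_idx = np.sort(rng.choice(n11, size=n_pc, replace=False))
    pc_mask = np.zeros(n11, dtype=bool)
    pc_mask[pc_idx] = True

    lo, hi = config.gene_length_range
    lengths = {}
    for g in a_one + a_many + a_only + b_one + b_many + b_only:
        lengths[g] = int(rng.integers(lo, hi + 1))
    # orthologous genes keep the same length on both sides (same ancestral gene)
    for ga, gb in zip(a_one, b_one):
        lengths[gb] = lengths[ga]

    # shared baseline log2 expression per ortholog unit; own draw otherwise
    base = {}
    for ga, gb in zip(a_one, b_one):
        b0 = rng.normal(0.0, config.baseline_log2_sd)
        base[ga] = b0
        base[gb] = b0
    for g in a_many + a_only + b_many + b_only:
        base[g] = rng.normal(0.0, config.baseline_log2_sd)

    # species-B batch shift per gene (species A is the reference level)
    batch_b = {
        g: rng.normal(0.0, config.species_batch_log2fc)
        for g in b_one + b_many + b_only
    }

    # signature assignment over protein-coding one-to-one pairs
    sig_classes = [
        c
        for c in config.signature_classes
        if not (config.grade_pair and c == config.grade_pair[1])
    ]
    n_sig = config.n_signature_genes_per_class
    k_shared = int(round(config.conserved_fraction * n_sig))
    k_private = n_sig - k_shared
    need = len(sig_classes) * (k_shared + 2 * k_private) + (
        config.n_grade_genes if config.grade_pair else 0
    )
    pool = [i for i in pc_idx.tolist()]
    if need > len(pool):
        raise SimulationError(
            f"not enough protein-coding one-to-one genes ({len(pool)}) for "
            f"{need} signature assignments"
        )
    pool = list(rng.permutation(pool))

    def take(k):
        taken, rest = pool[:k], pool[k:]
        del pool[:]
        pool.extend(rest)
        return taken

    effects_a: dict = {c: {} for c in config.class_names}
    effects_b: dict = {c: {} for c in config.class_names}
    sig_a: dict = {}
    sig_b: dict = {}
    lfc = config.signature_log2fc
    for c in sig_classes:
        shared = take(k_shared)
        priv_a = take(k_private)
        priv_b = take(k_private)
        for i in shared + priv_a:
            effects_a[c][a_one[i]] = lfc
        for i in shared + priv_b:
            effects_b[c][b_one[i]] = lfc
        sig_a[c] = {a_one[i] for i in shared + priv_a}
        sig_b[c] = {b_one[i] for i in shared + priv_b}

    grade_a: set = set()
    grade_b: set = set()
    if config.grade_pair:
        g1, g2 = config.grade_pair
        grade_idx = take(config.n_grade_genes)
        effects_a[g2] = dict(effects_a[g1])
        effects_b[g2] = dict(effects_b[g1])
        for i in grade_idx:
            effects_a[g2][a_one[i]] = (
                effects_a[g2].get(a_one[i], 0.0) + config.grade_delta_log2fc
            )
            effects_b[g2][b_one[i]] = (
                effects_b[g2].get(b_one[i], 0.0) + config.grade_delta_log2fc
            )
        grade_a = {a_one[i] for i in grade_idx}
        grade_b = {b_one[i] for i in grade_idx}
        sig_a[g2] = set(sig_a.get(g1, set())) | grade_a
        sig_b[g2] = set(sig_b.get(g1, set())) | grade_b

    return {
        "a_one": a_one,
        "b_one": b_one,
        "a_many": a_many,
        "b_many": b_many,
        "a_only": a_only,
        "b_only": b_only,
        "pc_mask": pc_mask,
        "lengths": lengths,
        "base": base,
        "batch_b": batch_b,
        "effects_a": effects_a,
        "effects_b": effects_b,
        "sig_a": sig_a,
        "sig_b": sig_b,
        "grade_a": grade_a,
        "grade_b": grade_b,
    }


def _annotation_for(config: SimulationConfig, st: dict, side: str) -> GeneAnnotation:
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xB10]))
    if side == "A":
        genes = st["a_one"] + st["a_many"] + st["a_only"]
        one_set = set(st["a_one"])
        pc_of_one = {g: bool(m) for g, m in zip(st["a_one"], st["pc_mask"])}
    else:
        genes = st["b_one"] + st["b_many"] + st["b_only"]
        one_set = set(st["b_one"])
        pc_of_one = {g: bool(m) for g, m in zip(st["b_one"], st["pc_mask"])}
    genes = sorted(genes)
    biotypes = []
    for g in genes:
        if g in one_set:
            biotypes.append("protein_coding" if pc_of_one[g] else "lncRNA")
        else:
            biotypes.append("protein_coding" if rng.random() < 0.7 else "lncRNA")
    return GeneAnnotation(
        gene_ids=genes,
        length_bp=np.array([st["lengths"][g] for g in genes]),
        biotype=biotypes,
    )


def generate_ortholog_table(
    config: SimulationConfig,
) -> tuple[OrthologTable, GeneAnnotation, GeneAnnotation]:
    """Build the synthetic ortholog export and both species' annotations.

    The table carries exactly the configured numbers of one-to-one and
    one-to-many rows; species-specific genes appear only in the annotations.
    The ``fraction_protein_coding`` of one-to-one pairs is protein-coding on
    the species-A (human-role) side. Deterministic under the config seed.
    """
    st = _structure(config)
    rows = []
    for i, (ga, gb) in enumerate(zip(st["a_one"], st["b_one"])):
        rows.append(
            {
                "human_gene_id": ga,
                "human_gene_name": ga.replace("G", "N", 1),
                "canine_gene_id": gb,
                "canine_gene_name": gb.replace("G", "N", 1),
                "homology_type": "ortholog_one2one",
                "pct_identity_h2c": 90.0,
                "pct_identity_c2h": 90.0,
                "gene_order_conservation_score": 100.0,
                "human_biotype": "protein_coding" if st["pc_mask"][i] else "lncRNA",
            }
        )
    for i, ga in enumerate(st["a_many"]):
        for gb in st["b_many"][2 * i : 2 * i + 2]:
            rows.append(
                {
                    "human_gene_id": ga,
                    "human_gene_name": ga.replace("G", "N", 1),
                    "canine_gene_id": gb,
                    "canine_gene_name": gb.replace("G", "N", 1),
                    "homology_type": "ortholog_one2many",
                    "pct_identity_h2c": 70.0,
                    "pct_identity_c2h": 70.0,
                    "gene_order_conservation_score": 75.0,
                    "human_biotype": "protein_coding",
                }
            )
    table = OrthologTable(frame=pd.DataFrame(rows))
    return table, _annotation_for(config, st, "A"), _annotation_for(config, st, "B")


def generate_cohort(
    config: SimulationConfig, species: str
) -> tuple[ExpressionMatrix, SampleLabels, GroundTruth]:
    """Draw a counts cohort for one species under the shared structure.

    ``species`` is ``'synthetic-A'`` (human role) or ``'synthetic-B'``
    (canine role). Mean counts follow
    ``mu_gs = L_g * 2**(base_g + class_effect + batch_g)`` rescaled so each
    sample's total equals a log-normal library size; counts are
    gamma-Poisson with the configured dispersion. Deterministic under seed.
    """
    if species not in (SPECIES_A, SPECIES_B):
        raise SimulationError(f"species must be {SPECIES_A!r} or {SPECIES_B!r}")
    side = "A" if species == SPECIES_A else "B"
    per_class = (
        config.samples_per_class_a if side == "A" else config.samples_per_class_b
    )
    if not any(n > 0 for n in per_class.values()):
        raise SimulationError(f"species {species!r} has no samples configured")

    st = _structure(config)
    if side == "A":
        genes = sorted(st["a_one"] + st["a_many"] + st["a_only"])
        effects = st["effects_a"]
        batch = {g: 0.0 for g in genes}
    else:
        genes = sorted(st["b_one"] + st["b_many"] + st["b_only"])
        effects = st["effects_b"]
        batch = st["batch_b"]

    length_kb = np.array([st["lengths"][g] for g in genes]) / 1000.0
    base = np.array([st["base"][g] for g in genes])
    batch_arr = np.array([batch.get(g, 0.0) for g in genes])
    gidx = {g: i for i, g in enumerate(genes)}

    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    class_of_sample: list[str] = []
    for c in config.class_names:
        for k in range(per_class.get(c, 0)):
            sid = f"{side}_{c}_{k:03d}"
            sample_ids.append(sid)
            labels[sid] = c
            class_of_sample.append(c)

    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 0xC0, 0 if side == "A" else 1])
    )
    n_g, n_s = len(genes), len(sample_ids)
    counts = np.empty((n_g, n_s), dtype=float)
    class_effect_vec = {}
    for c in config.class_names:
        vec = np.zeros(n_g)
        for g, e in effects.get(c, {}).items():
            vec[gidx[g]] = e
        class_effect_vec[c] = vec
    lib_sizes = config.library_size * np.exp(
        rng.normal(0.0, config.library_size_sigma, size=n_s)
    )
    inv_disp = 1.0 / config.nb_dispersion
    for j, c in enumerate(class_of_sample):
        mu = length_kb * np.exp2(base + batch_arr + class_effect_vec[c])
        mu *= lib_sizes[j] / mu.sum()
        lam = rng.gamma(shape=inv_disp, scale=mu * config.nb_dispersion)
        counts[:, j] = rng.poisson(lam)

    matrix = ExpressionMatrix(
        gene_ids=genes,
        sample_ids=sample_ids,
        values=counts,
        unit="counts",
        species=species,
    )
    truth = GroundTruth(
        signature_genes_a=st["sig_a"],
        signature_genes_b=st["sig_b"],
        ortholog_pairs={
            "ortholog_one2one": list(zip(st["a_one"], st["b_one"])),
            "ortholog_one2many": [
                (ga, gb)
                for i, ga in enumerate(st["a_many"])
                for gb in st["b_many"][2 * i : 2 * i + 2]
            ],
        },
        deg_sets_a=st["sig_a"],
        deg_sets_b=st["sig_b"],
        labels_a=labels if side == "A" else {},
        labels_b=labels if side == "B" else {},
        grade_genes_a=st["grade_a"],
        grade_genes_b=st["grade_b"],
    )
    return matrix, SampleLabels(labels=dict(labels)), truth


# ---------------------------------------------------------------------------
# nonlinear (XOR) single-species cohort for model-family comparisons
# ---------------------------------------------------------------------------

def generate_xor_cohort(
    n_per_class: int = 150,
    n_genes: int = 400,
    block_size: int = 20,
    effect_log2fc: float = 3.0,
    block_base_log2: float = -2.5,
    nb_dispersion: float = 0.1,
    gene_length_range: tuple = (300, 20000),
    seed: int = 0,
    species: str = SPECIES_A,
) -> tuple[ExpressionMatrix, SampleLabels, GeneAnnotation]:
    """Two-class cohort whose label is the XOR of two latent signature blocks.

    Each sample carries two hidden binary factors; block-1 genes are elevated
    when the first factor is on, block-2 genes when the second is on, and the
    class is the parity of the two factors. Block genes then have identical
    class-conditional marginals, so a linear model has no signal while a
    nonlinear model can recover the interaction. ``block_base_log2`` lowers
    the blocks' baseline so they carry little library mass — otherwise the
    per-sample TPM renormalization leaks a compositional (linear) signal
    through the background genes.
    """
    if n_genes < 2 * block_size + 2:
        raise SimulationError("n_genes too small for two blocks")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD0]))
    w = len(str(n_genes))
    block1 = [f"GX1{i:0{w}d}" for i in range(block_size)]
    block2 = [f"GX2{i:0{w}d}" for i in range(block_size)]
    rest = [f"GX9{i:0{w}d}" for i in range(n_genes - 2 * block_size)]
    genes = sorted(block1 + block2 + rest)
    gidx = {g: i for i, g in enumerate(genes)}
    lo, hi = gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    length_kb = lengths / 1000.0
    base = rng.normal(0.0, 1.0, size=n_genes)
    for g in block1 + block2:
        base[gidx[g]] += block_base_log2

    # balanced latent factor combinations: class 'even' <- {(0,0),(1,1)},
    # class 'odd' <- {(0,1),(1,0)}
    combos = []
    for z1, z2 in ((0, 0), (1, 1)):
        combos += [(z1, z2)] * math.ceil(n_per_class / 2)
    combos = combos[:n_per_class]
    for z1, z2 in ((0, 1), (1, 0)):
        combos += [(z1, z2)] * math.ceil(n_per_class / 2)
    combos = combos[: 2 * n_per_class]

    sample_ids, labels = [], {}
    counts = np.empty((n_genes, len(combos)))
    b1 = np.zeros(n_genes)
    b2 = np.zeros(n_genes)
    for g in block1:
        b1[gidx[g]] = effect_log2fc
    for g in block2:
        b2[gidx[g]] = effect_log2fc
    inv_disp = 1.0 / nb_dispersion
    for j, (z1, z2) in enumerate(combos):
        cls = "odd" if z1 ^ z2 else "even"
        sid = f"X_{cls}_{j:03d}"
        sample_ids.append(sid)
        labels[sid] = cls
        mu = length_kb * np.exp2(base + z1 * b1 + z2 * b2)
        mu *= 1.0e6 / mu.sum()
        lam = rng.gamma(shape=inv_disp, scale=mu * nb_dispersion)
        counts[:, j] = rng.poisson(lam)

    matrix = ExpressionMatrix(
        gene_ids=genes,
        sample_ids=sample_ids,
        values=counts,
        unit="counts",
        species=species,
    )
    annotation = GeneAnnotation(
        gene_ids=genes,
        length_bp=lengths,
        biotype=["protein_coding"] * n_genes,
    )
    return matrix, SampleLabels(labels=labels), annotation


def write_simulation(config: SimulationConfig, out_dir) -> dict:
    """Write counts, labels, ortholog table, annotations and ground truth.

    Returns the mapping of artifact name to path. Used by the ``simulate``
    CLI subcommand.
    """
    from orthoclass.datamodel import (
        write_expression_matrix,
        write_gene_annotation,
        write_sample_labels,
    )
    from orthoclass.orthology import write_ortholog_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, ann_a, ann_b = generate_ortholog_table(config)
    paths = {}
    write_ortholog_table(table, out / "orthologs.tsv")
    paths["orthologs"] = out / "orthologs.tsv"
    write_gene_annotation(ann_a, out / "annotation_A.tsv")
    write_gene_annotation(ann_b, out / "annotation_B.tsv")
    paths["annotation_A"] = out / "annotation_A.tsv"
    paths["annotation_B"] = out / "annotation_B.tsv"
    truth = None
    for species, tag, per_class in (
        (SPECIES_A, "A", config.samples_per_class_a),
        (SPECIES_B, "B", config.samples_per_class_b),
    ):
        if not any(n > 0 for n in per_class.values()):
            continue
        matrix, labels, truth_s = generate_cohort(config, species)
        write_expression_matrix(matrix, out / f"counts_{tag}.tsv")
        write_sample_labels(labels, out / f"labels_{tag}.tsv")
        paths[f"counts_{tag}"] = out / f"counts_{tag}.tsv"
        paths[f"labels_{tag}"] = out / f"labels_{tag}.tsv"
        if truth is None:
            truth = truth_s
        else:
            truth.labels_a.update(truth_s.labels_a)
            truth.labels_b.update(truth_s.labels_b)
    (out / "ground_truth.json").write_text(truth.to_json())
    paths["ground_truth"] = out / "ground_truth.json"
    return paths
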