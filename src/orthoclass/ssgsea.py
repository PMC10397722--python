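"""Single-sample gene-set enrichment scoring with permutation significance.

Per sample, genes are ranked by expression (descending; ties get average
ranks and are then ordered stably by gene id) and a running sum accumulates
the weighted ECDF of set members — member weights ``rank^alpha`` — minus the
uniform ECDF of non-members. The score is the sum of the running-sum values
(integrated deviation), so it depends only on ranks: any strictly monotone
transform of a sample's expression leaves its scores unchanged.

Significance uses size-matched random gene sets drawn from the matrix's gene
universe (a per-sample score admits no label permutation), a plus-one
permutation p-value, and Benjamini–Hochberg adjustment across all
(sample, set) pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from orthoclass.datamodel import ExpressionMatrix, GeneSetCollection, SampleLabels

logger = logging.getLogger(__name__)


class SsgseaError(ValueError):
    pass


@dataclass
class SsgseaConfig:
    """Rank-weight exponent, permutation count, seed, score normalization."""

    alpha: float = 0.25
    n_permutations: int = 1000
    seed: int = 0
    normalize_scores: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise SsgseaError("alpha must be >= 0")
        if self.n_permutations < 1:
            raise SsgseaError("n_permutations must be >= 1")


@dataclass
class SsgseaResult:
    """Sample × gene-set scores with permutation p-values and BH FDR."""

    sample_ids: list[str]
    set_names: list[str]
    scores: np.ndarray  # (n_samples, n_sets)
    pvalues: np.ndarray
    fdr: np.ndarray
    config: SsgseaConfig = field(default_factory=SsgseaConfig)

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}


def _order_and_weights(
    col: np.ndarray, gene_ids: list[str], alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Descending expression order (stable by gene id) and rank^alpha weights."""
    ranks = rankdata(col, method="average")  # 1 = lowest expression
    order = sorted(range(len(col)), key=lambda i: (-col[i], gene_ids[i]))
    order = np.asarray(order)
    return order, np.abs(ranks[order]) ** alpha


def _es(weights: np.ndarray, member_mask: np.ndarray) -> float:
    """Integrated running-sum deviation for one (sample, set) instance."""
    w_in = weights * member_mask
    denom_in = w_in.sum()
    n_out = (~member_mask).sum()
    p_in = np.cumsum(w_in) / denom_in
    p_out = np.cumsum(~member_mask) / n_out
    return float(np.sum(p_in - p_out))


def _resolve_sets(
    matrix: ExpressionMatrix, gene_sets: GeneSetCollection
) -> dict[str, np.ndarray]:
    index = matrix.gene_index()
    n = matrix.n_genes
    resolved = {}
    for name in gene_sets.names():
        members = [index[g] for g in gene_sets[name] if g in index]
        if len(members) < 2:
            logger.warning(
                "gene set %r has %d member(s) present in the matrix; skipped",
                name, len(members),
            )
            continue
        if len(members) == n:
            raise SsgseaError(
                f"gene set {name!r} covers every gene; non-member ECDF undefined"
            )
        mask = np.zeros(n, dtype=bool)
        mask[members] = True
        resolved[name] = mask
    return resolved


def ssgsea_score(
    matrix: ExpressionMatrix, gene_sets: GeneSetCollection, config: SsgseaConfig
) -> tuple[np.ndarray, list[str]]:
    """Score every (sample, set) pair; returns (samples × sets array, set names)."""
    if matrix.unit not in ("tpm", "log10_tpm", "counts", "fpkm_uq"):
        raise SsgseaError(f"unsupported unit {matrix.unit!r}")
    resolved = _resolve_sets(matrix, gene_sets)
    if not resolved:
        raise SsgseaError("no evaluable gene set (need >= 2 present members each)")
    names = list(resolved)
    scores = np.empty((matrix.n_samples, len(names)))
    for j in range(matrix.n_samples):
        order, weights = _order_and_weights(
            matrix.values[:, j], matrix.gene_ids, config.alpha
        )
        for s, name in enumerate(names):
            scores[j, s] = _es(weights, resolved[name][order])
    if config.normalize_scores and scores.size:
        rng_range = scores.max() - scores.min()
        if rng_range > 0:
            scores = scores / rng_range
    return scores, names


def ssgsea_significance(
    matrix: ExpressionMatrix, gene_sets: GeneSetCollection, config: SsgseaConfig
) -> SsgseaResult:
    """Permutation p-values from size-matched random gene sets, then BH FDR.

    p = (1 + #{|null| >= |observed|}) / (n_permutations + 1), so p is never 0.
    Deterministic under the config seed.
    """
    if config.n_permutations < 100:
        raise SsgseaError("significance calls need n_permutations >= 100")
    resolved = _resolve_sets(matrix, gene_sets)
    if not resolved:
        raise SsgseaError("no evaluable gene set (need >= 2 present members each)")
    names = list(resolved)
    sizes = sorted({int(resolved[n].sum()) for n in names})
    n_genes = matrix.n_genes
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x55]))
    # one shared bank of random member masks per set size (gene-sampling null)
    null_masks = {
        size: np.stack(
            [
                np.isin(
                    np.arange(n_genes),
                    rng.choice(n_genes, size=size, replace=False),
                )
                for _ in range(config.n_permutations)
            ]
        )
        for size in sizes
    }
    scores = np.empty((matrix.n_samples, len(names)))
    pvalues = np.empty_like(scores)
    for j in range(matrix.n_samples):
        order, weights = _order_and_weights(
            matrix.values[:, j], matrix.gene_ids, config.alpha
        )
        null_cache = {}
        for size in sizes:
            null_cache[size] = np.array(
                [_es(weights, mask[order]) for mask in null_masks[size]]
            )
        for s, name in enumerate(names):
            obs = _es(weights, resolved[name][order])
            scores[j, s] = obs
            null = null_cache[int(resolved[name].sum())]
            exceed = int(np.sum(np.abs(null) >= abs(obs)))
            pvalues[j, s] = (1 + exceed) / (config.n_permutations + 1)
    fdr = multipletests(pvalues.ravel(), method="fdr_bh")[1].reshape(pvalues.shape)
    if config.normalize_scores and scores.size:
        rng_range = scores.max() - scores.min()
        if rng_range > 0:
            scores = scores / rng_range
    return SsgseaResult(
        sample_ids=list(matrix.sample_ids),
        set_names=names,
        scores=scores,
        pvalues=pvalues,
        fdr=fdr,
        config=config,
    )


def select_enriched(
    result: SsgseaResult,
    fdr_threshold: float = 0.05,
    sample_fraction: float = 2.0 / 3.0,
    group: list[str] | None = None,
) -> list[str]:
    """Sets significant (FDR < threshold) in at least ceil(fraction·|group|)
    samples of the group."""
    if group is None:
        group = list(result.sample_ids)
    if not group:
        raise SsgseaError("empty sample group")
    index = result.sample_index()
    missing = [s for s in group if s not in index]
    if missing:
        raise SsgseaError(f"sample {missing[0]!r} not in the ssGSEA result")
    rows = [index[s] for s in group]
    needed = math.ceil(sample_fraction * len(group))
    hits = (result.fdr[rows, :] < fdr_threshold).sum(axis=0)
    return [name for name, h in zip(result.set_names, hits) if h >= needed]


def subsample_groups(labels: SampleLabels, per_group_n: int, seed: int) -> list[str]:
    """Pick exactly ``per_group_n`` samples per class label, deterministically."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B]))
    by_class: dict[str, list[str]] = {}
    for sid, lab in labels.labels.items():
        by_class.setdefault(lab, []).append(sid)
    chosen: list[str] = []
    for lab in sorted(by_class):
        members = sorted(by_class[lab])
        if len(members) < per_group_n:
            raise SsgseaError(
                f"group {lab!r} has {len(members)} sample(s), need {per_group_n}"
            )
        take = rng.choice(len(members), size=per_group_n, replace=False)
        chosen.extend(members[i] for i in sorted(take))
    return chosen
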