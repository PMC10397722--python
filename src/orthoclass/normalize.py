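"""Unit conversions along the chain counts → FPKM-UQ → TPM → log10(TPM).

All conversions preserve gene/sample ordering and ids bit-exactly; only the
values and the unit tag change. TPM is defined so each sample column sums to
1e6; FPKM-UQ → TPM is a pure per-sample renormalization (gene length and the
upper-quartile factor cancel).
"""

from __future__ import annotations

import logging

import numpy as np

from orthoclass.datamodel import DataModelError, ExpressionMatrix, GeneAnnotation

logger = logging.getLogger(__name__)

TPM_SUM = 1.0e6


class NormalizationError(ValueError):
    pass


def _lengths_kb(matrix: ExpressionMatrix, annotation: GeneAnnotation) -> np.ndarray:
    length_of = annotation.length_of()
    missing = [g for g in matrix.gene_ids if g not in length_of]
    if missing:
        raise NormalizationError(
            f"{len(missing)} gene(s) missing from annotation, e.g. {missing[:5]}"
        )
    return np.array([length_of[g] for g in matrix.gene_ids], dtype=float) / 1000.0


def counts_to_tpm(matrix: ExpressionMatrix, annotation: GeneAnnotation) -> ExpressionMatrix:
    """Convert raw counts to TPM: per-kilobase rates renormalized to 1e6 per sample."""
    if matrix.unit != "counts":
        raise NormalizationError(f"expected unit 'counts', got {matrix.unit!r}")
    zero = np.flatnonzero(matrix.values.sum(axis=0) == 0)
    if zero.size:
        raise NormalizationError(
            f"sample {matrix.sample_ids[zero[0]]!r} has all-zero counts"
        )
    rates = matrix.values / _lengths_kb(matrix, annotation)[:, None]
    tpm = rates * (TPM_SUM / rates.sum(axis=0))
    return matrix.with_values(tpm, "tpm")


def counts_to_fpkm_uq(
    matrix: ExpressionMatrix, annotation: GeneAnnotation
) -> ExpressionMatrix:
    """Convert raw counts to FPKM-UQ.

    Per sample: ``rate_g = count_g / length_kb_g`` and
    ``FPKM-UQ_g = rate_g * 1e6 / UQ`` where UQ is the 75th percentile of
    counts over protein-coding genes with nonzero counts in that sample
    (falls back to all nonzero genes, with a warning, if no protein-coding
    gene is expressed). Any positive per-sample scalar would cancel in the
    downstream TPM renormalization; this definition mirrors the upper-quartile
    convention.
    """
    if matrix.unit != "counts":
        raise NormalizationError(f"expected unit 'counts', got {matrix.unit!r}")
    zero = np.flatnonzero(matrix.values.sum(axis=0) == 0)
    if zero.size:
        raise NormalizationError(
            f"sample {matrix.sample_ids[zero[0]]!r} has all-zero counts"
        )
    biotype_of = annotation.biotype_of()
    pc_mask = np.array(
        [biotype_of.get(g) == "protein_coding" for g in matrix.gene_ids], dtype=bool
    )
    rates = matrix.values / _lengths_kb(matrix, annotation)[:, None]
    out = np.empty_like(rates)
    for j in range(matrix.n_samples):
        col = matrix.values[:, j]
        expressed = pc_mask & (col > 0)
        if not expressed.any():
            logger.warning(
                "sample %r has no expressed protein-coding gene; "
                "using all nonzero genes for the upper quartile",
                matrix.sample_ids[j],
            )
            expressed = col > 0
        uq = float(np.percentile(col[expressed], 75))
        out[:, j] = rates[:, j] * (TPM_SUM / uq)
    return matrix.with_values(out, "fpkm_uq")


def fpkm_uq_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Renormalize FPKM-UQ (or TPM) columns to sum to 1e6; idempotent on TPM."""
    if matrix.unit not in ("fpkm_uq", "tpm"):
        raise NormalizationError(
            f"expected unit 'fpkm_uq' (or 'tpm'), got {matrix.unit!r}"
        )
    sums = matrix.values.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise NormalizationError(
            f"sample {matrix.sample_ids[zero[0]]!r} has zero column sum"
        )
    return matrix.with_values(matrix.values * (TPM_SUM / sums), "tpm")


def log10_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise ``log10(value + pseudocount)`` of a TPM matrix.

    The pseudocount defaults to 1 so that TPM 0 maps to 0; it is configurable
    because the original preprocessing leaves the offset unstated.
    """
    if matrix.unit != "tpm":
        raise NormalizationError(f"expected unit 'tpm', got {matrix.unit!r}")
    if pseudocount <= 0:
        raise NormalizationError("pseudocount must be > 0")
    return matrix.with_values(np.log10(matrix.values + pseudocount), "log10_tpm")
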