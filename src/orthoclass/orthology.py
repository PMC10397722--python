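"""Ortholog-table parsing, the two-stage feature filter, and feature projection.

The feature axis shared by all models is built in two stages: keep strict
one-to-one ortholog pairs, then keep pairs whose human gene is protein-coding.
Features are ordered lexicographically by human gene id; a canine-side gene
maps into the axis through the bijective canine → feature-index map.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass

import pandas as pd

from orthoclass.datamodel import (
    CANINE_SIDE,
    HUMAN_SIDE,
    DataModelError,
    ExpressionMatrix,
    GeneAnnotation,
)

logger = logging.getLogger(__name__)

HOMOLOGY_TYPES = ("ortholog_one2one", "ortholog_one2many", "ortholog_many2many")

REQUIRED_COLUMNS = (
    "human_gene_id",
    "human_gene_name",
    "canine_gene_id",
    "canine_gene_name",
    "homology_type",
)

OPTIONAL_COLUMNS = (
    "pct_identity_h2c",
    "pct_identity_c2h",
    "gene_order_conservation_score",
    "human_biotype",
)

#: Default header-name mapping from a biomaRt export to canonical columns.
BIOMART_COLUMN_MAP = {
    "Gene stable ID": "human_gene_id",
    "Gene name": "human_gene_name",
    "Dog gene stable ID": "canine_gene_id",
    "Dog gene name": "canine_gene_name",
    "Dog homology type": "homology_type",
    "%id. target Dog gene identical to query gene": "pct_identity_h2c",
    "%id. query gene identical to target Dog gene": "pct_identity_c2h",
    "Dog Gene-order conservation score": "gene_order_conservation_score",
    "Gene type": "human_biotype",
}

_VERSION_SUFFIX = re.compile(r"\.\d+$")


class OrthologyError(ValueError):
    pass


def strip_version(gene_id: str) -> str:
    """Drop a trailing Ensembl version suffix ('.NN') from a gene id."""
    return _VERSION_SUFFIX.sub("", str(gene_id))


@dataclass
class OrthologTable:
    """A parsed ortholog export; thin wrapper over a canonical DataFrame."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        for col in REQUIRED_COLUMNS:
            if col not in self.frame.columns:
                raise OrthologyError(f"ortholog table missing column {col!r}")
        for col in OPTIONAL_COLUMNS:
            if col not in self.frame.columns:
                self.frame[col] = pd.NA
        bad = set(self.frame["homology_type"].dropna()) - set(HOMOLOGY_TYPES)
        if bad:
            raise OrthologyError(
                f"unknown homology type(s) {sorted(bad)}; expected {HOMOLOGY_TYPES}"
            )
        if self.frame.duplicated().any():
            raise OrthologyError("ortholog table contains fully duplicated rows")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class FeatureSpace:
    """The ordered human-gene feature axis and its canine-side bijection."""

    human_ids: tuple
    canine_ids: tuple  # canine_ids[i] pairs with human_ids[i]

    def __post_init__(self) -> None:
        if not self.human_ids:
            raise OrthologyError("empty feature space")
        if len(self.human_ids) != len(self.canine_ids):
            raise OrthologyError("human/canine id lists differ in length")
        if list(self.human_ids) != sorted(self.human_ids):
            raise OrthologyError("feature ids must be sorted lexicographically")
        if len(set(self.human_ids)) != len(self.human_ids):
            raise OrthologyError("duplicate human gene ids in feature space")
        if len(set(self.canine_ids)) != len(self.canine_ids):
            raise OrthologyError("duplicate canine gene ids in feature space")

    def __len__(self) -> int:
        return len(self.human_ids)

    @property
    def canine_to_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.canine_ids)}

    @property
    def human_to_index(self) -> dict[str, int]:
        return {h: i for i, h in enumerate(self.human_ids)}

    def fingerprint(self) -> str:
        """Hash of the ordered human feature ids; guards model/matrix alignment."""
        h = hashlib.sha256("\n".join(self.human_ids).encode())
        return h.hexdigest()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"human_gene_id": self.human_ids, "canine_gene_id": self.canine_ids}
        )


def read_ortholog_table(path, column_map: dict | None = None) -> OrthologTable:
    """Read a biomaRt-style ortholog TSV; header-name matched, order-free.

    Ensembl version suffixes are stripped from gene ids on ingest: GDC
    matrices and biomaRt exports disagree on versioning, so matching must be
    on stable ids. ``column_map`` maps file headers to canonical column
    names; canonical headers are accepted as-is.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping = dict(BIOMART_COLUMN_MAP)
    if column_map:
        mapping.update(column_map)
    df = df.rename(columns={k: v for k, v in mapping.items() if k in df.columns})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise OrthologyError(f"{path}: missing required column {col!r}")
    df = df.dropna(subset=["human_gene_id", "canine_gene_id", "homology_type"])
    df["human_gene_id"] = df["human_gene_id"].map(strip_version)
    df["canine_gene_id"] = df["canine_gene_id"].map(strip_version)
    for col in ("pct_identity_h2c", "pct_identity_c2h", "gene_order_conservation_score"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.drop_duplicates().reset_index(drop=True)
    return OrthologTable(frame=df)


def filter_one_to_one(table: OrthologTable) -> OrthologTable:
    """Keep strict one-to-one pairs.

    A row survives when its homology type is ``ortholog_one2one`` AND its
    human id appears exactly once AND its canine id appears exactly once
    among the type-filtered rows. The uniqueness re-check guards against
    label inconsistencies in real exports; the operation is idempotent.
    """
    df = table.frame
    kept = df[df["homology_type"] == "ortholog_one2one"]
    h_counts = kept["human_gene_id"].value_counts()
    c_counts = kept["canine_gene_id"].value_counts()
    mask = kept["human_gene_id"].map(h_counts).eq(1) & kept["canine_gene_id"].map(
        c_counts
    ).eq(1)
    return OrthologTable(frame=kept[mask].reset_index(drop=True))


def filter_protein_coding(
    table: OrthologTable, human_annotation: GeneAnnotation | None = None
) -> OrthologTable:
    """Keep pairs whose human gene is protein-coding.

    The annotation is authoritative over the table's own ``human_biotype``
    column when both are present; a human gene absent from the annotation
    drops its row with a logged warning (not an error).
    """
    df = table.frame
    if human_annotation is not None:
        biotype_of = human_annotation.biotype_of()
        present = df["human_gene_id"].isin(biotype_of)
        n_missing = int((~present).sum())
        if n_missing:
            logger.warning(
                "%d ortholog row(s) dropped: human gene absent from annotation",
                n_missing,
            )
        df = df[present]
        keep = df["human_gene_id"].map(biotype_of).eq("protein_coding")
    else:
        keep = df["human_biotype"].eq("protein_coding")
    return OrthologTable(frame=df[keep].reset_index(drop=True))


def build_feature_space(table: OrthologTable) -> FeatureSpace:
    """Build the ordered feature axis from a fully filtered ortholog table."""
    df = table.frame
    if df.empty:
        raise OrthologyError("cannot build a feature space from an empty table")
    if df["human_gene_id"].duplicated().any() or df["canine_gene_id"].duplicated().any():
        raise OrthologyError(
            "duplicate gene ids in filtered table (apply filter_one_to_one first, "
            "or ids collided after version-suffix stripping)"
        )
    ordered = df.sort_values("human_gene_id", kind="mergesort")
    return FeatureSpace(
        human_ids=tuple(ordered["human_gene_id"]),
        canine_ids=tuple(ordered["canine_gene_id"]),
    )


def project_to_feature_space(
    matrix: ExpressionMatrix, feature_space: FeatureSpace
) -> ExpressionMatrix:
    """Reindex a matrix onto the feature axis, renamed to human gene ids.

    Human-side input selects rows by human id; canine-side input selects
    through the canine → index map. Any feature whose source gene is absent
    from the input is an error (no silent zero-fill: a zero in log-TPM space
    is a strong spurious signal). Sample order and selected values are
    preserved bit-exactly.
    """
    if matrix.unit not in ("tpm", "log10_tpm"):
        raise OrthologyError(
            f"projection expects unit 'tpm' or 'log10_tpm', got {matrix.unit!r}"
        )
    if matrix.species in HUMAN_SIDE:
        wanted = list(feature_space.human_ids)
    elif matrix.species in CANINE_SIDE:
        wanted = list(feature_space.canine_ids)
    else:  # pragma: no cover - species validated upstream
        raise OrthologyError(f"unknown species {matrix.species!r}")
    index = matrix.gene_index()
    missing = [g for g in wanted if g not in index]
    if missing:
        raise OrthologyError(
            f"{len(missing)} feature gene(s) absent from input matrix "
            f"(first {min(len(missing), 20)}): {missing[:20]}"
        )
    rows = [index[g] for g in wanted]
    return ExpressionMatrix(
        gene_ids=list(feature_space.human_ids),
        sample_ids=list(matrix.sample_ids),
        values=matrix.values[rows, :],
        unit=matrix.unit,
        species=matrix.species,
    )


def write_ortholog_table(table: OrthologTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def write_feature_space(feature_space: FeatureSpace, path) -> None:
    feature_space.to_frame().to_csv(path, sep="\t", index=False)


def read_feature_space(path) -> FeatureSpace:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("human_gene_id", "canine_gene_id"):
        if col not in df.columns:
            raise OrthologyError(f"{path}: missing column {col!r}")
    df = df.sort_values("human_gene_id", kind="mergesort")
    return FeatureSpace(
        human_ids=tuple(df["human_gene_id"]), canine_ids=tuple(df["canine_gene_id"])
    )
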