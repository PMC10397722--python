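"""Core data types and file I/O for every format the pipeline touches.

Expression matrices are genes-in-rows, samples-in-columns TSV files with an
optional ``#unit=`` / ``#species=`` comment header; units are carried as
explicit metadata and are never inferred from values (TPM and FPKM-UQ are
numerically indistinguishable). Unit transitions happen only in
:mod:`orthoclass.normalize` — readers never silently convert.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Valid expression units. ``tpm`` columns must sum to 1e6.
UNITS = ("counts", "fpkm_uq", "tpm", "log10_tpm")

#: Valid species tags. ``synthetic-A`` plays the human (source) role and
#: ``synthetic-B`` the canine (target) role in simulated cohorts.
SPECIES = ("human", "canine", "synthetic-A", "synthetic-B")

#: Species tags whose gene ids live in the human-side namespace.
HUMAN_SIDE = frozenset({"human", "synthetic-A"})
#: Species tags whose gene ids live in the canine-side namespace.
CANINE_SIDE = frozenset({"canine", "synthetic-B"})

TPM_SUM = 1.0e6
TPM_RTOL = 1.0e-6


class DataModelError(ValueError):
    """Raised when a file or in-memory structure violates an invariant."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise DataModelError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A genes × samples expression matrix with declared unit and species.

    Parameters
    ----------
    gene_ids : list of str
        Ordered, unique, species-namespaced gene identifiers (rows).
    sample_ids : list of str
        Ordered, unique sample identifiers (columns).
    values : ndarray of shape (n_genes, n_samples)
    unit : {'counts', 'fpkm_uq', 'tpm', 'log10_tpm'}
    species : {'human', 'canine', 'synthetic-A', 'synthetic-B'}
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: str
    species: str

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataModelError("values must be a 2-D genes × samples array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataModelError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples"
            )
        if self.unit not in UNITS:
            raise DataModelError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.species not in SPECIES:
            raise DataModelError(
                f"unknown species {self.species!r}; expected one of {SPECIES}"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataModelError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r} (missing values are not permitted)"
            )
        if self.unit in ("counts", "fpkm_uq", "tpm") and self.values.size:
            neg = np.argwhere(self.values < 0)
            if neg.size:
                g, s = neg[0]
                raise DataModelError(
                    f"negative value under unit {self.unit!r} at gene "
                    f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
                )
        if self.unit == "tpm" and self.values.size:
            sums = self.values.sum(axis=0)
            bad = np.abs(sums - TPM_SUM) > TPM_RTOL * TPM_SUM
            if bad.any():
                j = int(np.argmax(bad))
                raise DataModelError(
                    f"tpm column {self.sample_ids[j]!r} sums to {sums[j]:.6g}, "
                    f"expected {TPM_SUM:g} within relative tolerance {TPM_RTOL:g}"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, cols],
            unit=self.unit,
            species=self.species,
        )

    def with_values(self, values: np.ndarray, unit: str) -> "ExpressionMatrix":
        """Same axes, new values and unit (used by the normalize module)."""
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            values=values,
            unit=unit,
            species=self.species,
        )


@dataclass
class GeneAnnotation:
    """Per-gene annotation: union-exon length (bp) and biotype.

    ``protein_coding`` is the distinguished biotype value used by the
    orthology filter. Gene ids must be unique within a species.
    """

    gene_ids: list[str]
    length_bp: np.ndarray
    biotype: list[str]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.length_bp = np.asarray(self.length_bp, dtype=np.int64)
        self.biotype = [str(b) for b in self.biotype]
        if not (len(self.gene_ids) == len(self.length_bp) == len(self.biotype)):
            raise DataModelError("annotation column lengths differ")
        _check_unique(self.gene_ids, "annotation gene")
        if self.length_bp.size and self.length_bp.min() < 1:
            bad = self.gene_ids[int(np.argmin(self.length_bp))]
            raise DataModelError(f"gene {bad!r} has length_bp < 1")

    def length_of(self) -> dict[str, int]:
        return dict(zip(self.gene_ids, self.length_bp.tolist()))

    def biotype_of(self) -> dict[str, str]:
        return dict(zip(self.gene_ids, self.biotype))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "length_bp": self.length_bp, "biotype": self.biotype}
        )


@dataclass
class SampleLabels:
    """Mapping from sample id to class label (e.g. BLCA, LGG, GBM, HGG)."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.labels = {str(k): str(v) for k, v in self.labels.items()}

    def __getitem__(self, sample_id: str) -> str:
        return self.labels[sample_id]

    def __len__(self) -> int:
        return len(self.labels)

    def classes(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def for_samples(self, sample_ids: list[str]) -> list[str]:
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise DataModelError(f"unlabeled sample ids: {missing[:20]}")
        return [self.labels[s] for s in sample_ids]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, ordered as read."""

    sets: dict[str, set] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not name:
                raise DataModelError("empty gene-set name")
            if any(not m for m in members):
                raise DataModelError(f"gene set {name!r} contains an empty member id")

    def names(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, name: str) -> set:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_header_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def read_expression_matrix(
    path, unit: str | None = None, species: str | None = None
) -> ExpressionMatrix:
    """Read a genes × samples TSV/CSV into a validated :class:`ExpressionMatrix`.

    The first non-comment row is the header (``gene_id`` then sample ids).
    ``#unit=`` / ``#species=`` comment lines supply metadata when the
    ``unit`` / ``species`` arguments are not given; explicit arguments win.
    The unit is recorded as declared, never inferred from values.
    """
    path = Path(path)
    meta = _read_header_meta(path)
    unit = unit or meta.get("unit")
    species = species or meta.get("species")
    if unit is None:
        raise DataModelError(f"{path}: no unit declared (argument or '#unit=' header)")
    if species is None:
        raise DataModelError(
            f"{path}: no species declared (argument or '#species=' header)"
        )
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(
        path, sep=sep, comment="#", dtype={0: str}, float_precision="round_trip"
    )
    gene_col = df.columns[0]
    gene_ids = df[gene_col].tolist()
    dupes = pd.Series(gene_ids)[pd.Series(gene_ids).duplicated()]
    if len(dupes):
        raise DataModelError(f"{path}: duplicate gene id {dupes.iloc[0]!r}")
    values = df.drop(columns=[gene_col]).to_numpy(dtype=float)
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=[str(c) for c in df.columns[1:]],
        values=values,
        unit=unit,
        species=species,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV with ``#unit=`` / ``#species=`` header comments.

    Round-trips through :func:`read_expression_matrix` bit-identically on
    metadata and to better than 1e-12 relative on values (full ``repr``
    precision is written).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#unit={matrix.unit}\n")
        fh.write(f"#species={matrix.species}\n")
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Parse an MSigDB-dialect GMT file (name, description, member ids).

    Duplicate member ids within a line are deduplicated with a logged
    warning; a duplicate set name or a line with fewer than 3 fields is an
    error citing the line number.
    """
    path = Path(path)
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataModelError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, desc, *members = fields
            if name in sets:
                raise DataModelError(
                    f"{path}:{lineno}: duplicate gene-set name {name!r}"
                )
            members = [m for m in members if m]
            unique: list[str] = []
            seen: set = set()
            for m in members:
                if m in seen:
                    continue
                seen.add(m)
                unique.append(m)
            if len(unique) < len(members):
                logger.warning(
                    "%s:%d: %d duplicate member id(s) in set %r deduplicated",
                    path, lineno, len(members) - len(unique), name,
                )
            sets[name] = set(unique)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + sorted(collection[name])) + "\n")


def read_gene_annotation(path) -> GeneAnnotation:
    """Read a gene annotation TSV with columns gene_id, length_bp, biotype."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    for col in ("gene_id", "length_bp", "biotype"):
        if col not in df.columns:
            raise DataModelError(f"{path}: missing annotation column {col!r}")
    return GeneAnnotation(
        gene_ids=df["gene_id"].tolist(),
        length_bp=df["length_bp"].to_numpy(),
        biotype=df["biotype"].tolist(),
    )


def write_gene_annotation(annotation: GeneAnnotation, path) -> None:
    annotation.to_frame().to_csv(path, sep="\t", index=False)


def read_sample_labels(path) -> SampleLabels:
    """Read a two-column TSV (sample_id, label) into :class:`SampleLabels`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise DataModelError(f"{path}: label table needs >= 2 columns")
    sid, lab = df.columns[0], df.columns[1]
    if df[sid].duplicated().any():
        dup = df[sid][df[sid].duplicated()].iloc[0]
        raise DataModelError(f"{path}: sample id {dup!r} labeled more than once")
    return SampleLabels(labels=dict(zip(df[sid], df[lab])))


def write_sample_labels(labels: SampleLabels, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, lab in labels.labels.items():
            fh.write(f"{sid}\t{lab}\n")
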