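"""Readers, writers and core domain containers.

All on-disk formats used by the pipeline live here so every other module
is format-agnostic:

* count matrices as a Cell-Ranger-style triple — Matrix Market coordinate
  file (1-based on disk, 0-based in memory) plus one-entry-per-line
  ``features.tsv`` / ``barcodes.tsv``, with a required ``cell_meta.tsv``
  sidecar keyed by barcode;
* gene sets as GMT (name, description, then genes, tab-separated);
* manifests as JSON;
* every tabular interchange file as TSV with a header row.

Gene and barcode order on disk is preserved in memory, and writing is the
exact inverse of reading (round-trip identity is property-tested).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("ecatlas")

#: Gene-symbol prefix marking mitochondrial genes (human convention).
#: Configurable per call for synthetic symbol universes.
DEFAULT_MITO_PREFIX = "MT-"

REGIONS = ("core", "periphery")


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant (duplicates, mismatch)."""


def _find_duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in items:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sparse genes × cells matrix of nonnegative integer UMI counts.

    Parameters
    ----------
    values
        ``genes × cells`` sparse matrix (any scipy format; stored as CSR).
    gene_symbols
        Unique gene symbols, one per row, disk order preserved.
    barcodes
        Unique cell barcodes, one per column, disk order preserved.
    cell_meta
        Per-cell metadata indexed by barcode with at least the columns
        ``patient`` and ``region`` (``core`` or ``periphery``).
    mito_flag
        Per-gene boolean, True where the symbol marks a mitochondrial gene.
    """

    values: sp.csr_matrix
    gene_symbols: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame
    mito_flag: np.ndarray = field(default=None)  # type: ignore[assignment]
    mito_prefix: str = DEFAULT_MITO_PREFIX

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.mito_flag is None:
            self.mito_flag = np.array(
                [s.startswith(self.mito_prefix) for s in self.gene_symbols]
            )
        self.mito_flag = np.asarray(self.mito_flag, dtype=bool)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_genes, n_cells = self.values.shape
        if len(self.gene_symbols) != n_genes:
            raise FormatError(
                f"matrix has {n_genes} rows but {len(self.gene_symbols)} gene symbols"
            )
        if len(self.barcodes) != n_cells:
            raise FormatError(
                f"matrix has {n_cells} columns but {len(self.barcodes)} barcodes"
            )
        dup_g = _find_duplicates(list(self.gene_symbols))
        if dup_g:
            raise ValidationError(f"duplicate gene symbols: {dup_g}")
        dup_b = _find_duplicates(list(self.barcodes))
        if dup_b:
            raise ValidationError(f"duplicate barcodes: {dup_b}")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidationError("counts must be nonnegative")
        if self.values.nnz and np.any(self.values.data != np.round(self.values.data)):
            raise ValidationError("counts must be integral")
        missing = [b for b in self.barcodes if b not in self.cell_meta.index]
        if missing:
            raise ValidationError(f"cell_meta missing barcodes: {missing[:5]}")
        for col in ("patient", "region"):
            if col not in self.cell_meta.columns:
                raise ValidationError(f"cell_meta lacks required column {col!r}")

    # -- convenience --------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def meta_column(self, col: str) -> np.ndarray:
        """Metadata column aligned to barcode (column) order."""
        return self.cell_meta.loc[list(self.barcodes), col].to_numpy()

    def total_counts(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Per-cell fraction of counts on mitochondrial genes (0 where total 0)."""
        tot = self.total_counts().astype(float)
        mito = np.asarray(self.values[self.mito_flag].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, mito / tot, 0.0)
        return frac

    def detected_genes(self) -> np.ndarray:
        """Per-cell number of genes with a nonzero count."""
        return np.asarray((self.values > 0).sum(axis=0)).ravel()

    def subset_cells(self, mask_or_idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        bcs = self.barcodes[idx]
        return CountMatrix(
            values=self.values[:, idx],
            gene_symbols=self.gene_symbols,
            barcodes=bcs,
            cell_meta=self.cell_meta.loc[list(bcs)],
            mito_flag=self.mito_flag,
            mito_prefix=self.mito_prefix,
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.values.shape == other.values.shape
            and (self.values != other.values).nnz == 0
            and np.array_equal(self.gene_symbols, other.gene_symbols)
            and np.array_equal(self.barcodes, other.barcodes)
            and np.array_equal(self.mito_flag, other.mito_flag)
            and self.cell_meta.loc[list(self.barcodes), ["patient", "region"]]
            .astype(str)
            .equals(
                other.cell_meta.loc[list(other.barcodes), ["patient", "region"]].astype(str)
            )
        )


def read_counts(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    meta_path: str | Path,
    mito_prefix: str = DEFAULT_MITO_PREFIX,
) -> CountMatrix:
    """Read a Cell-Ranger-style count triple plus its metadata sidecar.

    The matrix file is Matrix Market coordinate format (1-based indices on
    disk); features and barcodes are one entry per line; ``meta_path`` is a
    TSV keyed by barcode with columns ``patient`` and ``region``.
    """
    matrix_path, features_path, barcodes_path, meta_path = map(
        Path, (matrix_path, features_path, barcodes_path, meta_path)
    )
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise FormatError(f"{matrix_path}: not valid Matrix Market: {exc}") from exc
    genes = _read_lines(features_path)
    barcodes = _read_lines(barcodes_path)
    n_genes, n_cells = mat.shape
    if n_genes != len(genes):
        raise FormatError(
            f"{features_path}: {len(genes)} features but matrix has {n_genes} rows"
        )
    if n_cells != len(barcodes):
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix has {n_cells} columns"
        )
    dup_b = _find_duplicates(barcodes)
    if dup_b:
        raise ValidationError(f"{barcodes_path}: duplicate barcodes: {dup_b}")
    dup_g = _find_duplicates(genes)
    if dup_g:
        raise ValidationError(f"{features_path}: duplicate gene symbols: {dup_g}")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("barcode")
    return CountMatrix(
        values=sp.csr_matrix(mat),
        gene_symbols=np.array(genes, dtype=object),
        barcodes=np.array(barcodes, dtype=object),
        cell_meta=meta,
        mito_prefix=mito_prefix,
    )


def _read_lines(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def write_counts(cm: CountMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write ``cm`` as matrix.mtx / features.tsv / barcodes.tsv / cell_meta.tsv.

    ``read_counts`` applied to the returned paths reproduces ``cm`` exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
        "meta": out / "cell_meta.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(cm.values), field="integer")
    paths["features"].write_text("".join(f"{g}\n" for g in cm.gene_symbols))
    paths["barcodes"].write_text("".join(f"{b}\n" for b in cm.barcodes))
    meta = cm.cell_meta.loc[list(cm.barcodes)]
    meta.to_csv(paths["meta"], sep="\t", index_label="barcode")
    return paths


# ---------------------------------------------------------------------------
# GeneSet / GMT
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    """Named, ordered, duplicate-free collection of gene symbols."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if not genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        dups = _find_duplicates(genes)
        if dups:
            raise ValidationError(f"gene set {self.name!r} has duplicates: {dups}")
        self.genes = genes

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.genes)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


def read_gene_sets(gmt_path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: per line, name TAB description TAB gene [TAB gene ...].

    Within-line duplicate symbols are collapsed (order kept) with a warning.
    """
    sets: list[GeneSet] = []
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{gmt_path}: line {lineno}: expected ≥3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                warnings.warn(
                    f"{gmt_path}: line {lineno} ({name}): collapsed "
                    f"{len(genes) - len(deduped)} duplicate symbols"
                )
            sets.append(GeneSet(name=name, description=desc, genes=tuple(deduped)))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], gmt_path: str | Path) -> Path:
    gmt_path = Path(gmt_path)
    gmt_path.parent.mkdir(parents=True, exist_ok=True)
    with open(gmt_path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")
    return gmt_path


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass
class Manifest:
    """Key→value record of planted truth or run outputs; JSON round-trippable."""

    schema_version: str = "1"
    seed: int = 0
    entries: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "schema_version": self.schema_version,
            "seed": int(self.seed),
            "entries": _jsonable(self.entries),
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "Manifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            schema_version=payload["schema_version"],
            seed=int(payload["seed"]),
            entries=payload["entries"],
        )


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = list(obj) if not isinstance(obj, (set, frozenset)) else sorted(obj)
        return [_jsonable(v) for v in items]
    if isinstance(obj, GeneSet):
        return {"name": obj.name, "description": obj.description, "genes": list(obj.genes)}
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


# ---------------------------------------------------------------------------
# Generic TSV tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Read a TSV table with a header row (genes × samples orientation)."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "gene") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)
    return path
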