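"""Count-matrix and sample-metadata containers, readers, writers and merging.

The on-disk dialects are deliberately plain: a counts TSV whose first column
holds gene identifiers and whose header row holds sample identifiers, or a
MatrixMarket triplet (``matrix.mtx`` with sibling ``genes.tsv`` /
``samples.tsv`` index files); a metadata TSV with columns ``sample_id``,
``patient_id``, ``cohort``, ``sample_type``, ``sex``; and a gene annotation
TSV with columns ``gene_id``, ``length_bp``, ``biotype``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import ConsistencyError, FormatError

SAMPLE_TYPES = frozenset({"tumor", "normal"})
SEXES = frozenset({"female", "male", "unknown"})

METADATA_COLUMNS = ["sample_id", "patient_id", "cohort", "sample_type", "sex"]
ANNOTATION_COLUMNS = ["gene_id", "length_bp", "biotype"]

_ENSEMBL_VERSION = re.compile(r"^(ENS[A-Z]*G\d+)\.\d+$")


@dataclass
class CountMatrix:
    """Raw gene-level counts (genes x samples) with per-gene lengths in bp.

    ``gene_lengths`` is indexed by gene id and aligned to ``counts.index``;
    genes without an annotated length carry NaN and are *flagged*, never
    silently dropped (:attr:`missing_length_genes`).
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.gene_lengths is None:
            self.gene_lengths = pd.Series(np.nan, index=self.counts.index, dtype=float)
        else:
            self.gene_lengths = pd.Series(self.gene_lengths, dtype=float).reindex(
                self.counts.index
            )
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        values = self.counts.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise FormatError("counts contain missing or non-finite values")
        if values.size and (values < 0).any():
            gene = idx[np.argwhere(values < 0)[0][0]]
            raise FormatError(f"negative count for gene {gene!r}")
        known = self.gene_lengths.dropna()
        if (known <= 0).any():
            gene = known[known <= 0].index[0]
            raise FormatError(f"non-positive length for gene {gene!r}")

    # -- conveniences ------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def missing_length_genes(self) -> list[str]:
        """Gene ids that have no annotated length."""
        return list(self.gene_lengths.index[self.gene_lengths.isna()])

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.gene_lengths)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.gene_lengths)

    def strip_gene_versions(self) -> "CountMatrix":
        """Drop Ensembl-style ``.N`` version suffixes from gene ids (opt-in)."""
        mapper = {
            g: (_ENSEMBL_VERSION.match(g).group(1) if _ENSEMBL_VERSION.match(g) else g)
            for g in self.counts.index
        }
        counts = self.counts.rename(index=mapper)
        lengths = self.gene_lengths.rename(index=mapper)
        return CountMatrix(counts, lengths)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


def validate_sample_table(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata table and return it with canonical columns."""
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing column(s) {missing}")
    meta = meta[METADATA_COLUMNS].copy()
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample id {dup!r} in metadata")
    bad_type = set(meta["sample_type"]) - SAMPLE_TYPES
    if bad_type:
        raise FormatError(f"unknown sample_type value(s) {sorted(bad_type)}")
    bad_sex = set(meta["sex"]) - SEXES
    if bad_sex:
        raise FormatError(f"unknown sex value(s) {sorted(bad_sex)}")
    return meta


def load_sample_table(path: str | Path) -> pd.DataFrame:
    return validate_sample_table(pd.read_csv(path, sep="\t", dtype=str))


def write_sample_table(meta: pd.DataFrame, path: str | Path) -> None:
    validate_sample_table(meta).to_csv(path, sep="\t", index=False)


def load_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation TSV (gene_id, length_bp, biotype)."""
    annot = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in annot.columns]
    if missing:
        raise FormatError(f"annotation missing column(s) {missing}")
    if annot["gene_id"].duplicated().any():
        dup = annot.loc[annot["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene id {dup!r} in annotation")
    return annot[ANNOTATION_COLUMNS]


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def attach_lengths(cm: CountMatrix, annot: pd.DataFrame) -> CountMatrix:
    """Attach gene lengths from an annotation table; unmatched genes keep NaN."""
    lengths = annot.set_index("gene_id")["length_bp"].astype(float)
    return CountMatrix(cm.counts, lengths.reindex(cm.counts.index))


# ---------------------------------------------------------------------------
# counts readers / writers
# ---------------------------------------------------------------------------


def load_counts(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a count matrix from ``tsv`` or ``mtx`` (directory) layout.

    The returned matrix has no gene lengths attached; use
    :func:`load_annotation` + :func:`attach_lengths` for those.
    """
    if format == "tsv":
        return _load_counts_tsv(Path(path))
    if format == "mtx":
        return _load_counts_mtx(Path(path))
    raise ValueError(f"unknown counts format {format!r}")


def _load_counts_tsv(path: Path) -> CountMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        n_fields = len(header)
        seen_samples = set()
        for s in sample_ids:
            if s in seen_samples:
                raise FormatError(f"duplicate sample id {s!r}", line=1)
            seen_samples.add(s)
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        seen_genes: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_fields:
                raise FormatError(
                    f"expected {n_fields} fields, found {len(fields)}", line=lineno
                )
            gene = fields[0]
            if gene in seen_genes:
                raise FormatError(f"duplicate gene id {gene!r}", line=lineno)
            seen_genes.add(gene)
            try:
                values = [float(v) for v in fields[1:]]
            except ValueError as exc:
                raise FormatError(f"non-numeric count ({exc})", line=lineno) from None
            if any(v < 0 for v in values):
                raise FormatError(f"negative count for gene {gene!r}", line=lineno)
            gene_ids.append(gene)
            rows.append(values)
    counts = pd.DataFrame(rows, index=gene_ids, columns=sample_ids)
    return CountMatrix(counts)


def _load_counts_mtx(path: Path) -> CountMatrix:
    """Read a MatrixMarket triplet directory (matrix.mtx, genes.tsv, samples.tsv)."""
    if path.is_dir():
        mtx, genes_f, samples_f = (
            path / "matrix.mtx",
            path / "genes.tsv",
            path / "samples.tsv",
        )
    else:  # allow pointing at the .mtx file itself
        mtx = path
        genes_f = path.parent / "genes.tsv"
        samples_f = path.parent / "samples.tsv"
    matrix = scipy.io.mmread(mtx)
    gene_ids = [line.rstrip("\n") for line in open(genes_f) if line.strip()]
    sample_ids = [line.rstrip("\n") for line in open(samples_f) if line.strip()]
    dense = np.asarray(
        matrix.todense() if scipy.sparse.issparse(matrix) else matrix, dtype=float
    )
    if dense.shape != (len(gene_ids), len(sample_ids)):
        raise FormatError(
            f"matrix shape {dense.shape} does not match index files "
            f"({len(gene_ids)} genes, {len(sample_ids)} samples)"
        )
    return CountMatrix(pd.DataFrame(dense, index=gene_ids, columns=sample_ids))


def write_counts(cm: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    if format == "tsv":
        out = cm.counts.copy()
        out.index.name = "gene_id"
        # integer counts round-trip as integers
        if np.allclose(out.to_numpy(), np.round(out.to_numpy())):
            out = out.astype(np.int64)
        out.to_csv(path, sep="\t")
    elif format == "mtx":
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(cm.counts.to_numpy())
        scipy.io.mmwrite(path / "matrix.mtx", sparse)
        (path / "genes.tsv").write_text("".join(f"{g}\n" for g in cm.gene_ids))
        (path / "samples.tsv").write_text("".join(f"{s}\n" for s in cm.sample_ids))
    else:
        raise ValueError(f"unknown counts format {format!r}")


# ---------------------------------------------------------------------------
# filtering and merging
# ---------------------------------------------------------------------------


def filter_samples(
    cm: CountMatrix,
    meta: pd.DataFrame,
    keep_sex: Iterable[str] = SEXES,
    keep_types: Iterable[str] = SAMPLE_TYPES,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Restrict samples to those matching both the sex and type filters.

    Counts columns and metadata rows stay aligned; a counts column absent
    from the metadata is a consistency error.
    """
    meta = validate_sample_table(meta)
    keep_sex = set(keep_sex)
    keep_types = set(keep_types)
    known = set(meta["sample_id"])
    orphans = [s for s in cm.sample_ids if s not in known]
    if orphans:
        raise ConsistencyError(f"counts column(s) missing from metadata: {orphans[:5]}")
    status = meta.set_index("sample_id")
    kept = [
        s
        for s in cm.sample_ids
        if status.at[s, "sex"] in keep_sex and status.at[s, "sample_type"] in keep_types
    ]
    kept_set = set(kept)
    meta_out = meta[meta["sample_id"].isin(kept_set)].reset_index(drop=True)
    return cm.subset_samples(kept), meta_out


def sample_accounting(meta: pd.DataFrame) -> dict[str, int]:
    """Tumor / normal / total bookkeeping for a metadata table."""
    n_tumor = int((meta["sample_type"] == "tumor").sum())
    n_normal = int((meta["sample_type"] == "normal").sum())
    return {"tumor": n_tumor, "normal": n_normal, "total": int(len(meta))}


def merge_cohorts(matrices: Sequence[CountMatrix]) -> CountMatrix:
    """Column-concatenate cohorts on the intersection of their gene ids.

    Per-matrix sample order is preserved; gene order follows the first
    matrix.  Gene lengths must agree (where annotated) across inputs.
    """
    if len(matrices) < 2:
        raise ConsistencyError("merge requires at least two count matrices")
    seen: set[str] = set()
    for m in matrices:
        overlap = seen & set(m.sample_ids)
        if overlap:
            raise ConsistencyError(f"sample id(s) present in multiple cohorts: {sorted(overlap)[:5]}")
        seen |= set(m.sample_ids)
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    genes = [g for g in matrices[0].gene_ids if g in common]
    lengths = pd.Series(np.nan, index=pd.Index(genes), dtype=float)
    for m in matrices:
        theirs = m.gene_lengths.reindex(genes)
        both = lengths.notna() & theirs.notna()
        if both.any() and not np.allclose(lengths[both], theirs[both]):
            diff = lengths.index[both][~np.isclose(lengths[both], theirs[both])][0]
            raise ConsistencyError(f"conflicting lengths for shared gene {diff!r}")
        lengths = lengths.fillna(theirs)
    counts = pd.concat([m.counts.loc[genes] for m in matrices], axis=1)
    if not genes:
        warnings.warn("merged gene set is empty", stacklevel=2)
    return CountMatrix(counts, lengths)
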