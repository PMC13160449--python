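"""Loading, validation, preprocessing and cross-modality feature linking.

The integration pipeline consumes two cell-by-feature matrices measured on
disjoint sets of cells (e.g. an scRNA-seq matrix and an antibody-panel
protein matrix). The only cross-modal anchor information is a set of
*linked features*: feature columns measured in, or predictable from, both
modalities. This module builds that linkage three ways:

* identical feature names across modalities (``link_by_name``),
* a user-supplied gene-to-protein map (``link_gene_protein``),
* chromatin accessibility regions collapsed to gene-activity scores via
  gene-body / promoter-window overlap (``link_region_gene``).

The linkage ratio ``rho = min(p_link/px, p_link/py)`` quantifies how much
shared information exists; below 10% the scenario is called *weakly linked*.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

WEAK_LINKAGE_THRESHOLD = 0.10

__all__ = [
    "ModalityMatrix",
    "FeatureLinkage",
    "GeneAnnotation",
    "load_modality",
    "save_modality",
    "preprocess",
    "link_by_name",
    "link_gene_protein",
    "link_region_gene",
    "aggregate_gene_activity",
    "linkage_ratio",
    "WEAK_LINKAGE_THRESHOLD",
]


@dataclass
class ModalityMatrix:
    """One modality's cell-by-feature matrix with identifiers.

    ``values`` may be dense ``ndarray`` or ``scipy.sparse``; rows are cells,
    columns are features. Labels are optional cell-type annotations used
    only for evaluation, never by the pipeline itself.
    """

    values: np.ndarray | sp.spmatrix
    feature_ids: np.ndarray
    cell_ids: np.ndarray
    cell_type_labels: np.ndarray | None = None
    modality_tag: str = "unknown"

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.cell_type_labels is not None:
            self.cell_type_labels = np.asarray(self.cell_type_labels, dtype=object)
        self.validate()

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        n, p = self.values.shape
        if n < 2:
            raise ValueError(f"modality '{self.modality_tag}' needs >= 2 cells, got {n}")
        if p < 1:
            raise ValueError(f"modality '{self.modality_tag}' needs >= 1 feature")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {p} features")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} cells")
        if len(set(self.feature_ids)) != p:
            dup = pd.Index(self.feature_ids)[pd.Index(self.feature_ids).duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r} in modality '{self.modality_tag}'")
        if len(set(self.cell_ids)) != n:
            raise ValueError(f"duplicate cell ids in modality '{self.modality_tag}'")
        if self.cell_type_labels is not None and len(self.cell_type_labels) != n:
            raise ValueError("cell_type_labels length mismatch")
        dense = self.values.data if sp.issparse(self.values) else self.values
        if not np.all(np.isfinite(dense)):
            raise ValueError(f"non-finite values in modality '{self.modality_tag}'")

    def dense(self) -> np.ndarray:
        """Values as a dense float64 array."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=np.float64)
        return np.asarray(self.values, dtype=np.float64)


@dataclass(frozen=True)
class FeatureLinkage:
    """Ordered pairs of linked feature columns across two modalities."""

    pairs: tuple[tuple[int, int], ...]
    px: int
    py: int

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate linkage pairs")
        for i, j in self.pairs:
            if not (0 <= i < self.px and 0 <= j < self.py):
                raise ValueError(f"linkage pair ({i},{j}) out of range for px={self.px}, py={self.py}")
        if self.p_link > min(self.px, self.py):
            raise ValueError("more linked pairs than features in one modality")

    @property
    def p_link(self) -> int:
        return len(self.pairs)

    @property
    def rho(self) -> float:
        return linkage_ratio(self.p_link, self.px, self.py)[0]

    @property
    def category(self) -> str:
        return linkage_ratio(self.p_link, self.px, self.py)[1]

    def x_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.pairs], dtype=int)

    def y_indices(self) -> np.ndarray:
        return np.array([j for _, j in self.pairs], dtype=int)


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene coordinates in 0-based half-open convention.

    ``records`` maps gene_id -> (chromosome, strand, start, end).
    BED input is native; GTF start coordinates are shifted by -1 on read.
    """

    records: dict[str, tuple[str, str, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, (chrom, strand, start, end) in self.records.items():
            if start >= end:
                raise ValueError(f"gene {gene!r}: start {start} >= end {end}")
            if strand not in ("+", "-"):
                raise ValueError(f"gene {gene!r}: strand must be '+' or '-', got {strand!r}")

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneAnnotation":
        """Read a BED file with columns chrom, start, end, name, [score], strand."""
        records: dict[str, tuple[str, str, int, int]] = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {ln}: BED needs >= 4 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) >= 6 else "+"
            records[name] = (chrom, strand, start, end)
        return cls(records)

    @classmethod
    def from_gtf(cls, path: str | Path, feature_type: str = "gene",
                 id_attribute: str = "gene_name") -> "GeneAnnotation":
        """Read gene records from a GTF file (1-based inclusive -> half-open)."""
        records: dict[str, tuple[str, str, int, int]] = {}
        attr_re = re.compile(rf'{id_attribute}\s+"([^"]+)"')
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}: line {ln}: GTF needs 9 columns")
            if parts[2] != feature_type:
                continue
            m = attr_re.search(parts[8])
            if m is None:
                continue
            records[m.group(1)] = (parts[0], parts[6], int(parts[3]) - 1, int(parts[4]))
        return cls(records)


def load_modality(
    path: str | Path,
    format: Literal["csv", "mtx_triplet", "h5_annotated"] = "csv",
    label_key: str | None = None,
    modality_tag: str = "unknown",
    sep: str = ",",
) -> ModalityMatrix:
    """Load a cell-by-feature matrix.

    ``csv``: header row = feature ids, first column = cell ids.
    ``mtx_triplet``: MatrixMarket coordinate file (cells x features) with
    ``features.tsv`` / ``barcodes.tsv`` sidecars in the same directory;
    an optional ``labels.tsv`` sidecar supplies cell-type labels.
    ``h5_annotated``: an annotated single-cell HDF5 (h5ad) container;
    ``label_key`` selects the obs column holding cell-type labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        df = pd.read_csv(path, index_col=0, sep=sep)
        try:
            values = df.to_numpy(dtype=np.float64)
        except (TypeError, ValueError):
            for col in df.columns:
                bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
                if bad.any():
                    row = df.index[np.flatnonzero(bad)[0]]
                    raise ValueError(
                        f"{path}: non-numeric value at row {row!r}, column {col!r}"
                    ) from None
            raise
        labels = None
        if label_key is not None:
            lab_path = path.with_name(label_key)
            labels = pd.read_csv(lab_path, header=None).iloc[:, 0].to_numpy(dtype=object)
        return ModalityMatrix(values, df.columns.to_numpy(dtype=object),
                              df.index.to_numpy(dtype=object), labels, modality_tag)
    if format == "mtx_triplet":
        try:
            mat = scipy.io.mmread(path).tocsr()
        except Exception as exc:  # noqa: BLE001 - rewrap with file context
            raise ValueError(f"{path}: malformed MatrixMarket file: {exc}") from exc
        folder = path.parent
        feats = pd.read_csv(folder / "features.tsv", header=None, sep="\t").iloc[:, 0]
        cells = pd.read_csv(folder / "barcodes.tsv", header=None, sep="\t").iloc[:, 0]
        labels = None
        if (folder / "labels.tsv").exists():
            labels = pd.read_csv(folder / "labels.tsv", header=None, sep="\t").iloc[:, 0].to_numpy(object)
        return ModalityMatrix(mat, feats.to_numpy(object), cells.to_numpy(object), labels, modality_tag)
    if format == "h5_annotated":
        import anndata as ad

        adata = ad.read_h5ad(path)
        labels = None
        if label_key is not None:
            labels = adata.obs[label_key].to_numpy(dtype=object)
        values = adata.X if sp.issparse(adata.X) else np.asarray(adata.X, dtype=np.float64)
        return ModalityMatrix(values, adata.var_names.to_numpy(object),
                              adata.obs_names.to_numpy(object), labels, modality_tag)
    raise ValueError(f"unknown format {format!r}")


def save_modality(m: ModalityMatrix, path: str | Path,
                  format: Literal["csv", "mtx_triplet"] = "csv") -> None:
    """Write a ModalityMatrix back to disk (inverse of :func:`load_modality`)."""
    path = Path(path)
    if format == "csv":
        pd.DataFrame(m.dense(), index=m.cell_ids, columns=m.feature_ids).to_csv(path)
        if m.cell_type_labels is not None:
            pd.Series(m.cell_type_labels).to_csv(
                path.with_name(path.stem + "_labels.csv"), index=False, header=False)
        return
    if format == "mtx_triplet":
        path.parent.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path, sp.coo_matrix(m.values))
        folder = path.parent
        pd.Series(m.feature_ids).to_csv(folder / "features.tsv", sep="\t", index=False, header=False)
        pd.Series(m.cell_ids).to_csv(folder / "barcodes.tsv", sep="\t", index=False, header=False)
        if m.cell_type_labels is not None:
            pd.Series(m.cell_type_labels).to_csv(folder / "labels.tsv", sep="\t",
                                                 index=False, header=False)
        return
    raise ValueError(f"unknown format {format!r}")


def preprocess(
    m: ModalityMatrix,
    normalize_total: bool = True,
    log1p: bool = True,
    scale: bool = True,
) -> ModalityMatrix:
    """Standard preprocessing: per-cell total-count normalization to the
    median total, ``log1p``, then per-feature standardization.

    Each step is optional and logged; intended for raw count/intensity
    inputs. Already-preprocessed matrices should skip this.
    """
    values = m.dense()
    if normalize_total:
        totals = values.sum(axis=1)
        target = np.median(totals[totals > 0])
        nz = totals > 0
        values[nz] = values[nz] * (target / totals[nz])[:, None]
        logger.info("normalized %d cells to median total %.3g", m.n_cells, target)
    if log1p:
        if values.min() < 0:
            raise ValueError("log1p requires nonnegative values")
        values = np.log1p(values)
        logger.info("applied log1p")
    if scale:
        mu = values.mean(axis=0)
        sd = values.std(axis=0)
        sd[sd == 0] = 1.0
        values = (values - mu) / sd
        logger.info("standardized %d features", m.n_features)
    return replace(m, values=values)


def linkage_ratio(p_link: int, px: int, py: int) -> tuple[float, str]:
    """Linkage ratio ``rho = min(p_link/px, p_link/py)`` and its category.

    Scenarios with ``rho < 0.10`` are *weak*, otherwise *strong*.
    """
    if px < 1 or py < 1:
        raise ValueError("px and py must be >= 1")
    if not (0 <= p_link <= min(px, py)):
        raise ValueError(f"p_link={p_link} violates 0 <= p_link <= min(px={px}, py={py})")
    rho = min(p_link / px, p_link / py)
    return rho, ("weak" if rho < WEAK_LINKAGE_THRESHOLD else "strong")


def link_by_name(x: ModalityMatrix, y: ModalityMatrix,
                 case_insensitive: bool = False) -> FeatureLinkage:
    """Link features sharing the same name across the two modalities.

    Matching is case-sensitive unless ``case_insensitive`` is set (protein
    panels often capitalize nonstandardly). Pair order follows x's feature
    order.
    """
    key = (lambda s: str(s).lower()) if case_insensitive else str
    y_pos = {key(f): j for j, f in enumerate(y.feature_ids)}
    pairs = [(i, y_pos[key(f)]) for i, f in enumerate(x.feature_ids) if key(f) in y_pos]
    if not pairs:
        raise ValueError("no linked features: feature name sets are disjoint")
    return FeatureLinkage(tuple(pairs), x.n_features, y.n_features)


def link_gene_protein(x: ModalityMatrix, y: ModalityMatrix,
                      map_table: pd.DataFrame | Sequence[tuple[str, str]]) -> FeatureLinkage:
    """Link each protein in ``y`` to its encoding gene in ``x``.

    ``map_table`` holds (gene_name, protein_name) rows; rows whose gene or
    protein is absent are skipped, duplicates are deduplicated.
    """
    if isinstance(map_table, pd.DataFrame):
        if map_table.shape[1] != 2:
            raise ValueError(f"gene-protein map must have 2 columns, got {map_table.shape[1]}")
        rows = [tuple(r) for r in map_table.itertuples(index=False)]
    else:
        rows = [tuple(r) for r in map_table]
        if any(len(r) != 2 for r in rows):
            raise ValueError("gene-protein map rows must have exactly 2 entries")
    x_pos = {str(f): i for i, f in enumerate(x.feature_ids)}
    y_pos = {str(f): j for j, f in enumerate(y.feature_ids)}
    pairs: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for gene, protein in rows:
        if str(gene) in x_pos and str(protein) in y_pos:
            pair = (x_pos[str(gene)], y_pos[str(protein)])
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    if not pairs:
        raise ValueError("no linked features: no map row resolved in both modalities")
    return FeatureLinkage(tuple(pairs), x.n_features, y.n_features)


_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def _parse_region(feature_id: str) -> tuple[str, int, int]:
    m = _REGION_RE.match(str(feature_id))
    if m is None:
        raise ValueError(f"unparseable region id {feature_id!r}; expected 'chrom:start-end'")
    return m.group("chrom"), int(m.group("start")), int(m.group("end"))


def aggregate_gene_activity(
    x_atac: ModalityMatrix,
    annotation: GeneAnnotation,
    upstream_bp: int = 2000,
    mode: Literal["sum", "mean"] = "sum",
) -> ModalityMatrix:
    """Collapse accessibility regions into per-gene activity columns.

    A region counts toward a gene if it overlaps the gene body or the
    strand-aware promoter window of length ``upstream_bp`` upstream of the
    transcription start (+ strand: ``[start-upstream, start)``; - strand:
    ``[end, end+upstream)``). Regions assigned to a gene are summed (or
    averaged) into one gene-activity feature named after the gene.
    """
    regions = [_parse_region(f) for f in x_atac.feature_ids]
    values = x_atac.dense()
    gene_cols: dict[str, np.ndarray] = {}
    for gene, (chrom, strand, gstart, gend) in annotation.records.items():
        if strand == "+":
            win_start, win_end = max(0, gstart - upstream_bp), gend
        else:
            win_start, win_end = gstart, gend + upstream_bp
        idx = [k for k, (rc, rs, re_) in enumerate(regions)
               if rc == chrom and rs < win_end and re_ > win_start]
        if not idx:
            continue
        col = values[:, idx].sum(axis=1)
        if mode == "mean":
            col = col / len(idx)
        gene_cols[gene] = col
    if not gene_cols:
        raise ValueError("no linked features: no region overlaps any annotated gene")
    genes = list(gene_cols)
    return ModalityMatrix(
        np.column_stack([gene_cols[g] for g in genes]),
        np.array(genes, dtype=object),
        x_atac.cell_ids,
        x_atac.cell_type_labels,
        x_atac.modality_tag + "_gene_activity",
    )


def link_region_gene(
    x_atac: ModalityMatrix,
    y_rna: ModalityMatrix,
    annotation: GeneAnnotation,
    upstream_bp: int = 2000,
    mode: Literal["sum", "mean"] = "sum",
) -> tuple[FeatureLinkage, ModalityMatrix]:
    """Link accessibility-derived gene-activity features to RNA genes.

    Returns the linkage together with the gene-activity matrix it indexes
    into (region columns collapsed per gene; see
    :func:`aggregate_gene_activity`), since downstream stages consume the
    collapsed one-to-one linked columns.
    """
    activity = aggregate_gene_activity(x_atac, annotation, upstream_bp, mode)
    keep = [g for g in activity.feature_ids if g in set(map(str, y_rna.feature_ids))]
    if not keep:
        raise ValueError("no linked features: no gene-activity feature matches an RNA gene")
    return link_by_name(activity, y_rna), activity
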