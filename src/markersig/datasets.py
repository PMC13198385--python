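"""Core dataset container, validation, and readers/writers.

The central object is :class:`OmicsDataset`: a samples x features numeric
matrix (dense or sparse) together with unique feature names, unique sample
ids, categorical per-sample annotations, and one or more named
low-dimensional embeddings (n_samples x d, d >= 2).  Datasets can be read
from / written to AnnData ``.h5ad`` containers or a plain-text TSV-triplet
directory layout (``matrix.tsv`` + ``annotations.tsv`` + one
``embedding_<name>.tsv`` per embedding).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


class ValidationError(ValueError):
    """Raised when a dataset or selection violates its invariants."""


def _is_sparse(x) -> bool:
    return sp.issparse(x)


@dataclass
class OmicsDataset:
    """Samples x features omics matrix with annotations and embeddings.

    Parameters
    ----------
    matrix
        Numeric matrix of shape ``(n_samples, n_features)``; dense ndarray
        or scipy sparse.  Sparse input is preserved as sparse.
    feature_names
        Unique feature identifiers, length ``n_features``.
    sample_ids
        Unique sample identifiers, length ``n_samples``.
    annotations
        DataFrame indexed by sample id; each column is a categorical
        per-sample label (cluster, cell type, batch, ...).
    embeddings
        Mapping from embedding name to an ``(n_samples, d)`` array with
        ``d >= 2`` (PCA / UMAP / t-SNE / VAE coordinates, ...).
    """

    matrix: np.ndarray | sp.spmatrix
    feature_names: np.ndarray
    sample_ids: np.ndarray
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.feature_names = np.asarray(self.feature_names, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if not _is_sparse(self.matrix):
            self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.embeddings = {k: np.asarray(v, dtype=np.float64) for k, v in self.embeddings.items()}
        if self.annotations is None or len(self.annotations) == 0:
            self.annotations = pd.DataFrame(index=pd.Index(self.sample_ids, name="sample_id"))
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def validate(self) -> None:
        n, f = self.matrix.shape
        if len(self.feature_names) != f:
            raise ValidationError(f"feature_names length {len(self.feature_names)} != n_features {f}")
        if len(self.sample_ids) != n:
            raise ValidationError(f"sample_ids length {len(self.sample_ids)} != n_samples {n}")
        if len(set(self.feature_names)) != f:
            raise ValidationError("duplicate feature names")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        data = self.matrix.data if _is_sparse(self.matrix) else self.matrix
        if np.asarray(data, dtype=np.float64).size and not np.all(np.isfinite(np.asarray(data, dtype=np.float64))):
            raise ValidationError("matrix contains NaN or infinite values")
        if len(self.annotations) != n:
            raise ValidationError("annotation table row count does not match n_samples")
        if not self.embeddings:
            raise ValidationError("no embedding found")
        for name, emb in self.embeddings.items():
            if emb.ndim != 2 or emb.shape[0] != n:
                raise ValidationError(f"embedding {name!r} must have {n} rows")
            if emb.shape[1] < 2:
                raise ValidationError(f"embedding {name!r} must have >= 2 columns")
            if not np.all(np.isfinite(emb)):
                raise ValidationError(f"embedding {name!r} contains NaN or infinite values")

    # ------------------------------------------------------------------
    def feature_index(self, names) -> np.ndarray:
        """Map feature names to column indices (error on unknown names)."""
        lookup = {n: i for i, n in enumerate(self.feature_names)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown feature {e.args[0]!r}") from None

    def feature_values(self, index: int) -> np.ndarray:
        """Dense values of one feature column."""
        col = self.matrix[:, index]
        if _is_sparse(col):
            return np.asarray(col.todense()).ravel()
        return np.asarray(col).ravel()

    def dense_block(self, rows: np.ndarray, cols: np.ndarray | None = None) -> np.ndarray:
        """Dense (rows x cols) sub-block of the matrix."""
        block = self.matrix[rows]
        if cols is not None:
            block = block[:, cols]
        if _is_sparse(block):
            block = np.asarray(block.todense())
        return np.asarray(block, dtype=np.float64)

    def subset(self, rows) -> "OmicsDataset":
        """New dataset restricted to the given sample rows (mask or indices)."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return OmicsDataset(
            matrix=self.matrix[rows],
            feature_names=self.feature_names,
            sample_ids=self.sample_ids[rows],
            annotations=self.annotations.iloc[rows],
            embeddings={k: v[rows] for k, v in self.embeddings.items()},
        )

    def to_anndata(self):
        import anndata as ad

        obs = self.annotations.copy()
        obs.index = pd.Index([str(s) for s in self.sample_ids], name="sample_id")
        adata = ad.AnnData(
            X=self.matrix,
            obs=obs,
            var=pd.DataFrame(index=pd.Index([str(f) for f in self.feature_names], name="feature")),
        )
        for name, emb in self.embeddings.items():
            adata.obsm[name] = emb.copy()
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "OmicsDataset":
        embeddings = {}
        for name in adata.obsm.keys():
            arr = np.asarray(adata.obsm[name], dtype=np.float64)
            if arr.ndim == 2 and arr.shape[1] >= 2:
                embeddings[name] = arr
        ann = adata.obs.copy()
        for c in ann.columns:  # categoricals back to plain strings
            if isinstance(ann[c].dtype, pd.CategoricalDtype):
                ann[c] = ann[c].astype(str)
        X = adata.X
        if not _is_sparse(X):
            X = np.asarray(X, dtype=np.float64)
        return cls(
            matrix=X,
            feature_names=np.asarray(adata.var_names, dtype=object),
            sample_ids=np.asarray(adata.obs_names, dtype=object),
            annotations=ann,
            embeddings=embeddings,
        )


@dataclass
class SampleSelection:
    """Boolean subset of samples with a provenance string.

    Provenance examples: ``"label:cell_type=B"``, ``"lasso"``,
    ``"(lasso) union (label:cluster=c1)"``.
    """

    mask: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 1:
            raise ValidationError("selection mask must be 1-D")

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def complement(self) -> "SampleSelection":
        return SampleSelection(~self.mask, provenance=f"complement({self.provenance})")


@dataclass
class GroupStats:
    """Per-feature empirical mean and standard deviation of two groups."""

    means_a: np.ndarray
    stds_a: np.ndarray
    means_b: np.ndarray
    stds_b: np.ndarray

    def __post_init__(self):
        arrs = [np.asarray(a, dtype=np.float64) for a in
                (self.means_a, self.stds_a, self.means_b, self.stds_b)]
        self.means_a, self.stds_a, self.means_b, self.stds_b = arrs
        lengths = {a.shape for a in arrs}
        if len(lengths) != 1:
            raise ValidationError("GroupStats vectors must all have the same length")
        if np.any(self.stds_a < 0) or np.any(self.stds_b < 0):
            raise ValidationError("standard deviations must be non-negative")

    @property
    def n_features(self) -> int:
        return self.means_a.shape[0]


# ----------------------------------------------------------------------
# selection and statistics operations


def select_by_label(dataset: OmicsDataset, key: str, values) -> SampleSelection:
    """Select all samples whose annotation ``key`` is in ``values``.

    An empty result is allowed (a warning is emitted), an unknown key is an
    error naming the available annotation keys.
    """
    if key not in dataset.annotations.columns:
        raise KeyError(
            f"unknown annotation key {key!r}; available keys: "
            f"{sorted(map(str, dataset.annotations.columns))}"
        )
    if isinstance(values, str):
        values = {values}
    values = {str(v) for v in values}
    labels = dataset.annotations[key].astype(str).to_numpy()
    mask = np.isin(labels, sorted(values))
    if not mask.any():
        warnings.warn(f"selection label:{key}={sorted(values)} matched no samples")
    return SampleSelection(mask, provenance=f"label:{key}={','.join(sorted(values))}")


def _group_moments(matrix, rows: np.ndarray, ddof: int):
    """Mean and std (divisor n - ddof) per feature over the given rows.

    Sparse matrices stay sparse: the variance is obtained from E[x^2]-E[x]^2
    computed with sparse element-wise products.
    """
    n = rows.size
    if ddof >= n:
        raise ValidationError(f"ddof={ddof} requires group size > {ddof}")
    sub = matrix[rows]
    if _is_sparse(sub):
        mean = np.asarray(sub.mean(axis=0)).ravel()
        mean_sq = np.asarray(sub.multiply(sub).mean(axis=0)).ravel()
    else:
        mean = sub.mean(axis=0)
        mean_sq = np.mean(sub * sub, axis=0)
    var = np.clip(mean_sq - mean**2, 0.0, None)
    if ddof:
        var = var * (n / (n - ddof))
    return mean, np.sqrt(var)


def group_stats(
    dataset: OmicsDataset,
    sel_a: SampleSelection,
    sel_b: SampleSelection,
    ddof: int = 0,
) -> GroupStats:
    """Per-feature mean/std for two disjoint non-empty sample groups.

    The default divisor is ``n`` (population standard deviation, ddof=0),
    which is well defined for single-sample groups; ``ddof`` is exposed for
    users who prefer the unbiased estimator.
    """
    for name, sel in (("A", sel_a), ("B", sel_b)):
        if sel.mask.shape[0] != dataset.n_samples:
            raise ValidationError(f"group {name} mask length != n_samples")
        if sel.n_selected == 0:
            raise ValidationError(f"group {name} is empty")
    if np.any(sel_a.mask & sel_b.mask):
        raise ValidationError("groups A and B overlap")
    mean_a, std_a = _group_moments(dataset.matrix, sel_a.indices, ddof)
    mean_b, std_b = _group_moments(dataset.matrix, sel_b.indices, ddof)
    return GroupStats(mean_a, std_a, mean_b, std_b)


# ----------------------------------------------------------------------
# readers / writers

_MATRIX_TSV = "matrix.tsv"
_ANNOT_TSV = "annotations.tsv"
_EMB_PREFIX = "embedding_"

# %.17g round-trips IEEE double exactly through decimal text
_FLOAT_FMT = "%.17g"


def load_dataset(path: str, format: str | None = None) -> OmicsDataset:
    """Load a dataset from ``.h5ad`` or a TSV-triplet directory.

    ``format`` is ``"h5ad"`` or ``"tsv-triplet"``; when omitted it is
    inferred from the path (``.h5ad`` suffix vs directory).
    """
    if format is None:
        format = "h5ad" if str(path).endswith(".h5ad") else "tsv-triplet"
    if format == "h5ad":
        import anndata as ad

        return OmicsDataset.from_anndata(ad.read_h5ad(path))
    if format == "tsv-triplet":
        return _load_tsv_triplet(path)
    raise ValueError(f"unknown format {format!r}")


def _load_tsv_triplet(path: str) -> OmicsDataset:
    if not os.path.isdir(path):
        raise FileNotFoundError(f"tsv-triplet path {path!r} is not a directory")
    mat = pd.read_csv(os.path.join(path, _MATRIX_TSV), sep="\t", index_col=0,
                      float_precision="round_trip")
    ann_path = os.path.join(path, _ANNOT_TSV)
    ann = pd.read_csv(ann_path, sep="\t", index_col=0, dtype=str) if os.path.exists(ann_path) \
        else pd.DataFrame(index=mat.index)
    embeddings = {}
    for fn in sorted(os.listdir(path)):
        if fn.startswith(_EMB_PREFIX) and fn.endswith(".tsv"):
            name = fn[len(_EMB_PREFIX):-4]
            emb = pd.read_csv(os.path.join(path, fn), sep="\t", index_col=0,
                              float_precision="round_trip")
            embeddings[name] = emb.to_numpy(dtype=np.float64)
    if not embeddings:
        raise ValidationError("no embedding found")
    return OmicsDataset(
        matrix=mat.to_numpy(dtype=np.float64),
        feature_names=np.asarray(mat.columns, dtype=object),
        sample_ids=np.asarray(mat.index.astype(str), dtype=object),
        annotations=ann.loc[mat.index.astype(str)] if len(ann) else ann,
        embeddings=embeddings,
    )


def write_dataset(dataset: OmicsDataset, path: str, format: str | None = None) -> None:
    """Write a dataset as ``.h5ad`` or a TSV-triplet directory."""
    if format is None:
        format = "h5ad" if str(path).endswith(".h5ad") else "tsv-triplet"
    if format == "h5ad":
        dataset.to_anndata().write_h5ad(path)
        return
    if format != "tsv-triplet":
        raise ValueError(f"unknown format {format!r}")
    os.makedirs(path, exist_ok=True)
    X = dataset.matrix
    if _is_sparse(X):
        X = np.asarray(X.todense())
    pd.DataFrame(X, index=pd.Index(dataset.sample_ids, name="sample_id"),
                 columns=dataset.feature_names).to_csv(
        os.path.join(path, _MATRIX_TSV), sep="\t", float_format=_FLOAT_FMT)
    ann = dataset.annotations.copy()
    ann.index = pd.Index(dataset.sample_ids, name="sample_id")
    ann.to_csv(os.path.join(path, _ANNOT_TSV), sep="\t")
    for name, emb in dataset.embeddings.items():
        pd.DataFrame(emb, index=pd.Index(dataset.sample_ids, name="sample_id"),
                     columns=[f"dim{j}" for j in range(emb.shape[1])]).to_csv(
            os.path.join(path, f"{_EMB_PREFIX}{name}.tsv"), sep="\t", float_format=_FLOAT_FMT)


def write_signature_table(result, path: str, header_lines=()) -> None:
    """Write a signature or oriented-signature result as a ranked TSV.

    Signature columns: rank, feature, wasserstein, threshold, direction,
    mcc.  Oriented columns: rank, feature, pearson_r.  Row order is rank
    order; optional comment header lines (prefixed ``#``) come first.
    """
    frame = result.to_frame()
    if len(frame) == 0:
        raise ValueError("refusing to write an empty signature table")
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")
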