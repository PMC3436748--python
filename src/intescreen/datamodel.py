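"""Data containers, standardization, cross-study gene matching and I/O.

A screening analysis starts from M independent case/control studies, each
a samples x genes expression matrix with a binary response. Studies may
measure only partially overlapping gene sets; the collection records, for
every gene in the (ordered) union, which studies measured it.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("intescreen")

__all__ = [
    "StudyDataset",
    "MultiStudyCollection",
    "standardize",
    "build_collection",
    "read_study",
    "write_study",
    "read_collection",
    "write_collection",
]


@dataclass
class StudyDataset:
    """One study's expression matrix and binary response.

    Parameters
    ----------
    study_id : str
        Unique label for the study.
    X : ndarray, shape (n_samples, n_genes)
        Expression values, one column per gene.
    y : ndarray, shape (n_samples,)
        Binary response in {0, 1}.
    gene_ids : list of str
        Column labels; unique within the study.
    standardized : bool
        True once every column has sample mean 0 and sample SD 1 (ddof=1).
    sample_ids : list of str, optional
        Row labels; generated if absent.
    """

    study_id: str
    X: np.ndarray
    y: np.ndarray
    gene_ids: list
    standardized: bool = False
    sample_ids: list = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x genes)")
        n, d = self.X.shape
        if n < 2:
            raise ValueError(f"study {self.study_id!r}: need at least 2 samples, got {n}")
        if self.y.shape != (n,):
            raise ValueError(
                f"study {self.study_id!r}: response length {self.y.shape} "
                f"does not match {n} samples"
            )
        vals = set(np.unique(self.y).tolist())
        if not vals <= {0, 1}:
            raise ValueError(f"study {self.study_id!r}: response must be binary 0/1, saw {sorted(vals)}")
        self.y = self.y.astype(np.int8)
        if len(self.gene_ids) != d:
            raise ValueError(f"study {self.study_id!r}: {len(self.gene_ids)} gene ids for {d} columns")
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(set(self.gene_ids)) != d:
            raise ValueError(f"study {self.study_id!r}: gene ids are not unique")
        if not np.all(np.isfinite(self.X)):
            raise ValueError(f"study {self.study_id!r}: expression matrix contains missing/non-finite values")
        if self.sample_ids is None:
            self.sample_ids = [f"{self.study_id}_s{i}" for i in range(n)]
        else:
            self.sample_ids = [str(s) for s in self.sample_ids]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def has_both_classes(self) -> bool:
        return 0 < self.y.sum() < len(self.y)


def standardize(ds: StudyDataset) -> StudyDataset:
    """Center and scale every gene column to mean 0, sample SD 1 (ddof=1).

    Columns with zero variance carry no information and cannot be scaled;
    they are dropped from the study with a log message. The response is
    unchanged. Idempotent within floating-point tolerance.
    """
    X = ds.X
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        dropped = [g for g, k in zip(ds.gene_ids, keep) if not k]
        logger.warning(
            "study %s: dropping %d zero-variance gene(s): %s%s",
            ds.study_id, n_dropped, ", ".join(dropped[:5]),
            "..." if n_dropped > 5 else "",
        )
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    gene_ids = [g for g, k in zip(ds.gene_ids, keep) if k]
    return replace(ds, X=Z, gene_ids=gene_ids, standardized=True)


@dataclass
class MultiStudyCollection:
    """M studies over a shared (ordered-union) gene universe.

    ``availability[j]`` lists the indices of the studies measuring gene j;
    ``study_cols[m][j]`` gives gene j's column in study m, or -1 if absent.
    """

    studies: list
    gene_universe: list
    availability: list
    study_cols: list = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.studies) < 1:
            raise ValueError("collection needs at least one study")
        if self.study_cols is None:
            self.study_cols = []
            for ds in self.studies:
                pos = {g: i for i, g in enumerate(ds.gene_ids)}
                self.study_cols.append(
                    np.array([pos.get(g, -1) for g in self.gene_universe], dtype=np.int64)
                )

    @property
    def M(self) -> int:
        return len(self.studies)

    @property
    def n_total(self) -> int:
        return sum(ds.n_samples for ds in self.studies)

    @property
    def n_genes(self) -> int:
        return len(self.gene_universe)

    def availability_mask(self) -> np.ndarray:
        """Boolean (n_genes, M) matrix: gene j measured in study m."""
        return np.stack([c >= 0 for c in self.study_cols], axis=1)

    def aligned_matrix(self, m: int) -> np.ndarray:
        """Study m's expressions aligned to the gene universe.

        Columns for genes the study does not measure are zero (they never
        contribute to pooled likelihoods; their coefficients are treated
        as unavailable upstream).
        """
        cols = self.study_cols[m]
        X = self.studies[m].X[:, np.where(cols >= 0, cols, 0)]
        X = np.where(cols >= 0, X, 0.0)
        return X


def build_collection(datasets, min_studies: int = None) -> MultiStudyCollection:
    """Assemble studies into a collection, keeping genes measured in at
    least ``min_studies`` studies (default: all of them, i.e. fully
    matched genes only — screening statistics based on few studies are
    less reliable).
    """
    if not datasets:
        raise ValueError("no studies supplied")
    ids = [ds.study_id for ds in datasets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate study ids: {sorted(ids)}")
    for ds in datasets:
        if not ds.standardized:
            raise ValueError(f"study {ds.study_id!r} is not standardized; call standardize() first")
    M = len(datasets)
    if min_studies is None:
        min_studies = M
    if min_studies < 1:
        raise ValueError("min_studies must be >= 1")

    universe, counts, members = [], {}, {}
    for m, ds in enumerate(datasets):
        for g in ds.gene_ids:
            if g not in counts:
                universe.append(g)
                counts[g] = 0
                members[g] = []
            counts[g] += 1
            members[g].append(m)
    kept = [g for g in universe if counts[g] >= min_studies]
    if not kept:
        raise ValueError(f"no gene is measured in >= {min_studies} studies")
    n_removed = len(universe) - len(kept)
    if n_removed:
        logger.info("gene matching: removed %d gene(s) measured in < %d studies", n_removed, min_studies)
    return MultiStudyCollection(
        studies=list(datasets),
        gene_universe=kept,
        availability=[members[g] for g in kept],
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_study(expr_path, response_path, study_id: str = None, transpose: bool = False) -> StudyDataset:
    """Read one study from delimited text.

    The expression file is samples x genes with a gene-id header row and a
    sample-id first column (``transpose=True`` accepts genes x samples).
    The response file has two columns (sample_id, y) with y in {0, 1};
    rows are aligned to the expression matrix by sample id.
    """
    expr = pd.read_csv(expr_path, sep=_sep_for(expr_path), index_col=0)
    if expr.shape[1] == 0:
        raise ValueError(f"{expr_path}: no gene columns found (missing header?)")
    if transpose:
        expr = expr.T
    if expr.isna().any().any():
        raise ValueError(f"{expr_path}: missing values are not supported")
    resp = pd.read_csv(response_path, sep=_sep_for(response_path), index_col=0).iloc[:, 0]
    missing = [s for s in expr.index if s not in resp.index]
    extra = [s for s in resp.index if s not in expr.index]
    if missing or extra:
        raise ValueError(
            f"sample ids do not match between {expr_path} and {response_path}: "
            f"without response {missing[:10]}, without expression {extra[:10]}"
        )
    y = resp.reindex(expr.index).to_numpy()
    bad = set(np.unique(y).tolist()) - {0, 1}
    if bad:
        raise ValueError(f"{response_path}: non-binary response values {sorted(bad)}")
    if study_id is None:
        study_id = os.path.splitext(os.path.basename(str(expr_path)))[0]
    return StudyDataset(
        study_id=study_id,
        X=expr.to_numpy(dtype=float),
        y=y,
        gene_ids=list(expr.columns),
        sample_ids=list(expr.index.astype(str)),
    )


def write_study(ds: StudyDataset, expr_path, response_path) -> None:
    """Write a study back to the delimited-text layout read_study expects."""
    pd.DataFrame(ds.X, index=ds.sample_ids, columns=ds.gene_ids).to_csv(
        expr_path, sep=_sep_for(expr_path), index_label="sample_id"
    )
    pd.DataFrame({"y": ds.y}, index=ds.sample_ids).to_csv(
        response_path, sep=_sep_for(response_path), index_label="sample_id"
    )


def read_collection(manifest_path, min_studies: int = None, do_standardize: bool = True) -> MultiStudyCollection:
    """Read a collection from a YAML manifest.

    The manifest is a list of ``{study_id, expression, response}`` entries
    (paths relative to the manifest file).
    """
    import yaml

    with open(manifest_path) as fh:
        entries = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(str(manifest_path)))
    datasets = []
    for e in entries:
        ds = read_study(
            os.path.join(base, e["expression"]),
            os.path.join(base, e["response"]),
            study_id=e.get("study_id"),
            transpose=bool(e.get("transpose", False)),
        )
        datasets.append(standardize(ds) if do_standardize else ds)
    return build_collection(datasets, min_studies=min_studies)


def write_collection(coll: MultiStudyCollection, out_dir) -> str:
    """Write every study plus a manifest under out_dir; returns the manifest path."""
    import yaml

    os.makedirs(out_dir, exist_ok=True)
    entries = []
    for ds in coll.studies:
        expr = f"{ds.study_id}_expr.tsv"
        resp = f"{ds.study_id}_response.tsv"
        write_study(ds, os.path.join(out_dir, expr), os.path.join(out_dir, resp))
        entries.append({"study_id": ds.study_id, "expression": expr, "response": resp})
    manifest = os.path.join(out_dir, "manifest.yaml")
    with open(manifest, "w") as fh:
        yaml.safe_dump(entries, fh)
    return manifest
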