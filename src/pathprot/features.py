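"""Descriptor-matrix ingestion, cleaning and dimensional reduction.

Compounds arrive as a PaDEL-style CSV (first column ``Name``, ~1848 numeric
physicochemical/topological descriptor columns) plus a label file assigning
each compound to {agonist, antagonist, query}.  Agonists of alpha7 nAChR
carry the neuroprotective (positive) training label, antagonists the
negative one, and query compounds are the analogs to be predicted.

Two reductions feed the downstream perceptron:

* PCA on the standardized matrix (correlation-matrix PCA), keeping the top
  ``k`` axes and reporting their cumulative explained-variance fraction.
* k-means as a feature map: each compound is represented by its Euclidean
  distances to the ``k`` cluster centroids, with explained variance defined
  as the between-cluster over total sum of squares.

All reduction models are fit on labeled compounds only and then applied to
queries, so no information about query identity leaks into the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "DescriptorMatrix",
    "ReducedFeatures",
    "load_descriptors",
    "clean_descriptors",
    "pca_reduce",
    "kmeans_reduce",
]

log = logging.getLogger(__name__)

AGONIST = "agonist"
ANTAGONIST = "antagonist"
QUERY = "query"
_VALID_LABELS = {AGONIST, ANTAGONIST, QUERY}


@dataclass
class DescriptorMatrix:
    compound_ids: list[str]
    labels: list[str]
    X: np.ndarray
    descriptor_names: list[str]

    def __post_init__(self):
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicate compound ids")
        if len(self.labels) != len(self.compound_ids):
            raise ValueError("labels must cover every compound row")
        bad = set(self.labels) - _VALID_LABELS
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    @property
    def labeled_mask(self) -> np.ndarray:
        return np.array([l != QUERY for l in self.labels])

    @property
    def y(self) -> np.ndarray:
        """Binomial target on labeled rows: agonist/neuroprotective = 1."""
        return np.array([1.0 if l == AGONIST else 0.0
                         for l in self.labels if l != QUERY])

    @property
    def query_ids(self) -> list[str]:
        return [c for c, l in zip(self.compound_ids, self.labels) if l == QUERY]

    def to_csv(self, descriptors_path: str | Path, labels_path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=self.descriptor_names)
        df.insert(0, "Name", self.compound_ids)
        df.to_csv(descriptors_path, index=False)
        pd.DataFrame({"Name": self.compound_ids, "label": self.labels}).to_csv(
            labels_path, index=False)


@dataclass
class ReducedFeatures:
    coordinates: np.ndarray
    method: str
    explained_variance: float
    compound_ids: list[str]
    labels: list[str]
    model_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.explained_variance <= 1.0 + 1e-12:
            raise ValueError("explained_variance must lie in [0, 1]")

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.coordinates,
                          columns=[f"{self.method}_{i + 1}" for i in range(self.k)])
        df.insert(0, "Name", self.compound_ids)
        df.insert(1, "label", self.labels)
        df.to_csv(path, index=False)
        return path


def load_descriptors(csv_path: str | Path, labels_path: str | Path) -> DescriptorMatrix:
    """Read a PaDEL-dialect descriptor CSV and join compound labels by name.

    Non-numeric cells are coerced to missing (and logged); a compound
    missing from the label file is an error.
    """
    df = pd.read_csv(csv_path)
    name_col = df.columns[0]
    ids = df[name_col].astype(str).tolist()
    raw = df.drop(columns=[name_col])
    X = raw.apply(pd.to_numeric, errors="coerce")
    n_coerced = int((X.isna() & raw.notna()).sum().sum())
    if n_coerced:
        log.warning("coerced %d non-numeric descriptor cells to missing", n_coerced)

    lab = pd.read_csv(labels_path)
    lab.columns = [c.lower() for c in lab.columns]
    label_map = dict(zip(lab.iloc[:, 0].astype(str), lab["label"].astype(str)))
    missing = [c for c in ids if c not in label_map]
    if missing:
        raise ValueError(f"compounds without labels: {missing}")
    return DescriptorMatrix(
        compound_ids=ids,
        labels=[label_map[c] for c in ids],
        X=X.to_numpy(dtype=float),
        descriptor_names=list(X.columns),
    )


def clean_descriptors(dm: DescriptorMatrix) -> DescriptorMatrix:
    """Drop unusable columns and z-score the rest.

    Columns with any missing value, or zero variance over the labeled
    compounds, are dropped.  Remaining columns are standardized to mean 0 /
    sd 1 computed on labeled rows only; query rows are transformed with the
    same parameters.
    """
    labeled = dm.labeled_mask
    finite = ~np.isnan(dm.X).any(axis=0)
    sd = np.where(finite, np.nanstd(dm.X[labeled], axis=0, ddof=0), 0.0)
    keep = finite & (sd > 0)
    if keep.sum() < 2:
        raise ValueError(
            f"only {int(keep.sum())} descriptor columns survive cleaning; need >= 2")
    Xk = dm.X[:, keep]
    mean = Xk[labeled].mean(axis=0)
    Z = (Xk - mean) / sd[keep]
    return replace(dm, X=Z,
                   descriptor_names=[n for n, k in zip(dm.descriptor_names, keep) if k])


def pca_reduce(dm: DescriptorMatrix, k: int = 3) -> ReducedFeatures:
    """Project on the top-k principal axes fit on labeled compounds."""
    labeled = dm.labeled_mask
    n_lab, n_cols = int(labeled.sum()), dm.X.shape[1]
    if k > min(n_lab - 1, n_cols):
        raise ValueError(
            f"k={k} exceeds min(labeled rows - 1, columns) = {min(n_lab - 1, n_cols)}")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(dm.X[labeled])
    coords = pca.transform(dm.X)
    return ReducedFeatures(
        coordinates=coords,
        method="pca",
        explained_variance=float(np.clip(pca.explained_variance_ratio_.sum(), 0.0, 1.0)),
        compound_ids=list(dm.compound_ids),
        labels=list(dm.labels),
        model_params={"mean": pca.mean_, "components": pca.components_,
                      "explained_variance_ratio": pca.explained_variance_ratio_},
    )


def kmeans_reduce(dm: DescriptorMatrix, k: int = 2, seed: int | None = None,
                  n_restarts: int = 50) -> ReducedFeatures:
    """k-means feature map: per-compound distances to the k centroids.

    Explained variance is the between-cluster share of the total sum of
    squares on labeled compounds.  A fully degenerate matrix (all labeled
    points identical) yields explained variance 0 with a warning rather
    than an error.
    """
    labeled = dm.labeled_mask
    n_lab = int(labeled.sum())
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n_lab:
        raise ValueError(f"k={k} must be smaller than the {n_lab} labeled compounds")
    Xl = dm.X[labeled]
    tss = float(((Xl - Xl.mean(axis=0)) ** 2).sum())
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    km.fit(Xl)
    if tss <= 0:
        log.warning("total sum of squares is 0 (identical compounds); "
                    "explained variance defined as 0")
        ev = 0.0
    else:
        ev = float(np.clip(1.0 - km.inertia_ / tss, 0.0, 1.0))
    coords = cdist(dm.X, km.cluster_centers_)
    return ReducedFeatures(
        coordinates=coords,
        method="kmeans",
        explained_variance=ev,
        compound_ids=list(dm.compound_ids),
        labels=list(dm.labels),
        model_params={"centroids": km.cluster_centers_, "inertia": float(km.inertia_),
                      "labels_": km.labels_},
    )
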