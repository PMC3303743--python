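"""Comparison objects derived from structures and ensembles.

Every structure or ensemble is reduced to objects that can be correlated the
way SHAPE profiles are:

* the binary pair matrix of a single structure (1 at (i,j) and (j,i) iff i
  pairs j);
* the partition matrix of an ensemble — the entrywise mean of its members'
  pair matrices, i.e. the empirical probability that i pairs j;
* per-nucleotide "structure vectors" in [0, 1] where 1 means unpaired, so that
  high values align with high SHAPE reactivity;
* the Z centroid — the structure made of exactly the pairs with ensemble
  probability > 50% (always a valid nested structure: two conflicting pairs
  are mutually exclusive events, so their probabilities cannot both exceed
  one half);
* PCA landscape projections and k-means cluster occupancies, with a medoid
  "cluster centroid structure" for the most populated cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .fold import SecondaryStructure, StructureEnsemble

__all__ = [
    "PairProbabilityMatrix",
    "LandscapeProjection",
    "structure_to_pair_matrix",
    "ensemble_partition_matrix",
    "pairing_vector",
    "z_centroid",
    "structure_binary_vector",
    "pca_project",
    "cluster_centroid_structure",
]


@dataclass
class PairProbabilityMatrix:
    """Symmetric matrix of pairing probabilities with zero diagonal."""

    n: int
    p: np.ndarray
    provenance: str = "exact"  # "exact" or "sampled(<size>)"

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.n, self.n):
            raise ValueError("matrix shape must be (n, n)")
        if not np.allclose(self.p, self.p.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if np.any(self.p < -1e-12) or np.any(self.p > 1 + 1e-9):
            raise ValueError("entries must lie in [0, 1]")
        rows = self.p.sum(axis=1)
        if np.any(rows > 1 + 1e-6):
            raise ValueError("row sums must not exceed 1")

    def to_sparse_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# i\tj\tp\n")
            for i in range(self.n):
                for j in range(i + 1, self.n):
                    if self.p[i, j] > 0:
                        fh.write(f"{i + 1}\t{j + 1}\t{float(self.p[i, j])!r}\n")

    @classmethod
    def from_sparse_text(cls, path, n: int, provenance: str = "external") -> "PairProbabilityMatrix":
        p = np.zeros((n, n))
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                i, j, v = line.split()
                p[int(i) - 1, int(j) - 1] = float(v)
                p[int(j) - 1, int(i) - 1] = float(v)
        return cls(n=n, p=p, provenance=provenance)


def structure_to_pair_matrix(s: SecondaryStructure) -> np.ndarray:
    """Binary symmetric pair matrix of a single structure."""
    m = np.zeros((s.n, s.n))
    for i, j in s.pairs:
        m[i - 1, j - 1] = 1.0
        m[j - 1, i - 1] = 1.0
    return m


def ensemble_partition_matrix(e: StructureEnsemble) -> PairProbabilityMatrix:
    """Entrywise mean of the members' pair matrices (sampled partition matrix)."""
    acc = np.zeros((e.sequence.n, e.sequence.n))
    for s in e.structures:
        for i, j in s.pairs:
            acc[i - 1, j - 1] += 1.0
    acc /= e.size
    acc = acc + acc.T
    return PairProbabilityMatrix(n=e.sequence.n, p=acc, provenance=f"sampled({e.size})")


def pairing_vector(P: PairProbabilityMatrix) -> np.ndarray:
    """Per-nucleotide probability of being unpaired: 1 - row sum of P."""
    return np.clip(1.0 - P.p.sum(axis=1), 0.0, 1.0)


def z_centroid(P: PairProbabilityMatrix, min_loop: int = 3) -> SecondaryStructure:
    """Structure made of exactly the pairs with probability > 0.5."""
    idx = np.argwhere(np.triu(P.p) > 0.5)
    s = SecondaryStructure(
        n=P.n, pairs=frozenset((int(i) + 1, int(j) + 1) for i, j in idx)
    )
    s.validate(min_loop=min_loop)
    return s


def structure_binary_vector(s: SecondaryStructure) -> np.ndarray:
    """Per-nucleotide unpaired indicator: 1 if unpaired, 0 if paired."""
    v = np.ones(s.n)
    for i, j in s.pairs:
        v[i - 1] = 0.0
        v[j - 1] = 0.0
    return v


@dataclass
class LandscapeProjection:
    """Pooled PC1/PC2 coordinates plus k-means labels and occupancies."""

    points: pd.DataFrame  # columns: variant, pc1, pc2, cluster
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    occupancies: pd.DataFrame  # index variant, columns cluster ids, rows sum to 1
    k: int
    seed: int


def _binary_matrix(ensembles: list[tuple[str, StructureEnsemble]]) -> tuple[np.ndarray, list[str]]:
    rows, labels = [], []
    for variant, e in ensembles:
        for s in e.structures:
            rows.append(structure_binary_vector(s))
            labels.append(variant)
    return np.asarray(rows), labels


def pca_project(
    ensembles: list[tuple[str, StructureEnsemble]],
    k: int = 4,
    seed: int = 0,
) -> LandscapeProjection:
    """Project pooled WT + mutant ensembles onto PC1/PC2 and cluster.

    PCA is fitted on the pooled per-structure binary (unpaired) vectors;
    k-means runs on the two-component projection with a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X, labels = _binary_matrix(ensembles)
    if X.shape[0] < 10:
        raise ValueError("need a pooled ensemble of >= 10 structures")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("zero-variance pooled structure matrix: PCA undefined")
    pca = PCA(n_components=2, random_state=seed)
    coords = pca.fit_transform(X)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    clusters = km.fit_predict(coords)
    points = pd.DataFrame(
        {"variant": labels, "pc1": coords[:, 0], "pc2": coords[:, 1], "cluster": clusters}
    )
    occ = (
        points.groupby("variant")["cluster"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=range(k), fill_value=0.0)
    )
    return LandscapeProjection(
        points=points,
        loadings=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        occupancies=occ,
        k=k,
        seed=seed,
    )


def cluster_centroid_structure(
    e: StructureEnsemble, k: int = 4, seed: int = 0
) -> SecondaryStructure:
    """Medoid of the most populated k-means cluster of one ensemble.

    The representative is the member structure closest (Euclidean, in PC
    space) to its cluster mean — an arithmetic mean of binary vectors is not
    itself a structure.  k = 1 returns the medoid of the whole ensemble.
    Cluster-size ties resolve to the lowest cluster index.
    """
    if e.size < max(k, 1):
        raise ValueError("ensemble smaller than k")
    X = np.asarray([structure_binary_vector(s) for s in e.structures])
    if k == 1 or np.allclose(X.var(axis=0), 0):
        center = X.mean(axis=0)
        idx = int(np.argmin(((X - center) ** 2).sum(axis=1)))
        return e.structures[idx]
    n_comp = min(2, int(np.linalg.matrix_rank(X - X.mean(axis=0))))
    pca = PCA(n_components=max(n_comp, 1), random_state=seed)
    coords = pca.fit_transform(X)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    clusters = km.fit_predict(coords)
    sizes = np.bincount(clusters, minlength=k)
    top = int(np.argmax(sizes))  # argmax takes the lowest index on ties
    members = np.nonzero(clusters == top)[0]
    center = coords[members].mean(axis=0)
    best = members[np.argmin(((coords[members] - center) ** 2).sum(axis=1))]
    return e.structures[int(best)]
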