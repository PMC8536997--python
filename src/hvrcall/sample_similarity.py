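"""Presence/absence analyses across samples: Jaccard similarity,
agglomerative clustering (single/complete linkage), classical MDS and a
majorize-minimize logistic PCA for binary data."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit


@dataclass
class BinaryAlleleMatrix:
    """Samples x alleles 0/1 matrix."""

    data: pd.DataFrame  # index: sample ids; columns: allele peptides

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")
        if (values.sum(axis=1) == 0).any():
            raise ValueError("sample with zero alleles")
        if (values.sum(axis=0) == 0).any():
            raise ValueError("allele column with no occurrences")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def alleles(self) -> list[str]:
        return list(self.data.columns)


def build_matrix(per_sample_sets: Mapping[str, Iterable[str]]) -> BinaryAlleleMatrix:
    """Binary matrix over the union of all samples' allele sets.

    Columns are ordered by first appearance across samples (sample order
    as given), making the layout deterministic.
    """
    if len(per_sample_sets) < 2:
        raise ValueError("need at least 2 samples")
    sets = {s: set(v) for s, v in per_sample_sets.items()}
    for s, v in sets.items():
        if not v:
            raise ValueError(f"sample {s!r} has zero alleles")
    columns: dict[str, None] = {}
    for s in per_sample_sets:
        for peptide in sorted(sets[s]):
            columns.setdefault(peptide)
    alleles = list(columns)
    rows = [[1 if a in sets[s] else 0 for a in alleles] for s in per_sample_sets]
    df = pd.DataFrame(rows, index=list(per_sample_sets), columns=alleles, dtype=np.int8)
    return BinaryAlleleMatrix(df)


def jaccard_matrix(matrix: BinaryAlleleMatrix) -> pd.DataFrame:
    """Pairwise |intersection| / |union| of the samples' allele sets."""
    X = matrix.data.to_numpy(dtype=np.int64)
    inter = X @ X.T
    sizes = X.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    J = inter / union
    return pd.DataFrame(J, index=matrix.samples, columns=matrix.samples)


@dataclass(frozen=True)
class Merge:
    step: int
    height: float
    left: frozenset[str]
    right: frozenset[str]

    @property
    def members(self) -> frozenset[str]:
        return self.left | self.right


def linkage_cluster(dissimilarity: pd.DataFrame, method: str = "complete") -> list[Merge]:
    """Naive agglomerative clustering returning the ordered merge list.

    ``method`` is ``"single"`` (minimum) or ``"complete"`` (maximum)
    inter-cluster distance.  Ties are broken by merging the pair whose
    lexicographically smallest representative labels sort first, so
    dendrograms are reproducible.
    """
    if method not in ("single", "complete"):
        raise ValueError(f"unknown linkage method {method!r}")
    D = dissimilarity.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("dissimilarity must be square symmetric")
    if (D < 0).any() or not np.allclose(np.diag(D), 0):
        raise ValueError("dissimilarity must be non-negative with zero diagonal")
    labels = [str(x) for x in dissimilarity.index]
    dist = {
        frozenset((a, b)): D[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }
    clusters: list[frozenset[str]] = [frozenset((l,)) for l in labels]
    cdist: dict[frozenset[frozenset[str]], float] = {}
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            a, b = clusters[i], clusters[j]
            cdist[frozenset((a, b))] = dist[frozenset((next(iter(a)), next(iter(b))))]
    agg = min if method == "single" else max

    merges: list[Merge] = []
    step = 0
    while len(clusters) > 1:
        def pair_key(a: frozenset[str], b: frozenset[str]):
            reps = sorted((min(a), min(b)))
            return (cdist[frozenset((a, b))], reps[0], reps[1])

        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                key = pair_key(clusters[i], clusters[j])
                if best is None or key < best[0]:
                    best = (key, clusters[i], clusters[j])
        (_, a, b) = best[0], best[1], best[2]
        height = cdist[frozenset((a, b))]
        left, right = sorted((a, b), key=min)
        merged = a | b
        merges.append(Merge(step, height, left, right))
        step += 1
        clusters = [c for c in clusters if c is not a and c is not b]
        for c in clusters:
            cdist[frozenset((merged, c))] = agg(
                cdist.pop(frozenset((a, c))), cdist.pop(frozenset((b, c)))
            )
        cdist.pop(frozenset((a, b)))
        clusters.append(merged)
    return merges


def to_newick(merges: Sequence[Merge], labels: Sequence[str]) -> str:
    """Serialize a merge list as a Newick string with branch lengths."""
    node_repr: dict[frozenset[str], str] = {frozenset((l,)): l for l in labels}
    node_height: dict[frozenset[str], float] = {frozenset((l,)): 0.0 for l in labels}
    for m in merges:
        lb = node_repr.pop(m.left)
        rb = node_repr.pop(m.right)
        bl = max(m.height - node_height[m.left], 0.0)
        br = max(m.height - node_height[m.right], 0.0)
        node_repr[m.members] = f"({lb}:{bl:g},{rb}:{br:g})"
        node_height[m.members] = m.height
    (root,) = node_repr.values()
    return root + ";"


def classical_mds(dissimilarity: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Torgerson scaling: double-center squared distances, top-k eigenpairs.

    Coordinates reproduce the input distances exactly when the input is
    Euclidean-embeddable in ``k`` dimensions.  Components with
    non-positive eigenvalues are zeroed.
    """
    D = dissimilarity.to_numpy(dtype=float)
    n = D.shape[0]
    if D.shape[1] != n or not np.allclose(D, D.T):
        raise ValueError("dissimilarity must be square symmetric")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:k]
    lam = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(lam)[None, :]
    cols = [f"mds{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=dissimilarity.index, columns=cols)


@dataclass
class LogisticPCAResult:
    scores: pd.DataFrame  # n x k
    loadings: np.ndarray  # m x k, orthonormal columns
    mu: np.ndarray  # length m column offsets
    deviance_trace: list[float] = field(default_factory=list)
    natural_parameters: np.ndarray | None = None

    @property
    def fitted_probabilities(self) -> np.ndarray:
        return expit(self.natural_parameters)


def _bernoulli_deviance(X: np.ndarray, theta: np.ndarray) -> float:
    p = np.clip(expit(theta), 1e-12, 1 - 1e-12)
    return float(-2.0 * (X * np.log(p) + (1 - X) * np.log1p(-p)).sum())


def logistic_pca(
    matrix: BinaryAlleleMatrix,
    k: int = 2,
    m: float = 4.0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> LogisticPCAResult:
    """Low-rank natural-parameter logistic PCA via majorize-minimize.

    Saturated natural parameters are represented as ``m * (2X - 1)``; the
    model projects their column-offset-centered version onto a rank-``k``
    orthonormal subspace.  Each iteration majorizes the Bernoulli deviance
    by a quadratic (curvature 1/4) and solves the offset and subspace
    updates in closed form, so the deviance trace is non-increasing.
    """
    X = matrix.data.to_numpy(dtype=float)
    n, p = X.shape
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= min(n, p):
        raise ValueError("k must be smaller than min(n_samples, n_alleles)")
    theta_tilde = m * (2.0 * X - 1.0)
    mu = theta_tilde.mean(axis=0)
    E = theta_tilde - mu
    # initial subspace: leading right singular vectors of the centered
    # saturated parameters
    _, _, Vt = np.linalg.svd(E, full_matrices=False)
    V = Vt[:k].T

    trace: list[float] = []
    theta = mu + E @ V @ V.T
    for _ in range(max_iter):
        dev = _bernoulli_deviance(X, theta)
        trace.append(dev)
        if len(trace) > 1 and abs(trace[-2] - dev) <= tol * abs(trace[-2]):
            break
        Z = theta + 4.0 * (X - expit(theta))
        # offset update: argmin ||Z - mu - (theta_tilde - mu) V V'||^2
        mu = (Z - theta_tilde @ V @ V.T).mean(axis=0) @ (
            np.eye(p) - V @ V.T
        ) + (theta_tilde.mean(axis=0)) @ (V @ V.T)
        E = theta_tilde - mu
        Zc = Z - mu
        B = Zc.T @ E + E.T @ Zc - E.T @ E
        eigval, eigvec = np.linalg.eigh(B)
        V = eigvec[:, np.argsort(eigval)[::-1][:k]]
        theta = mu + E @ V @ V.T

    scores = E @ V
    cols = [f"lpca{i + 1}" for i in range(k)]
    return LogisticPCAResult(
        scores=pd.DataFrame(scores, index=matrix.samples, columns=cols),
        loadings=V,
        mu=mu,
        deviance_trace=trace,
        natural_parameters=theta,
    )


@dataclass
class SimilarityResult:
    jaccard: pd.DataFrame
    dissimilarity: pd.DataFrame
    linkage: dict[str, list[Merge]]
    mds_coords: pd.DataFrame
    lpca: LogisticPCAResult


def analyze_similarity(
    per_sample_sets: Mapping[str, Iterable[str]],
    k: int = 2,
    m: float = 4.0,
    linkage_methods: Sequence[str] = ("single", "complete"),
) -> SimilarityResult:
    """Run the full presence/absence similarity suite.

    ``k`` is clamped to the largest feasible rank (``min(n, m) - 1``) so
    small sample sets degrade gracefully instead of erroring.
    """
    matrix = build_matrix(per_sample_sets)
    k = max(1, min(k, min(matrix.data.shape) - 1))
    J = jaccard_matrix(matrix)
    D = 1.0 - J
    np.fill_diagonal(D.values, 0.0)
    linkage = {meth: linkage_cluster(D, meth) for meth in linkage_methods}
    mds = classical_mds(D, k=k)
    lpca = logistic_pca(matrix, k=k, m=m)
    return SimilarityResult(J, D, linkage, mds, lpca)
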