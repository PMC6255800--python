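"""Correspondence between the semantic space and the ratings space.

The central empirical claim behind zero-shot transfer is that the two
descriptor-by-descriptor correlation structures -- one computed from how
molecules are *rated* on the descriptors, the other from the descriptors'
*word embeddings* -- are similar.  This module builds the two
cross-correlation matrices and tests their correspondence:

* Procrustes dissimilarity against row-permuted surrogates (does the matrix
  of semantic correlations, as a shape, match the ratings one better than
  chance when descriptor identity is destroyed?);
* Spearman correlation between the per-descriptor maxima of the two
  matrices;
* smoothness of per-descriptor prediction performance over the semantic
  space (nearest-neighbor correlation and distance-weighted k-NN
  regression, both with permutation nulls);

plus the descriptive organization tools: average-linkage clustering on
cosine distances and 2-D metric multidimensional scaling.

All permutation p-values use the add-one estimator
``p = (1 + #{surrogate at least as extreme}) / (1 + n_perm)``, so the
smallest reportable p is ``1 / (n_perm + 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr, wilcoxon
from sklearn.manifold import MDS

from .containers import DescriptorLexicon, RatingsTable, SemanticSpace

logger = logging.getLogger(__name__)

__all__ = [
    "CrossCorrMatrix",
    "DendrogramSpec",
    "MDSMap",
    "ProcrustesTest",
    "cross_correlation",
    "procrustes_similarity_test",
    "maxima_spearman",
    "semantic_dendrogram",
    "mds_map",
    "nn_smoothness_test",
    "knn_perm_test",
]


@dataclass(frozen=True)
class CrossCorrMatrix:
    """Target x source matrix of Pearson correlations between profiles."""

    rows: DescriptorLexicon
    cols: DescriptorLexicon
    values: np.ndarray
    basis: str = "ratings"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.rows), len(self.cols)):
            raise ValueError("values shape must match (rows, cols) lexicons")
        finite = values[np.isfinite(values)]
        if finite.size and (finite.min() < -1.0 - 1e-9 or finite.max() > 1.0 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        if self.basis not in ("ratings", "semantic"):
            raise ValueError(f"unknown basis: {self.basis!r}")
        object.__setattr__(self, "values", values)


def _corr_profiles(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlations between all rows of A and all rows of B."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    a_norm = np.linalg.norm(Ac, axis=1)
    b_norm = np.linalg.norm(Bc, axis=1)
    bad_a, bad_b = a_norm == 0, b_norm == 0
    if bad_a.any() or bad_b.any():
        logger.warning(
            "%d constant profiles produce NaN correlations",
            int(bad_a.sum() + bad_b.sum()),
        )
    a_norm[bad_a] = np.nan
    b_norm[bad_b] = np.nan
    return (Ac @ Bc.T) / np.outer(a_norm, b_norm)


def cross_correlation(
    source: RatingsTable | SemanticSpace,
    target: RatingsTable | SemanticSpace,
    basis: str = "ratings",
) -> CrossCorrMatrix:
    """Correlate every target-descriptor profile with every source one.

    In the ``ratings`` basis, a descriptor's profile is its rating vector
    across the shared molecules (the two tables must be row-aligned); in the
    ``semantic`` basis it is the descriptor's embedding vector.  Entry
    (t, s) is the Pearson correlation of target descriptor t's profile with
    source descriptor s's.
    """
    if basis == "ratings":
        if not isinstance(source, RatingsTable) or not isinstance(target, RatingsTable):
            raise TypeError("ratings basis requires two RatingsTables")
        if list(source.molecule_ids) != list(target.molecule_ids):
            raise ValueError("ratings tables must be row-aligned on shared molecules")
        src_profiles, tgt_profiles = source.values.T, target.values.T
    elif basis == "semantic":
        if not isinstance(source, SemanticSpace) or not isinstance(target, SemanticSpace):
            raise TypeError("semantic basis requires two SemanticSpaces")
        if source.dim != target.dim:
            raise ValueError("semantic spaces must share the embedding dimension")
        src_profiles, tgt_profiles = source.vectors, target.vectors
    else:
        raise ValueError(f"unknown basis: {basis!r}")
    return CrossCorrMatrix(
        rows=target.lexicon,
        cols=source.lexicon,
        values=_corr_profiles(tgt_profiles, src_profiles),
        basis=basis,
    )


class ProcrustesTest(NamedTuple):
    dissimilarity: float
    p_value: float
    wilcoxon_p: float
    n_perm: int


def procrustes_similarity_test(
    M1: np.ndarray, M2: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> ProcrustesTest:
    """Procrustes dissimilarity of two matrices against a permutation null.

    The observed dissimilarity (after optimal translation, scaling and
    orthogonal rotation) is compared with the dissimilarities obtained from
    row-permuted surrogates of ``M2``: permuting rows destroys the
    descriptor correspondence, which is the hypothesis under test.  Besides
    the permutation-fraction p-value, a one-sided Wilcoxon signed-rank p for
    "surrogate dissimilarities exceed the observed one" is reported.
    """
    M1 = np.atleast_2d(np.asarray(M1, dtype=float))
    M2 = np.atleast_2d(np.asarray(M2, dtype=float))
    if M1.shape != M2.shape:
        raise ValueError("matrices must have equal shapes")
    if np.allclose(M1, M1.ravel()[0]) or np.allclose(M2, M2.ravel()[0]):
        raise ValueError("degenerate (constant) input matrix")
    _, _, d_obs = procrustes(M1, M2)
    rng = np.random.default_rng(seed)
    d_perm = np.empty(n_perm)
    for b in range(n_perm):
        _, _, d_perm[b] = procrustes(M1, M2[rng.permutation(M2.shape[0])])
    p = (1.0 + np.sum(d_perm <= d_obs)) / (1.0 + n_perm)
    diffs = d_perm - d_obs
    if np.all(diffs == 0):
        w_p = 1.0
    else:
        w_p = float(wilcoxon(diffs, alternative="greater").pvalue)
    return ProcrustesTest(float(d_obs), float(p), w_p, n_perm)


def maxima_spearman(
    M_ratings: CrossCorrMatrix, M_semantic: CrossCorrMatrix, axis: str = "source"
) -> tuple[float, float]:
    """Spearman correlation between per-descriptor maxima of the two matrices.

    For ``axis='source'``, each source descriptor contributes its maximum
    correlation over target descriptors (one value per source descriptor,
    from each matrix); ``axis='target'`` takes maxima the other way.  A high
    rank correlation between the two maxima sequences says the best-matching
    partner strengths agree between the ratings and semantic views.
    """
    if list(M_ratings.rows) != list(M_semantic.rows) or list(M_ratings.cols) != list(
        M_semantic.cols
    ):
        raise ValueError("matrices must share both lexicons")
    if axis == "source":
        a = np.nanmax(M_ratings.values, axis=0)
        b = np.nanmax(M_semantic.values, axis=0)
    elif axis == "target":
        a = np.nanmax(M_ratings.values, axis=1)
        b = np.nanmax(M_semantic.values, axis=1)
    else:
        raise ValueError(f"axis must be 'source' or 'target', got {axis!r}")
    good = np.isfinite(a) & np.isfinite(b)
    if not good.all():
        logger.warning("dropping %d NaN maxima", int((~good).sum()))
    rho, p = spearmanr(a[good], b[good])
    return float(rho), float(p)


@dataclass(frozen=True)
class DendrogramSpec:
    """Average-linkage merge tree on cosine distances."""

    merges: np.ndarray  # scipy linkage matrix [(n-1) x 4]
    labels: tuple[str, ...]
    leaf_order: tuple[int, ...]

    def __post_init__(self) -> None:
        merges = np.asarray(self.merges, dtype=float)
        if merges.size and np.any(np.diff(merges[:, 2]) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")
        object.__setattr__(self, "merges", merges)

    def to_newick(self) -> str:
        """The merge tree as a Newick string with height-derived branch lengths."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: _quote_newick(self.labels[i]) for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[n + k] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
            height[n + k] = h
        root = n + len(self.merges) - 1 if len(self.merges) else 0
        return node[root] + ";"


def _quote_newick(label: str) -> str:
    return label.replace(" ", "_").replace("(", "").replace(")", "").replace(",", "")


def semantic_dendrogram(space: SemanticSpace) -> DendrogramSpec:
    """Agglomerative average-linkage tree on cosine distances between embeddings."""
    if len(space.lexicon) < 2:
        raise ValueError("need at least 2 descriptors")
    norms = np.linalg.norm(space.vectors, axis=1)
    if np.any(norms == 0):
        bad = [space.lexicon[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero-norm embedding for descriptor(s): {bad}")
    Z = linkage(space.vectors, method="average", metric="cosine")
    return DendrogramSpec(
        merges=Z,
        labels=tuple(space.lexicon),
        leaf_order=tuple(int(i) for i in leaves_list(Z)),
    )


@dataclass(frozen=True)
class MDSMap:
    coords: np.ndarray
    stress: float
    labels: tuple[str, ...] = ()


def mds_map(
    space_or_profiles: SemanticSpace | np.ndarray,
    dim: int = 2,
    seed: int = 0,
    n_init: int = 8,
) -> MDSMap:
    """Metric MDS (stress majorization) of items under cosine distance.

    Accepts a semantic space (items = descriptors, profiles = embeddings) or
    any items x features array (e.g. descriptors as rating profiles over
    molecules).  Uses seeded random initialization with best-of-``n_init``
    restarts; identical items simply collapse onto the same point.
    """
    if isinstance(space_or_profiles, SemanticSpace):
        X = space_or_profiles.vectors
        labels = tuple(space_or_profiles.lexicon)
    else:
        X = np.atleast_2d(np.asarray(space_or_profiles, dtype=float))
        labels = ()
    if X.shape[0] < 3:
        raise ValueError("need at least 3 items")
    D = squareform(pdist(X, metric="cosine"))
    if np.any(~np.isfinite(D)):
        raise ValueError("cosine distance undefined (zero-norm profile)")
    if np.any(squareform(D) == 0):
        logger.warning("identical items present; they will collapse in the map")
    mds = MDS(
        n_components=dim,
        metric="precomputed",
        metric_mds=True,
        n_init=n_init,
        init="random",
        random_state=seed,
        normalized_stress=False,
    )
    coords = mds.fit_transform(D)
    return MDSMap(coords=coords, stress=float(mds.stress_), labels=labels)


def _cosine_distance_matrix(space: SemanticSpace) -> np.ndarray:
    D = squareform(pdist(space.vectors, metric="cosine"))
    if np.any(~np.isfinite(D)):
        raise ValueError("cosine distance undefined (zero-norm embedding)")
    return D


def _rowwise_pearson(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Pearson r of vector y with each row of X."""
    yc = y - y.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(yc) * np.linalg.norm(Xc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Xc @ yc) / denom


def nn_smoothness_test(
    perf: np.ndarray,
    space: SemanticSpace,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Is per-descriptor performance smooth over the semantic space?

    Computes the Pearson correlation between each descriptor's score and the
    score of its cosine-nearest neighbor.  The null redirects each
    descriptor's nearest neighbor through a random relabeling of the
    descriptors and recomputes the correlation; p is the add-one-smoothed
    fraction of surrogate correlations at least as large as the observed
    one.  A constant performance vector has no defined correlation: returns
    (NaN, 1.0).
    """
    perf = np.asarray(perf, dtype=float).ravel()
    n = perf.size
    if n != len(space.lexicon):
        raise ValueError("perf must align with the lexicon")
    if n < 5:
        raise ValueError("need at least 5 descriptors")
    if np.std(perf) == 0.0:
        logger.warning("constant performance vector: smoothness undefined")
        return float("nan"), 1.0
    D = _cosine_distance_matrix(space)
    np.fill_diagonal(D, np.inf)
    nn = np.argmin(D, axis=1)  # ties resolve to the lowest index (lexicon order)
    r_obs = float(np.corrcoef(perf, perf[nn])[0, 1])

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    neighbor_vals = perf[perms[:, nn]]  # [n_perm x n]
    r_perm = _rowwise_pearson(perf, neighbor_vals)
    r_perm = np.where(np.isfinite(r_perm), r_perm, -np.inf)
    p = (1.0 + np.sum(r_perm >= r_obs)) / (1.0 + n_perm)
    return r_obs, float(p)


def knn_perm_test(
    perf: np.ndarray,
    space: SemanticSpace,
    k: int = 1,
    n_perm: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Leave-self-out distance-weighted k-NN regression of performance.

    Each descriptor's score is predicted as the 1/distance-weighted average
    of its k nearest semantic neighbors' scores; the statistic is the mean
    squared error.  The permutation null relabels the descriptors before the
    neighbor averaging, and p is the add-one-smoothed fraction of surrogate
    MSEs at most the observed one.  Zero cosine distances fall back to rank
    weighting (1/rank) for the affected descriptor.
    """
    perf = np.asarray(perf, dtype=float).ravel()
    n = perf.size
    if n != len(space.lexicon):
        raise ValueError("perf must align with the lexicon")
    if not 1 <= k < n:
        raise ValueError("need 1 <= k < n")
    D = _cosine_distance_matrix(space)
    np.fill_diagonal(D, np.inf)
    W = np.zeros((n, n))
    for i in range(n):
        nbrs = np.argsort(D[i], kind="stable")[:k]
        d = D[i, nbrs]
        if np.any(d == 0):
            logger.warning("zero cosine distance at descriptor %d: rank weighting", i)
            wts = 1.0 / np.arange(1, k + 1)
        else:
            wts = 1.0 / d
        W[i, nbrs] = wts / wts.sum()
    mse_obs = float(np.mean((perf - W @ perf) ** 2))

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    preds = W @ perf[perms].T  # [n x n_perm]
    mse_perm = np.mean((perf[:, None] - preds) ** 2, axis=0)
    p = (1.0 + np.sum(mse_perm <= mse_obs)) / (1.0 + n_perm)
    return mse_obs, float(p)
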