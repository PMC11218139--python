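"""Unconstrained ordination and distance-based hypothesis tests.

PCA operates on the (centered, optionally standardised) feature matrix;
PCoA (metric multidimensional scaling) on any sample dissimilarity matrix,
here typically Bray-Curtis. PERMANOVA partitions the squared dissimilarities
by a grouping factor and assesses the pseudo-F by permutation; fuzzy set
ordination (FSO, Roberts' single-variable formulation) asks how well a
continuous covariate is expressed in community structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .errors import ParameterError, ValidationError
from .io import FeatureTable

__all__ = [
    "bray_curtis", "euclidean_distance", "pca", "pcoa", "permanova", "fso",
    "OrdinationResult", "PermanovaResult", "FsoResult",
]


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: d(i,j) = sum|x_i - x_j| / sum(x_i + x_j)."""
    X = table.values
    if (X < 0).any():
        raise ValidationError(
            "Bray-Curtis needs non-negative data; use raw or relative abundances")
    if (X.sum(axis=1) <= 0).any():
        raise ValidationError("Bray-Curtis needs positive sample totals")
    return DistanceMatrix(squareform(pdist(X, metric="braycurtis")),
                          ids=table.sample_ids)


def euclidean_distance(table: FeatureTable) -> DistanceMatrix:
    return DistanceMatrix(squareform(pdist(table.values, metric="euclidean")),
                          ids=table.sample_ids)


@dataclass
class OrdinationResult:
    method: str
    scores: pd.DataFrame                 # samples x axes
    explained: np.ndarray                # fraction per axis
    eigenvalues: np.ndarray              # all eigenvalues (negatives included for PCoA)
    loadings: pd.DataFrame | None = None  # features x axes (PCA only)
    extras: dict = field(default_factory=dict)


def _fix_signs(scores: np.ndarray, loadings: np.ndarray | None) -> None:
    """Deterministic orientation: the largest-|entry| of each axis is positive.

    Uses loadings when available, else the scores. In-place.
    """
    ref = loadings if loadings is not None else scores
    for j in range(scores.shape[1]):
        col = ref[:, j]
        if col[np.abs(col).argmax()] < 0:
            scores[:, j] *= -1
            if loadings is not None:
                loadings[:, j] *= -1


def pca(table: FeatureTable, center: bool = True, unit_scale: bool = False,
        n_axes: int | None = None) -> OrdinationResult:
    """Principal component analysis via SVD of the processed matrix.

    Community count tables are typically centered only; metabolite tables
    should be Pareto-scaled upstream instead of setting ``unit_scale``.
    """
    X = table.values.astype(float)
    n, p = X.shape
    if n < 2:
        raise ValidationError("PCA needs at least 2 samples")
    max_axes = min(n - 1, p)
    if n_axes is None:
        n_axes = max_axes
    if not 1 <= n_axes <= max_axes:
        raise ParameterError(f"n_axes must be in [1, {max_axes}]")
    if center:
        X = X - X.mean(axis=0)
    if unit_scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValidationError("unit_scale with constant features")
        X = X / sd
    if not np.any(X):
        raise ValidationError("matrix is constant after centering")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eig = s ** 2 / (n - 1)
    total = eig.sum()
    scores = U[:, :n_axes] * s[:n_axes]
    loadings = Vt[:n_axes].T.copy()
    _fix_signs(scores, loadings)
    axes = [f"PC{i+1}" for i in range(n_axes)]
    return OrdinationResult(
        method="pca",
        scores=pd.DataFrame(scores, index=table.data.index, columns=axes),
        loadings=pd.DataFrame(loadings, index=table.data.columns, columns=axes),
        explained=eig[:n_axes] / total,
        eigenvalues=eig,
    )


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Metric multidimensional scaling (principal coordinates analysis).

    Gower double-centering of -d^2/2, then eigendecomposition. Axes with
    negative eigenvalues (metric violations of d) are reported in
    ``eigenvalues`` and ``extras['negative_eigenvalues']`` but excluded from
    the scores and from the explained-fraction denominator (positive-only).
    """
    n = len(d.ids)
    if n < 3:
        raise ValidationError("PCoA needs at least 3 samples")
    A = -0.5 * d.data ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12
    pos = eigval > tol
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValidationError("no positive eigenvalues; distances are degenerate")
    if n_axes is None:
        n_axes = n_pos
    n_axes = min(n_axes, n_pos)
    scores = eigvec[:, :n_axes] * np.sqrt(eigval[:n_axes])
    _fix_signs(scores, None)
    axes = [f"PCo{i+1}" for i in range(n_axes)]
    return OrdinationResult(
        method="pcoa",
        scores=pd.DataFrame(scores, index=list(d.ids), columns=axes),
        explained=eigval[:n_axes] / eigval[pos].sum(),
        eigenvalues=eigval,
        extras={"negative_eigenvalues": eigval[eigval < -tol]},
    )


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    df_between: int
    df_within: int
    n_perm: int
    seed: int
    dropped: list[str] = field(default_factory=list)


def _permanova_f(D2: np.ndarray, codes: np.ndarray, n_groups: int):
    """(pseudo-F, R2) from squared distances and integer group codes."""
    N = D2.shape[0]
    iu = np.triu_indices(N, 1)
    ss_total = D2[iu].sum() / N
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_b, df_w = n_groups - 1, N - n_groups
    F = (ss_between / df_b) / (ss_within / df_w)
    return F, ss_between / ss_total


def permanova(d: DistanceMatrix, groups: pd.Series, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Single-factor permutational multivariate ANOVA on a distance matrix.

    Partitions sums of squared dissimilarities between and within groups and
    assesses pseudo-F = (SS_b/(a-1))/(SS_w/(N-a)) by random relabeling.
    Samples whose group label is missing are dropped and reported. The
    permutation p includes the observed statistic (+1/+1), so p is never 0.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    groups = groups.reindex(list(d.ids))
    keep = groups.notna().to_numpy()
    dropped = [i for i, k in zip(d.ids, keep) if not k]
    ids = [i for i, k in zip(d.ids, keep) if k]
    if len(ids) < 3:
        raise ValidationError("too few labelled samples for PERMANOVA")
    D2 = d.filter(ids).data ** 2
    labels = groups.loc[ids]
    codes, uniques = pd.factorize(labels)
    a, N = len(uniques), len(ids)
    if a < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    if N - a == 0:
        raise ValidationError("no within-group degrees of freedom")
    iu = np.triu_indices(N, 1)
    if D2[iu].sum() == 0:
        raise ValidationError("degenerate distance matrix: all distances are 0")
    F_obs, r2 = _permanova_f(D2, codes, a)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        F_perm, _ = _permanova_f(D2, perm, a)
        if F_perm >= F_obs:
            hits += 1
    return PermanovaResult(
        pseudo_F=float(F_obs), R2=float(r2),
        p=(hits + 1) / (n_perm + 1),
        df_between=a - 1, df_within=N - a,
        n_perm=n_perm, seed=seed, dropped=dropped,
    )


@dataclass
class FsoResult:
    mu: pd.Series        # fuzzy memberships scaled to [0, 1]
    apparent: pd.Series  # similarity-weighted apparent memberships
    r: float
    p: float
    n_perm: int
    seed: int


def fso(d: DistanceMatrix, x: pd.Series, n_perm: int = 999,
        seed: int = 0) -> FsoResult:
    """Fuzzy set ordination of one continuous covariate against a distance matrix.

    Memberships mu_i rescale x to [0, 1]; the apparent membership of sample i
    is the similarity-weighted mean of the other samples' memberships, with
    similarity s = 1 - d/max(d). The correlation r between mu and the
    apparent values measures how strongly the covariate gradient is expressed
    in community structure; its one-sided significance comes from permuting x.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    x = pd.to_numeric(x.reindex(list(d.ids)))
    if x.isna().any():
        raise ValidationError(f"missing covariate for: {list(x.index[x.isna()])}")
    n = len(d.ids)
    if n < 4:
        raise ValidationError("FSO needs at least 4 samples")
    dmax = d.data.max()
    if dmax == 0:
        raise ValidationError("degenerate distance matrix: all distances are 0")
    xv = x.to_numpy(float)
    if xv.max() == xv.min():
        raise ValidationError("constant covariate")
    S = 1.0 - d.data / dmax
    np.fill_diagonal(S, 0.0)
    wsum = S.sum(axis=1)
    if (wsum == 0).any():
        raise ValidationError("a sample has zero similarity to all others")

    def _r(mu: np.ndarray) -> tuple[float, np.ndarray]:
        apparent = S @ mu / wsum
        return float(np.corrcoef(mu, apparent)[0, 1]), apparent

    mu = (xv - xv.min()) / (xv.max() - xv.min())
    r_obs, apparent = _r(mu)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        r_perm, _ = _r(rng.permutation(mu))
        if r_perm >= r_obs:
            hits += 1
    return FsoResult(
        mu=pd.Series(mu, index=list(d.ids), name="mu"),
        apparent=pd.Series(apparent, index=list(d.ids), name="apparent"),
        r=r_obs, p=(hits + 1) / (n_perm + 1), n_perm=n_perm, seed=seed,
    )
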