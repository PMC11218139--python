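"""Phylogenetic alpha diversity: MPD/MNTD and their standardized effect sizes.

MPD (mean pairwise distance) and MNTD (mean nearest-taxon distance) measure
how phylogenetically close the taxa present in a sample are. Their
standardized effect sizes against a taxon-label-shuffle null give the Net
Relatedness Index (NRI = -SES of MPD) and Nearest Taxon Index
(NTI = -SES of MNTD); positive values indicate phylogenetic clustering,
negative values overdispersion.

The null model permutes tip labels on the cophenetic distance matrix, which
for a fixed community size k draws uniformly among all k-subsets of the
taxon pool ("taxa.labels" style).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .errors import ParameterError, ValidationError
from .io import FeatureTable

__all__ = ["cophenetic_matrix", "community_phylo_stat", "ses_phylo", "SesResult"]


def cophenetic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length (cophenetic) distances of a rooted tree."""
    for tip in tree.tips():
        if tip.name is None:
            raise ValidationError("tree has unlabelled tips")
    return tree.tip_tip_distances()


def _stat_from_submatrix(sub: np.ndarray, statistic: str) -> float:
    k = sub.shape[0]
    if statistic == "mpd":
        iu = np.triu_indices(k, 1)
        return float(sub[iu].mean())
    # mntd: mean over taxa of the distance to the nearest other present taxon
    masked = sub + np.diag(np.full(k, np.inf))
    return float(masked.min(axis=1).mean())


def community_phylo_stat(present: set[str] | list[str], d: DistanceMatrix,
                         statistic: str = "mpd") -> float:
    """Observed MPD or MNTD of one community; NaN when < 2 taxa are present."""
    if statistic not in ("mpd", "mntd"):
        raise ParameterError(f"unknown statistic {statistic!r}")
    ids = set(d.ids)
    present = sorted(set(present))
    missing = [p for p in present if p not in ids]
    if missing:
        raise ValidationError(f"taxa absent from the distance matrix: {missing}")
    if len(present) < 2:
        return float("nan")
    idx = np.array([d.index(p) for p in present])
    return _stat_from_submatrix(d.data[np.ix_(idx, idx)], statistic)


@dataclass
class SesResult:
    """Per-sample SES of MPD/MNTD with the null-distribution summary.

    ``index_value`` is NRI (for mpd) or NTI (for mntd), i.e. -SES.
    ``rank_p`` = (count(null <= observed) + 1) / (n_null + 1): small values
    mean the community is more clustered than almost every null draw.
    SES and the index are NaN where the null sd is 0 (see ``flags``).
    """

    statistic: str
    table: pd.DataFrame  # observed, null_mean, null_sd, ses, index_value, rank_p
    n_null: int
    seed: int
    null_model: str = "taxa_label_shuffle"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


def ses_phylo(table: FeatureTable, d: DistanceMatrix, statistic: str = "mpd",
              n_null: int = 999, seed: int = 0) -> SesResult:
    """Standardized effect size of MPD/MNTD under a taxon-label-shuffle null.

    Presence/absence is taken as value > 0 (unweighted statistics). The same
    label permutation is applied to all samples within one null replicate.
    Deterministic for a fixed seed.
    """
    if statistic not in ("mpd", "mntd"):
        raise ParameterError(f"unknown statistic {statistic!r}")
    if n_null < 1:
        raise ParameterError("n_null must be >= 1")
    pool = list(d.ids)
    missing = [f for f in table.feature_ids if f not in set(pool)]
    if missing:
        raise ValidationError(f"features absent from the distance matrix: {missing}")
    D = d.data
    col_idx = np.array([d.index(f) for f in table.feature_ids])
    presence = table.values > 0
    sample_indices = [col_idx[presence[i]] for i in range(table.n_samples)]

    observed = np.array([
        _stat_from_submatrix(D[np.ix_(ix, ix)], statistic) if len(ix) >= 2 else np.nan
        for ix in sample_indices
    ])

    rng = np.random.default_rng(seed)
    n = len(pool)
    null = np.empty((n_null, table.n_samples))
    for r in range(n_null):
        perm = rng.permutation(n)
        for s, ix in enumerate(sample_indices):
            if len(ix) < 2:
                null[r, s] = np.nan
                continue
            pix = perm[ix]
            null[r, s] = _stat_from_submatrix(D[np.ix_(pix, pix)], statistic)

    null_mean = np.nanmean(null, axis=0)
    null_sd = np.array([np.nan if np.isnan(observed[s]) else null[:, s].std(ddof=1)
                        for s in range(table.n_samples)])
    with np.errstate(invalid="ignore", divide="ignore"):
        ses = np.where(null_sd > 0, (observed - null_mean) / null_sd, np.nan)
    rank_p = np.array([
        np.nan if np.isnan(observed[s])
        else (np.sum(null[:, s] <= observed[s]) + 1) / (n_null + 1)
        for s in range(table.n_samples)
    ])
    flags = [
        "too_few_taxa" if np.isnan(observed[s])
        else ("constant_null" if not null_sd[s] > 0 else "")
        for s in range(table.n_samples)
    ]
    out = pd.DataFrame({
        "observed": observed,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "ses": ses,
        "index_value": -ses,
        "rank_p": rank_p,
        "flag": flags,
    }, index=table.data.index)
    return SesResult(statistic=statistic, table=out, n_null=n_null, seed=seed)
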