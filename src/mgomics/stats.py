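"""Nonparametric group comparison, post hoc testing and correlation.

The differential-abundance workflow is: per-feature omnibus test
(Kruskal-Wallis for independent groups, Friedman for repeated measures),
Benjamini-Hochberg correction across features, and Dunn's pairwise post hoc
(BH across pairs within a feature) for the features that pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError
from .io import FeatureTable

__all__ = [
    "kruskal_wallis", "friedman", "dunn_posthoc", "adjust_pvalues",
    "differential_table", "correlate",
    "KruskalResult", "FriedmanResult", "GroupTestResult", "CorrelationResult",
]


@dataclass
class KruskalResult:
    H: float
    df: int
    p: float


def kruskal_wallis(values, groups) -> KruskalResult:
    """Kruskal-Wallis rank test with mid-rank tie correction.

    All-identical values are not an error: H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValidationError("values and groups must have equal length")
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 groups")
    if len(values) < 3:
        raise ValidationError("Kruskal-Wallis needs at least 3 observations")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValidationError("empty group")
    df = len(levels) - 1
    if np.all(values == values[0]):
        return KruskalResult(H=0.0, df=df, p=1.0)
    stat, p = sps.kruskal(*samples)
    return KruskalResult(H=float(stat), df=df, p=float(p))


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p: float
    n_blocks: int
    dropped_blocks: list = field(default_factory=list)


def friedman(block_matrix) -> FriedmanResult:
    """Friedman rank test for k >= 2 related treatments over n blocks.

    Within-block mid-ranks with tie correction (Conover's form, which reduces
    to chi2 = 12/(nk(k+1)) * sum R_j^2 - 3n(k+1) without ties). Blocks with
    missing entries are dropped and reported.
    """
    df = pd.DataFrame(block_matrix)
    k = df.shape[1]
    if k < 2:
        raise ValidationError("Friedman needs at least 2 treatments")
    complete = df.dropna()
    dropped = [i for i in df.index if i not in complete.index]
    n = complete.shape[0]
    if n < 2:
        raise ValidationError("Friedman needs at least 2 complete blocks")
    ranks = np.apply_along_axis(sps.rankdata, 1, complete.to_numpy(float))
    col_sums = ranks.sum(axis=0)
    # tie-corrected statistic: (k-1) * S / (sum r^2 - n k (k+1)^2 / 4)
    s = float(((col_sums - n * (k + 1) / 2) ** 2).sum())
    denom = float((ranks ** 2).sum()) - n * k * (k + 1) ** 2 / 4
    if denom == 0:  # every block fully tied
        chi2 = 0.0
    else:
        chi2 = (k - 1) * s / denom
    p = float(sps.chi2.sf(chi2, k - 1)) if chi2 > 0 else 1.0
    return FriedmanResult(chi2=chi2, df=k - 1, p=p, n_blocks=n,
                          dropped_blocks=dropped)


def dunn_posthoc(values, groups, adjust: str = "bh") -> pd.DataFrame:
    """Dunn's pairwise z-tests on the joint mid-ranks, with tie correction.

    z_ab = (Rbar_a - Rbar_b) / sqrt([N(N+1)/12 - T/(12(N-1))] (1/n_a + 1/n_b))
    with T = sum(t^3 - t) over tie groups. Two-sided normal p-values,
    adjusted across all unordered pairs by the chosen method.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValidationError("Dunn post hoc needs at least 2 groups")
    sizes = {g: int((groups == g).sum()) for g in levels}
    if any(n == 0 for n in sizes.values()):
        raise ValidationError("empty group")
    N = len(values)
    ranks = sps.rankdata(values)
    mean_rank = {g: ranks[groups == g].mean() for g in levels}
    _, counts = np.unique(values, return_counts=True)
    tie_term = float((counts ** 3 - counts).sum())
    var_core = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            se = np.sqrt(var_core * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
            p = float(2 * sps.norm.sf(abs(z)))
            rows.append({"group_a": a, "group_b": b, "z": float(z), "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["padj"] = adjust_pvalues(out["p"].tolist(), method=adjust)
    return out


def adjust_pvalues(p, method: str = "bh") -> list[float]:
    """Multiple-testing correction: Benjamini-Hochberg, Bonferroni, or none."""
    p = list(p)
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ParameterError("p-values must lie in [0, 1]")
    if method == "none":
        return [float(v) for v in arr]
    if method not in ("bh", "bonferroni"):
        raise ParameterError(f"unknown adjustment method {method!r}")
    sm_method = "fdr_bh" if method == "bh" else "bonferroni"
    return [float(v) for v in multipletests(arr, method=sm_method)[1]]


@dataclass
class GroupTestResult:
    feature_id: str
    statistic: float
    df: int
    p: float
    padj: float
    group_means: dict
    pairwise: pd.DataFrame | None = None
    flag: str = ""


def differential_table(table: FeatureTable, groups: pd.Series,
                       design: str = "independent",
                       blocks: pd.Series | None = None,
                       alpha: float = 0.05,
                       adjust: str = "bh") -> list[GroupTestResult]:
    """Per-feature omnibus test with BH correction and Dunn post hoc.

    ``design='independent'`` runs Kruskal-Wallis on ``groups``;
    ``design='repeated'`` runs Friedman with ``blocks`` identifying the
    subject of each sample (treatments = groups). Dunn's post hoc is computed
    for independent-design features with padj <= alpha. Group means are
    reported on the table's transform scale. Degenerate features (constant
    across samples) are flagged rather than aborting the run.
    """
    if design not in ("independent", "repeated"):
        raise ParameterError(f"unknown design {design!r}")
    groups = groups.reindex(table.data.index)
    keep = groups.notna()
    if design == "repeated":
        if blocks is None:
            raise ParameterError("repeated design needs a blocks series")
        blocks = blocks.reindex(table.data.index)
        keep &= blocks.notna()
    data = table.data.loc[keep]
    g = groups.loc[keep]
    results: list[GroupTestResult] = []
    for fid in table.feature_ids:
        vals = data[fid]
        means = {str(lv): float(vals[g == lv].mean()) for lv in pd.unique(g)}
        if vals.nunique() <= 1:
            results.append(GroupTestResult(
                feature_id=fid, statistic=np.nan, df=0, p=np.nan, padj=np.nan,
                group_means=means, flag="constant"))
            continue
        try:
            if design == "independent":
                r = kruskal_wallis(vals.to_numpy(), g.to_numpy())
                stat, df, p = r.H, r.df, r.p
            else:
                wide = pd.DataFrame({
                    "block": blocks.loc[keep], "treat": g, "v": vals,
                }).pivot_table(index="block", columns="treat", values="v")
                r = friedman(wide)
                stat, df, p = r.chi2, r.df, r.p
        except ValidationError as exc:
            results.append(GroupTestResult(
                feature_id=fid, statistic=np.nan, df=0, p=np.nan, padj=np.nan,
                group_means=means, flag=str(exc)))
            continue
        results.append(GroupTestResult(
            feature_id=fid, statistic=float(stat), df=df, p=float(p),
            padj=np.nan, group_means=means))
    tested = [r for r in results if not r.flag]
    if tested:
        padj = adjust_pvalues([r.p for r in tested], method=adjust)
        for r, q in zip(tested, padj):
            r.padj = q
    if design == "independent":
        for r in tested:
            if r.padj <= alpha:
                r.pairwise = dunn_posthoc(data[r.feature_id].to_numpy(),
                                          g.to_numpy(), adjust=adjust)
    return results


@dataclass
class CorrelationResult:
    method: str
    r: float
    p: float
    n: int


def correlate(x, y, method: str = "spearman") -> CorrelationResult:
    """Pairwise-complete correlation: Pearson, Spearman, or Kendall tau-b.

    Pearson/Spearman p-values use the t approximation; Kendall the normal
    approximation (tau-b with tie correction).
    """
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    if len(x) != len(y):
        raise ValidationError("x and y must be paired")
    keep = x.notna() & y.notna()
    xv, yv = x[keep].to_numpy(), y[keep].to_numpy()
    n = len(xv)
    if n < 3:
        raise ValidationError("need at least 3 complete pairs")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValidationError("zero variance in x or y")
    if method == "pearson":
        r, p = sps.pearsonr(xv, yv)
    elif method == "spearman":
        r, p = sps.spearmanr(xv, yv)
    elif method == "kendall":
        r, p = sps.kendalltau(xv, yv, variant="b", method="asymptotic")
    else:
        raise ParameterError(f"unknown method {method!r}")
    return CorrelationResult(method=method, r=float(r), p=float(min(p, 1.0)), n=n)
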