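"""Seeded generators for every input kind, with planted, known structure.

These generators define the study conditions the rest of the toolkit is
validated against: overdispersed case-control count tables with planted
differentially abundant taxa, paired omics blocks with planted joint and
distinctive low-rank structure, and pure-birth phylogenies. Every generator
is bit-reproducible for a fixed seed, and its outputs pass the I/O
validation contracts unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import ParameterError
from .io import FeatureTable, SampleMetadata

__all__ = [
    "SimTruth", "simulate_community", "simulate_paired_blocks",
    "simulate_tree", "noise_sd_for_snr",
]


@dataclass
class SimTruth:
    """Ground truth of one simulation; fully determines the data given seed."""

    seed: int
    groups: pd.Series | None = None
    affected_features: list[str] = field(default_factory=list)
    effects: dict[str, float] = field(default_factory=dict)
    joint_scores: np.ndarray | None = None
    joint_loadings: dict[str, np.ndarray] = field(default_factory=dict)
    distinct_loadings: dict[str, np.ndarray] = field(default_factory=dict)
    newick: str | None = None


def simulate_community(n_samples: int = 60, n_taxa: int = 200,
                       n_groups: int = 2, n_affected: int = 5,
                       effect: float = 2.0, dispersion: float = 0.5,
                       depth: int = 20000, seed: int = 0):
    """Overdispersed case-control count table with planted group effects.

    Counts follow a gamma-mixed Poisson (negative-binomial-like) model:
    baseline taxon proportions are lognormal, affected taxa receive a
    log-scale offset of +/- ``effect`` in every non-reference group
    (alternating sign across the affected taxa), and per-cell gamma noise
    with the given ``dispersion`` overdisperses the Poisson draws. Group
    labels are balanced G1..Gk.

    Defaults emulate a two-group shotgun-metagenomics comparison of 60
    samples over 200 genome clusters with 5 truly differential taxa at a
    log-effect of 2 (~7.4-fold).

    Returns
    -------
    (FeatureTable, SampleMetadata, SimTruth)
    """
    if n_affected > n_taxa:
        raise ParameterError("n_affected cannot exceed n_taxa")
    if n_samples < n_groups or n_groups < 1:
        raise ParameterError("need at least one sample per group")
    if effect < 0 or dispersion <= 0:
        raise ParameterError("effect must be >= 0 and dispersion > 0")
    rng = np.random.default_rng(seed)
    taxa = [f"C{i+1}" for i in range(n_taxa)]
    samples = [f"S{i+1:03d}" for i in range(n_samples)]
    group_labels = np.array([f"G{(i % n_groups) + 1}" for i in range(n_samples)])
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_taxa)
    base /= base.sum()
    affected = list(rng.choice(n_taxa, size=n_affected, replace=False)) \
        if n_affected else []
    log_offset = np.zeros((n_groups, n_taxa))
    effects: dict[str, float] = {}
    for j, tx in enumerate(affected):
        signed = effect if j % 2 == 0 else -effect
        log_offset[1:, tx] = signed
        effects[taxa[tx]] = signed if effect > 0 else 0.0
    if effect == 0:
        affected, effects = [], {}
    gidx = np.array([int(g[1:]) - 1 for g in group_labels])
    mu = depth * base[None, :] * np.exp(log_offset[gidx])
    mu *= (base.sum() / (base[None, :] * np.exp(log_offset[gidx])).sum(
        axis=1, keepdims=True))  # keep library sizes comparable across groups
    shape = 1.0 / dispersion
    lam = mu * rng.gamma(shape, scale=1.0 / shape, size=mu.shape)
    counts = rng.poisson(lam)
    table = FeatureTable(pd.DataFrame(counts.astype(float), index=samples,
                                      columns=taxa),
                         feature_kind="taxon_cluster", transform_tag="raw")
    meta = SampleMetadata(
        pd.DataFrame({"group": group_labels}, index=samples),
        {"group": "categorical"})
    truth = SimTruth(seed=seed,
                     groups=pd.Series(group_labels, index=samples, name="group"),
                     affected_features=[taxa[t] for t in affected],
                     effects=effects)
    return table, meta, truth


def noise_sd_for_snr(snr: float, n_samples: int, n_features: int,
                     signal_energy: float = 1.0) -> float:
    """Entrywise noise sd giving E||E||_F^2 = signal_energy / snr."""
    if snr <= 0:
        raise ParameterError("snr must be positive")
    return float(np.sqrt(signal_energy / (snr * n_samples * n_features)))


def simulate_paired_blocks(n_samples: int = 40, p1: int = 30, p2: int = 25,
                           joint_rank: int = 1,
                           distinct_ranks: tuple[int, int] = (1, 1),
                           noise_sd: float = 0.005, seed: int = 0,
                           joint_strength: float = 1.0,
                           distinct_strength: float = 0.6):
    """Two paired blocks X_b = T P_b' + D_b Q_b' + E_b with shared scores T.

    Joint components are shared score vectors with block-specific loadings;
    distinctive components live in one block only, with score directions
    orthogonal to the joint ones. Scores and loadings are unit-norm, so each
    joint component contributes ``joint_strength``^2 Frobenius energy per
    block and each distinctive component ``distinct_strength``^2. Gaussian
    noise has entrywise sd ``noise_sd`` (see :func:`noise_sd_for_snr`).

    Returns
    -------
    (FeatureTable, FeatureTable, SimTruth)
    """
    r_tot = joint_rank + max(distinct_ranks)
    if r_tot > n_samples or joint_rank + distinct_ranks[0] > p1 \
            or joint_rank + distinct_ranks[1] > p2:
        raise ParameterError("ranks exceed the block dimensions")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    samples = [f"S{i+1:03d}" for i in range(n_samples)]
    n_dirs = joint_rank + sum(distinct_ranks)
    raw = rng.standard_normal((n_samples, max(n_dirs, 1)))
    raw -= raw.mean(axis=0)  # zero-mean scores survive column-centering
    basis, _ = np.linalg.qr(raw)
    T = basis[:, :joint_rank]
    D1 = basis[:, joint_rank:joint_rank + distinct_ranks[0]]
    D2 = basis[:, joint_rank + distinct_ranks[0]:n_dirs]

    def _unit_loadings(p, r):
        L = rng.standard_normal((p, r))
        if r:
            L /= np.linalg.norm(L, axis=0)
        return L

    P1 = _unit_loadings(p1, joint_rank)
    P2 = _unit_loadings(p2, joint_rank)
    Q1 = _unit_loadings(p1, distinct_ranks[0])
    Q2 = _unit_loadings(p2, distinct_ranks[1])
    X1 = joint_strength * T @ P1.T + distinct_strength * D1 @ Q1.T \
        + noise_sd * rng.standard_normal((n_samples, p1))
    X2 = joint_strength * T @ P2.T + distinct_strength * D2 @ Q2.T \
        + noise_sd * rng.standard_normal((n_samples, p2))
    t1 = FeatureTable(pd.DataFrame(X1, index=samples,
                                   columns=[f"F1_{j+1}" for j in range(p1)]),
                      feature_kind="taxon_cluster", transform_tag="centered")
    t2 = FeatureTable(pd.DataFrame(X2, index=samples,
                                   columns=[f"F2_{j+1}" for j in range(p2)]),
                      feature_kind="metabolite", transform_tag="centered")
    truth = SimTruth(seed=seed, joint_scores=T,
                     joint_loadings={"block1": P1, "block2": P2},
                     distinct_loadings={"block1": Q1, "block2": Q2})
    return t1, t2, truth


def simulate_tree(n_tips: int, model: str = "yule", seed: int = 0) -> TreeNode:
    """Pure-birth (Yule) topology with independent Exp(1) branch lengths.

    Tips are labelled T1..Tn. The same seed always yields the same newick
    string.
    """
    if model != "yule":
        raise ParameterError(f"unknown tree model {model!r}")
    if n_tips < 2:
        raise ParameterError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    # nodes are [name, children]; start from the root cherry and split
    # uniformly chosen tips until n_tips is reached
    next_label = 3
    root = ["", [["T1", []], ["T2", []]]]
    tips = root[1][:]
    while len(tips) < n_tips:
        k = int(rng.integers(len(tips)))
        node = tips[k]
        left = [node[0], []]
        right = [f"T{next_label}", []]
        next_label += 1
        node[0] = ""
        node[1] = [left, right]
        tips[k] = left
        tips.append(right)

    def _newick(node) -> str:
        length = rng.exponential(1.0)
        if not node[1]:
            return f"{node[0]}:{length:.6f}"
        inner = ",".join(_newick(c) for c in node[1])
        return f"({inner}):{length:.6f}"

    inner = ",".join(_newick(c) for c in root[1])
    return TreeNode.read([f"({inner});"])
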