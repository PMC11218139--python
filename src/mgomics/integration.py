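"""Two-block multi-omics joint decomposition: DISCO-SCA, JIVE and O2PLS.

All three methods split each (centered, Frobenius-normalised) omics block
into structure shared across blocks ("joint"/"common"), structure confined
to one block ("distinctive"/"individual"/"orthogonal"), and residual noise:

* DISCO-SCA fits one simultaneous component analysis of the concatenated
  blocks and then rotates the components so that distinctive components have
  (near-)zero loadings outside their block; common components remain
  unconstrained.
* JIVE alternates low-rank fits of a joint matrix across blocks and
  individual matrices per block, with sample-space orthogonality between the
  joint and each individual part.
* O2PLS extracts joint components from the singular triplets of the
  cross-block covariance Y'X after filtering per-block structured
  ("orthogonal") variation uncorrelated with the other block.

Blocks must be prepared with :func:`mgomics.preprocess.block_scale` (see
:func:`make_block`) so that each contributes equal total sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .io import FeatureTable
from .preprocess import BlockScaling, block_scale

__all__ = [
    "OmicsBlock", "make_block", "JointModel",
    "disco_sca", "jive", "o2pls", "ranked_loadings", "sca_scree",
]


@dataclass
class OmicsBlock:
    """A labelled, centered, unit-Frobenius-norm omics data block."""

    label: str
    table: FeatureTable
    scaling: BlockScaling | None = None

    def __post_init__(self) -> None:
        X = self.table.values
        col_means = X.mean(axis=0)
        if np.abs(col_means).max() > 1e-8:
            raise ValidationError(
                f"block {self.label!r} is not column-centered; use make_block")
        if abs(np.linalg.norm(X) - 1.0) > 1e-8:
            raise ValidationError(
                f"block {self.label!r} does not have unit Frobenius norm")

    @property
    def values(self) -> np.ndarray:
        return self.table.values

    @property
    def sample_ids(self) -> list[str]:
        return self.table.sample_ids

    @property
    def feature_ids(self) -> list[str]:
        return self.table.feature_ids


def make_block(label: str, table: FeatureTable) -> OmicsBlock:
    """Center and Frobenius-normalise a table into an :class:`OmicsBlock`."""
    scaled, scaling = block_scale(table)
    return OmicsBlock(label=label, table=scaled, scaling=scaling)


@dataclass
class JointModel:
    """Common scores plus per-block joint/distinctive structure.

    ``common_scores`` columns are orthonormal. ``variance_explained`` has one
    row per block with columns joint / distinctive / residual (fractions of
    the block's total sum of squares).
    """

    method: str
    common_scores: pd.DataFrame
    joint_loadings: dict[str, pd.DataFrame]
    distinct_scores: dict[str, pd.DataFrame]
    distinct_loadings: dict[str, pd.DataFrame]
    variance_explained: pd.DataFrame
    converged: bool = True
    n_iter: int = 0
    criterion: float = 0.0
    extras: dict = field(default_factory=dict)

    @property
    def block_labels(self) -> list[str]:
        return list(self.joint_loadings)


def _check_blocks(blocks: list[OmicsBlock]) -> None:
    ref = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ref:
            raise ValidationError(
                f"blocks {blocks[0].label!r} and {b.label!r} do not share "
                "the same samples in the same order")


def _svd_trunc(X: np.ndarray, rank: int):
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    return U[:, :rank], s[:rank], Vt[:rank]


def _fix_component_signs(scores: np.ndarray, loadings: np.ndarray) -> None:
    """Orient each component so its largest-|loading| entry is positive."""
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col.size and col[np.abs(col).argmax()] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1


def sca_scree(blocks: list[OmicsBlock], n_values: int = 10) -> np.ndarray:
    """Singular values of the concatenated blocks, to guide rank choices."""
    _check_blocks(blocks)
    X = np.hstack([b.values for b in blocks])
    s = np.linalg.svd(X, compute_uv=False)
    return s[:n_values]


# ---------------------------------------------------------------------------
# DISCO-SCA
# ---------------------------------------------------------------------------

def _distinctive_mask(p_sizes: list[int], n_common: int,
                      n_distinct: tuple[int, ...]) -> np.ndarray:
    """1 where a loading is constrained to zero (distinctive component of one
    block must vanish in the other blocks), 0 where it is free."""
    p_total = sum(p_sizes)
    R = n_common + sum(n_distinct)
    W = np.zeros((p_total, R))
    offsets = np.concatenate([[0], np.cumsum(p_sizes)])
    col = n_common
    for b, r_b in enumerate(n_distinct):
        for _ in range(r_b):
            W[:, col] = 1.0
            W[offsets[b]:offsets[b + 1], col] = 0.0
            col += 1
    return W


def _rotate_to_structure(P: np.ndarray, W: np.ndarray, tol: float,
                         max_sweeps: int, seed: int, n_starts: int):
    """Find orthogonal V minimising ||W o (P V)||_F^2 by pairwise Jacobi
    rotations, from the identity plus ``n_starts`` seeded random starts.

    For a planar rotation of columns (a, b) by angle theta the masked energy
    is const + a1 cos(2 theta) + a2 sin(2 theta), so each pair has a closed-
    form optimum; sweeps repeat until the objective stops improving.
    """
    R = P.shape[1]
    rng = np.random.default_rng(seed)
    starts = [np.eye(R)]
    for _ in range(n_starts):
        Q, _ = np.linalg.qr(rng.standard_normal((R, R)))
        starts.append(Q)
    best_V, best_f = None, np.inf
    # absolute threshold: gains are compared to the total loading energy so
    # convergence is not declared early merely because f is already small
    thresh = tol * max(float((P ** 2).sum()), 1e-300)
    for V0 in starts:
        V = V0.copy()
        L = P @ V
        f = float((W * L ** 2).sum())
        for _ in range(max_sweeps):
            improved = 0.0
            for a in range(R - 1):
                for b in range(a + 1, R):
                    wa, wb = W[:, a], W[:, b]
                    la, lb = L[:, a], L[:, b]
                    dw = wa - wb
                    a1 = 0.5 * float(np.dot(dw, la ** 2 - lb ** 2))
                    a2 = float(np.dot(dw, la * lb))
                    amp = np.hypot(a1, a2)
                    gain = a1 + amp  # f(0) - min_theta f(theta)
                    if gain <= thresh:
                        continue
                    theta = 0.5 * (np.arctan2(a2, a1) + np.pi)
                    c, s = np.cos(theta), np.sin(theta)
                    L[:, a], L[:, b] = la * c + lb * s, -la * s + lb * c
                    va, vb = V[:, a].copy(), V[:, b].copy()
                    V[:, a], V[:, b] = va * c + vb * s, -va * s + vb * c
                    f -= gain
                    improved += gain
            if improved <= thresh:
                break
        if f < best_f:
            best_f, best_V = f, V
    return best_V, best_f


def disco_sca(blocks: list[OmicsBlock], n_common: int,
              n_distinct: tuple[int, int] = (0, 0), tol: float = 1e-12,
              max_iter: int = 1000, seed: int = 0,
              n_starts: int = 10) -> JointModel:
    """DISCO-SCA: simultaneous component analysis with a DIStinctive/COmmon
    rotation of the loading matrix.

    A rank-R SCA (R = n_common + sum(n_distinct)) of the column-concatenated
    blocks is rotated by an orthogonal V chosen to minimise the squared
    loadings on positions constrained to zero: the distinctive components of
    a block must have ~zero loadings in the other block. The rotation stays
    inside the SCA subspace, so the overall fit is unchanged.
    """
    if len(blocks) != 2:
        raise ValidationError("disco_sca is defined for exactly 2 blocks")
    _check_blocks(blocks)
    if n_common < 0 or any(r < 0 for r in n_distinct):
        raise ParameterError("ranks must be non-negative")
    R = n_common + sum(n_distinct)
    if R < 1:
        raise ParameterError("total rank must be at least 1")
    X = np.hstack([b.values for b in blocks])
    if R > min(X.shape):
        raise ParameterError(f"total rank {R} exceeds min dimension {min(X.shape)}")
    p_sizes = [b.values.shape[1] for b in blocks]
    U, s, Vt = _svd_trunc(X, R)
    T = U                      # orthonormal scores
    P = (Vt.T * s)             # loadings carry the scale: X ~ T P'
    W = _distinctive_mask(p_sizes, n_common, n_distinct)
    if W.sum() > 0:
        V, crit = _rotate_to_structure(P, W, tol=tol, max_sweeps=max_iter,
                                       seed=seed, n_starts=n_starts)
        T, P = T @ V, P @ V
    else:
        crit = 0.0
    _fix_component_signs(T, P)
    return _assemble_sca_model("disco_sca", blocks, T, P, n_common, n_distinct,
                               criterion=crit,
                               extras={"singular_values": s,
                                       "rotation_objective": crit})


def _assemble_sca_model(method: str, blocks: list[OmicsBlock], T: np.ndarray,
                        P: np.ndarray, n_common: int,
                        n_distinct: tuple[int, ...], criterion: float,
                        extras: dict) -> JointModel:
    sample_index = blocks[0].table.data.index
    p_sizes = [b.values.shape[1] for b in blocks]
    offsets = np.concatenate([[0], np.cumsum(p_sizes)])
    common_cols = [f"C{i+1}" for i in range(n_common)]
    common_scores = pd.DataFrame(T[:, :n_common], index=sample_index,
                                 columns=common_cols)
    joint_loadings, dist_scores, dist_loadings = {}, {}, {}
    var_rows = []
    col = n_common
    dist_cols_per_block = []
    for b, r_b in enumerate(n_distinct):
        dist_cols_per_block.append(list(range(col, col + r_b)))
        col += r_b
    for b, blk in enumerate(blocks):
        Pb = P[offsets[b]:offsets[b + 1]]
        joint_loadings[blk.label] = pd.DataFrame(
            Pb[:, :n_common], index=blk.table.data.columns, columns=common_cols)
        cols = dist_cols_per_block[b]
        dnames = [f"D{i+1}" for i in range(len(cols))]
        dist_scores[blk.label] = pd.DataFrame(T[:, cols], index=sample_index,
                                              columns=dnames)
        dist_loadings[blk.label] = pd.DataFrame(
            Pb[:, cols], index=blk.table.data.columns, columns=dnames)
        ss_total = float((blk.values ** 2).sum())
        joint_ss = float((Pb[:, :n_common] ** 2).sum())
        dist_ss = float((Pb[:, cols] ** 2).sum())
        resid_ss = float(((blk.values - T @ Pb.T) ** 2).sum())
        var_rows.append({"block": blk.label,
                         "joint": joint_ss / ss_total,
                         "distinctive": dist_ss / ss_total,
                         "residual": resid_ss / ss_total})
    var = pd.DataFrame(var_rows).set_index("block")
    return JointModel(method=method, common_scores=common_scores,
                      joint_loadings=joint_loadings,
                      distinct_scores=dist_scores,
                      distinct_loadings=dist_loadings,
                      variance_explained=var, converged=True, n_iter=0,
                      criterion=criterion, extras=extras)


# ---------------------------------------------------------------------------
# JIVE
# ---------------------------------------------------------------------------

def jive(blocks: list[OmicsBlock], joint_rank: int,
         individual_ranks: list[int] | tuple[int, ...],
         tol: float = 1e-12, max_iter: int = 500) -> JointModel:
    """JIVE: Joint and Individual Variation Explained.

    Alternates a rank-``joint_rank`` fit J of the concatenation minus the
    individual structure with per-block rank-r_i fits A_i of the block minus
    its joint slice, each projected so its sample-space (score) subspace is
    orthogonal to J's. Returns converged=False if max_iter is hit.
    """
    if len(blocks) < 2:
        raise ValidationError("jive needs at least 2 blocks")
    _check_blocks(blocks)
    individual_ranks = list(individual_ranks)
    if len(individual_ranks) != len(blocks):
        raise ParameterError("one individual rank per block is required")
    if joint_rank < 0 or any(r < 0 for r in individual_ranks):
        raise ParameterError("ranks must be non-negative")
    Xs = [b.values for b in blocks]
    n = Xs[0].shape[0]
    for X, r in zip(Xs, individual_ranks):
        if joint_rank + r > min(X.shape):
            raise ParameterError("joint + individual rank exceeds a block dimension")
    X_cat = np.hstack(Xs)
    p_sizes = [X.shape[1] for X in Xs]
    offsets = np.concatenate([[0], np.cumsum(p_sizes)])
    A = [np.zeros_like(X) for X in Xs]
    J = np.zeros_like(X_cat)
    U_J = np.zeros((n, max(joint_rank, 1)))
    converged, it = False, 0
    for it in range(1, max_iter + 1):
        J_prev, A_prev = J, [a.copy() for a in A]
        Rmat = X_cat - np.hstack(A)
        if joint_rank > 0:
            U_J, s_J, Vt_J = _svd_trunc(Rmat, joint_rank)
            J = U_J @ (Vt_J * s_J[:, None])
        else:
            J = np.zeros_like(X_cat)
        for i, (X, r_i) in enumerate(zip(Xs, individual_ranks)):
            if r_i == 0:
                A[i] = np.zeros_like(X)
                continue
            B = X - J[:, offsets[i]:offsets[i + 1]]
            if joint_rank > 0:
                B = B - U_J @ (U_J.T @ B)   # sample-space orthogonality to J
            Ui, si, Vti = _svd_trunc(B, r_i)
            A[i] = Ui @ (Vti * si[:, None])
        change = np.linalg.norm(J - J_prev) ** 2 + sum(
            np.linalg.norm(a - ap) ** 2 for a, ap in zip(A, A_prev))
        if change < tol:
            converged = True
            break
    # final decompositions
    if joint_rank > 0:
        U_J, s_J, Vt_J = _svd_trunc(J, joint_rank)
        P_J = Vt_J.T * s_J
        _fix_component_signs(U_J, P_J)
    else:
        U_J = np.zeros((n, 0))
        P_J = np.zeros((X_cat.shape[1], 0))
    sample_index = blocks[0].table.data.index
    common_cols = [f"C{i+1}" for i in range(joint_rank)]
    common_scores = pd.DataFrame(U_J, index=sample_index, columns=common_cols)
    joint_loadings, dist_scores, dist_loadings = {}, {}, {}
    var_rows = []
    for i, blk in enumerate(blocks):
        Jb = J[:, offsets[i]:offsets[i + 1]]
        Pb = P_J[offsets[i]:offsets[i + 1]]
        joint_loadings[blk.label] = pd.DataFrame(
            Pb, index=blk.table.data.columns, columns=common_cols)
        r_i = individual_ranks[i]
        if r_i > 0:
            Ui, si, Vti = _svd_trunc(A[i], r_i)
            Pi = Vti.T * si
            _fix_component_signs(Ui, Pi)
        else:
            Ui = np.zeros((n, 0))
            Pi = np.zeros((p_sizes[i], 0))
        dnames = [f"D{k+1}" for k in range(r_i)]
        dist_scores[blk.label] = pd.DataFrame(Ui, index=sample_index,
                                              columns=dnames)
        dist_loadings[blk.label] = pd.DataFrame(
            Pi, index=blk.table.data.columns, columns=dnames)
        ss = float((Xs[i] ** 2).sum())
        var_rows.append({
            "block": blk.label,
            "joint": float((Jb ** 2).sum()) / ss,
            "distinctive": float((A[i] ** 2).sum()) / ss,
            "residual": float(((Xs[i] - Jb - A[i]) ** 2).sum()) / ss,
        })
    var = pd.DataFrame(var_rows).set_index("block")
    return JointModel(method="jive", common_scores=common_scores,
                      joint_loadings=joint_loadings,
                      distinct_scores=dist_scores,
                      distinct_loadings=dist_loadings,
                      variance_explained=var, converged=converged, n_iter=it,
                      criterion=float(change),
                      extras={"joint_singular_values":
                              np.linalg.svd(J, compute_uv=False)[:joint_rank]})


# ---------------------------------------------------------------------------
# O2PLS
# ---------------------------------------------------------------------------

def _extract_orthogonal(Xd: np.ndarray, W: np.ndarray, n_orth: int):
    """Strip structured variation of X uncorrelated with the joint scores.

    Each round takes the dominant direction of (Xd - T W')' T, scores it on
    Xd and deflates. Returns the deflated matrix plus orthogonal scores and
    loadings.
    """
    t_os, p_os = [], []
    for _ in range(n_orth):
        T = Xd @ W
        E = Xd - T @ W.T
        M = E.T @ T
        if np.linalg.norm(M) == 0:
            break
        w_o, _, _ = _svd_trunc(M, 1)
        w_o = w_o[:, 0]
        t_o = Xd @ w_o
        denom = float(t_o @ t_o)
        if denom == 0:
            break
        p_o = Xd.T @ t_o / denom
        Xd = Xd - np.outer(t_o, p_o)
        t_os.append(t_o)
        p_os.append(p_o)
    T_orth = np.column_stack(t_os) if t_os else np.zeros((Xd.shape[0], 0))
    P_orth = np.column_stack(p_os) if p_os else np.zeros((Xd.shape[1], 0))
    return Xd, T_orth, P_orth


def o2pls(x: OmicsBlock, y: OmicsBlock, n_joint: int, n_orth_x: int = 0,
          n_orth_y: int = 0) -> JointModel:
    """O2PLS: two-way orthogonal projections to latent structures.

    Joint weights come from the leading singular triplets of the cross-block
    covariance X'Y; per-block orthogonal components (structured variation
    unrelated to the other block) are estimated from the residuals and
    deflated before the final joint fit.
    """
    _check_blocks([x, y])
    X, Y = x.values, y.values
    if n_joint < 1:
        raise ParameterError("n_joint must be >= 1")
    M = X.T @ Y
    s_all = np.linalg.svd(M, compute_uv=False)
    rank = int((s_all > s_all[0] * 1e-12).sum()) if s_all.size else 0
    if n_joint > rank:
        raise ParameterError(
            f"n_joint={n_joint} exceeds the rank {rank} of the cross-covariance")
    W, _, Ct = _svd_trunc(M, n_joint)
    C = Ct.T
    Xd, Tox, Pox = _extract_orthogonal(X, W, n_orth_x)
    Yd, Toy, Poy = _extract_orthogonal(Y, C, n_orth_y)
    W, _, Ct = _svd_trunc(Xd.T @ Yd, n_joint)
    C = Ct.T
    T = Xd @ W
    Uy = Yd @ C
    _fix_component_signs(T, W)
    _fix_component_signs(Uy, C)
    P_x = Xd.T @ T @ np.linalg.pinv(T.T @ T)
    P_y = Yd.T @ Uy @ np.linalg.pinv(Uy.T @ Uy)

    def _ortho_scores(T):
        if T.shape[1] == 0:
            return T
        Q, _ = np.linalg.qr(T)
        return Q

    sample_index = x.table.data.index
    common_cols = [f"C{i+1}" for i in range(n_joint)]
    common_scores = pd.DataFrame(_ortho_scores(T), index=sample_index,
                                 columns=common_cols)
    joint_loadings = {
        x.label: pd.DataFrame(W, index=x.table.data.columns, columns=common_cols),
        y.label: pd.DataFrame(C, index=y.table.data.columns, columns=common_cols),
    }
    dist_scores = {
        x.label: pd.DataFrame(Tox, index=sample_index,
                              columns=[f"D{i+1}" for i in range(Tox.shape[1])]),
        y.label: pd.DataFrame(Toy, index=sample_index,
                              columns=[f"D{i+1}" for i in range(Toy.shape[1])]),
    }
    dist_loadings = {
        x.label: pd.DataFrame(Pox, index=x.table.data.columns,
                              columns=[f"D{i+1}" for i in range(Pox.shape[1])]),
        y.label: pd.DataFrame(Poy, index=y.table.data.columns,
                              columns=[f"D{i+1}" for i in range(Poy.shape[1])]),
    }
    var_rows = []
    for blk, joint_hat, orth_scores, orth_loads, X0 in (
            (x, T @ P_x.T, Tox, Pox, X), (y, Uy @ P_y.T, Toy, Poy, Y)):
        orth_hat = orth_scores @ orth_loads.T
        ss = float((X0 ** 2).sum())
        var_rows.append({
            "block": blk.label,
            "joint": float((joint_hat ** 2).sum()) / ss,
            "distinctive": float((orth_hat ** 2).sum()) / ss,
            "residual": float(((X0 - joint_hat - orth_hat) ** 2).sum()) / ss,
        })
    var = pd.DataFrame(var_rows).set_index("block")
    return JointModel(method="o2pls", common_scores=common_scores,
                      joint_loadings=joint_loadings,
                      distinct_scores=dist_scores,
                      distinct_loadings=dist_loadings,
                      variance_explained=var, converged=True, n_iter=0,
                      criterion=0.0,
                      extras={"T": pd.DataFrame(T, index=sample_index,
                                                columns=common_cols),
                              "U": pd.DataFrame(Uy, index=sample_index,
                                                columns=common_cols),
                              "P_x": P_x, "P_y": P_y,
                              "cross_singular_values": s_all[:n_joint]})


def ranked_loadings(model: JointModel, block: str, component: int = 1,
                    top_k: int = 30, which: str = "joint") -> pd.DataFrame:
    """Top-k features of one component, sorted by |loading| descending.

    Ties are broken by feature id; the signed loading is kept in the output.
    ``component`` is 1-based.
    """
    loadings = (model.joint_loadings if which == "joint"
                else model.distinct_loadings)
    if block not in loadings:
        raise ParameterError(f"unknown block {block!r}; have {list(loadings)}")
    L = loadings[block]
    if not 1 <= component <= L.shape[1]:
        raise ParameterError(
            f"component {component} out of range 1..{L.shape[1]}")
    col = L.iloc[:, component - 1]
    out = pd.DataFrame({
        "feature_id": col.index,
        "loading": col.to_numpy(),
        "abs_loading": np.abs(col.to_numpy()),
    })
    out = out.sort_values(["abs_loading", "feature_id"],
                          ascending=[False, True], kind="mergesort",
                          ignore_index=True)
    return out.head(top_k).drop(columns="abs_loading")
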