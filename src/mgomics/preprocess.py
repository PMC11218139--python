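"""Transformations applied before testing, ordination and integration.

The usual chain for count tables is relative_abundance -> log_transform;
metabolite intensity tables go through pareto_scale; blocks entering a
multi-block decomposition are column-centered and Frobenius-normalised by
block_scale so that every block contributes equal total sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .io import FeatureTable, MappingTable

__all__ = [
    "relative_abundance",
    "log_transform",
    "pareto_scale",
    "aggregate_by_group",
    "block_scale",
    "BlockScaling",
]


def relative_abundance(table: FeatureTable) -> FeatureTable:
    """Convert counts to within-sample proportions (rows sum to 1)."""
    if table.transform_tag != "raw":
        raise ValidationError("relative_abundance expects a raw table")
    sums = table.data.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValidationError(f"all-zero samples: {list(zero.index)}")
    return table.with_data(table.data.div(sums, axis=0), transform_tag="relative")


def log_transform(table: FeatureTable, pseudocount_mode: str = "half_min_nonzero",
                  fixed_value: float | None = None) -> FeatureTable:
    """Natural log with a pseudocount.

    The default pseudocount is half the smallest non-zero entry of the whole
    table, a scale-aware offset that keeps zeros below every observed value;
    ``pseudocount_mode='fixed'`` uses ``fixed_value`` instead.
    """
    vals = table.values
    if (vals < 0).any():
        raise ValidationError("log_transform expects non-negative values")
    if pseudocount_mode == "half_min_nonzero":
        nonzero = vals[vals > 0]
        if nonzero.size == 0:
            raise ValidationError("table has no non-zero entries")
        eps = nonzero.min() / 2.0
    elif pseudocount_mode == "fixed":
        if fixed_value is None or fixed_value <= 0:
            raise ParameterError("fixed pseudocount must be a positive real")
        eps = float(fixed_value)
    else:
        raise ParameterError(f"unknown pseudocount_mode {pseudocount_mode!r}")
    tag = "log_relative" if table.transform_tag == "relative" else "log"
    out = pd.DataFrame(np.log(vals + eps), index=table.data.index,
                       columns=table.data.columns)
    return table.with_data(out, transform_tag=tag)


def pareto_scale(table: FeatureTable):
    """Pareto scaling: per feature, (x - mean) / sqrt(sd), sample (n-1) sd.

    Intermediate between plain centering and unit-variance autoscaling; the
    metabolomics convention for intensity tables. Constant features scale to
    all-zero and are listed in the returned report.

    Returns
    -------
    (FeatureTable, list[str])
        The scaled table and the ids of constant features.
    """
    if table.n_samples < 2:
        raise ValidationError("pareto_scale needs at least 2 samples")
    df = table.data
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    constant = list(sd.index[sd == 0])
    scale = np.sqrt(sd.replace(0.0, np.nan))
    out = (df - mean).div(scale, axis=1)
    out[constant] = 0.0
    return table.with_data(out, transform_tag="pareto"), constant


def aggregate_by_group(coverage: FeatureTable, assignment: MappingTable,
                       stat: str = "mean"):
    """Collapse contig coverages to genome-cluster abundances.

    Each cluster's value is the mean (default, "genomes expressed in average
    abundances") or sum of its member contigs. Contigs absent from the
    assignment are dropped and reported.

    Returns
    -------
    (FeatureTable, list[str])
        Cluster table (feature_kind=taxon_cluster) and the dropped contig ids.
    """
    if stat not in ("mean", "sum"):
        raise ParameterError(f"unknown stat {stat!r}")
    if assignment.role != "contig_to_cluster":
        raise ValidationError("assignment must have role=contig_to_cluster")
    contig_to_cluster = {e: g for e, g in zip(assignment.pairs["element_id"],
                                              assignment.pairs["group_id"])}
    assigned = [c for c in coverage.feature_ids if c in contig_to_cluster]
    dropped = [c for c in coverage.feature_ids if c not in contig_to_cluster]
    if not assigned:
        raise ValidationError("no contig in the coverage table matches the assignment")
    grouped = coverage.data[assigned].T.groupby(
        [contig_to_cluster[c] for c in assigned])
    agg = grouped.mean() if stat == "mean" else grouped.sum()
    out = agg.T.sort_index(axis=1)
    return coverage.with_data(out, feature_kind="taxon_cluster"), dropped


@dataclass
class BlockScaling:
    """Centering/scaling record allowing the inverse transform.

    ``centers`` hold per-feature column means; ``block_weight`` is the
    Frobenius norm the centered block was divided by.
    """

    centers: pd.Series
    block_weight: float

    def inverse(self, scaled: pd.DataFrame) -> pd.DataFrame:
        """Undo the Frobenius scaling (returns the centered block)."""
        return scaled * self.block_weight

    def inverse_full(self, scaled: pd.DataFrame) -> pd.DataFrame:
        """Undo scaling and centering."""
        return scaled * self.block_weight + self.centers


def block_scale(table: FeatureTable):
    """Column-center a block and normalise it to unit Frobenius norm.

    After this, every block entering a joint decomposition contributes equal
    total sum of squares, so no block dominates by sheer scale or size.
    """
    if table.n_samples < 2:
        raise ValidationError("block_scale needs at least 2 samples")
    centers = table.data.mean(axis=0)
    centered = table.data - centers
    norm = float(np.linalg.norm(centered.to_numpy()))
    if norm == 0:
        raise ValidationError("block is constant after centering")
    return (table.with_data(centered / norm, transform_tag="centered"),
            BlockScaling(centers=centers, block_weight=norm))
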