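"""Classical per-sample (alpha) diversity indices.

With :math:`p_i` the within-sample proportions over features with
:math:`p_i > 0`:

* Shannon entropy  :math:`H = -\\sum_i p_i \\ln p_i`  (natural log)
* Gini-Simpson     :math:`D = 1 - \\sum_i p_i^2`  (larger = more diverse)
* Pielou evenness  :math:`J = H / \\ln S` with :math:`S` the number of
  non-zero features; undefined (NaN) when :math:`S = 1`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .io import FeatureTable

__all__ = ["AlphaResult", "alpha_diversity", "ALPHA_INDICES"]

ALPHA_INDICES = ("shannon", "simpson", "pielou")


@dataclass
class AlphaResult:
    index: str
    values: pd.Series  # per sample; NaN where undefined

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


def _sample_alpha(row: np.ndarray, index: str) -> float:
    p = row[row > 0]
    p = p / p.sum()
    s = p.size
    h = float(-(p * np.log(p)).sum())
    if index == "shannon":
        return h
    if index == "simpson":
        return float(1.0 - (p ** 2).sum())
    # pielou
    if s == 1:
        return np.nan
    return h / np.log(s)


def alpha_diversity(table: FeatureTable, index: str = "shannon") -> AlphaResult:
    """Compute one alpha-diversity index for every sample.

    Accepts raw counts or relative abundances (indices are invariant to the
    within-sample total). Samples with no non-zero feature are an error.
    """
    if index not in ALPHA_INDICES:
        raise ParameterError(f"unknown index {index!r}; choose from {ALPHA_INDICES}")
    vals = table.values
    if (vals < 0).any():
        raise ValidationError("alpha diversity expects non-negative abundances")
    sums = vals.sum(axis=1)
    if (sums <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, sums) if t <= 0]
        raise ValidationError(f"all-zero samples: {bad}")
    out = pd.Series([_sample_alpha(vals[i], index) for i in range(vals.shape[0])],
                    index=table.data.index, name=index)
    return AlphaResult(index=index, values=out)
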