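"""KEGG metabolic-pathway over-representation analysis.

Pathway membership is defined on KEGG Orthology identifiers (KOs): a feature
(genome cluster, gene) contributes the union of its KOs. Over-representation
of a selected KO set against a background universe is assessed with the
hypergeometric upper tail, BH-corrected across pathways. Depletion is not
tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError
from .io import MappingTable
from .stats import adjust_pvalues

__all__ = ["build_pathway_sets", "pathway_enrichment", "features_to_kos"]


def build_pathway_sets(feature_to_ko: MappingTable, ko_to_pathway: MappingTable,
                       universe: str = "in-pathway"):
    """Assemble pathway -> KO sets and the background universe.

    With ``universe='in-pathway'`` (default) the background contains only the
    annotated KOs that belong to at least one pathway; ``'all-annotated'``
    keeps every KO seen in the feature annotations.

    Returns
    -------
    (pathway_sets, feature_index, universe_set, report)
        ``pathway_sets`` maps pathway id -> set of KOs restricted to the
        universe; ``feature_index`` maps feature id -> set of KOs;
        ``report`` lists KOs excluded from the default universe.
    """
    if universe not in ("in-pathway", "all-annotated"):
        raise ValidationError(f"unknown universe option {universe!r}")
    if len(feature_to_ko) == 0 or len(ko_to_pathway) == 0:
        raise ValidationError("empty mapping table")
    feature_index = feature_to_ko.as_dict_of_sets(by="element")
    annotated = set(feature_to_ko.pairs["group_id"])
    pathway_sets = ko_to_pathway.as_dict_of_sets(by="group")
    in_pathway = set().union(*pathway_sets.values())
    if universe == "in-pathway":
        uni = annotated & in_pathway
    else:
        uni = set(annotated)
    report = sorted(annotated - in_pathway)
    pathway_sets = {pw: kos & uni for pw, kos in pathway_sets.items()}
    pathway_sets = {pw: kos for pw, kos in pathway_sets.items() if kos}
    if not pathway_sets or not uni:
        raise ValidationError("no pathway retains any KO after filtering")
    return pathway_sets, feature_index, uni, report


def features_to_kos(feature_ids, feature_index: dict[str, set[str]]) -> set[str]:
    """Union of the KOs annotated on the given features."""
    out: set[str] = set()
    for f in feature_ids:
        out |= feature_index.get(f, set())
    return out


def pathway_enrichment(selected_kos: set[str], universe: set[str],
                       pathway_sets: dict[str, set[str]],
                       pathway_names: dict[str, str] | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation of each pathway in the selection.

    For a pathway with K universe members, a selection of n from a universe
    of N, the p-value is the upper tail P(X >= k) of Hypergeometric(N, K, n)
    at the observed overlap k. Rows are sorted by p ascending, ties broken by
    pathway id; padj is BH across the tested pathways.
    """
    selected = set(selected_kos)
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    strays = sorted(selected - universe)
    if strays:
        raise ValidationError(f"selected KOs outside the universe: {strays}")
    N, n = len(universe), len(selected)
    rows = []
    for pw in sorted(pathway_sets):
        members = pathway_sets[pw] & universe
        if not members:
            continue
        K = len(members)
        k = len(selected & members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "pathway_id": pw,
            "pathway_name": (pathway_names or {}).get(pw, pw),
            "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0),
        })
    if not rows:
        raise ValidationError("no pathway overlaps the universe")
    out = pd.DataFrame(rows)
    out["padj"] = adjust_pvalues(out["p"].tolist(), method="bh")
    out = out.sort_values(["p", "pathway_id"], kind="mergesort",
                          ignore_index=True)
    return out
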