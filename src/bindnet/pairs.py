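"""Pairwise pathway TF-sharing enrichment and the regional-enrichment rank.

For every unordered pair of annotated pathways, the TFs bound to each
pathway's promoters form two sets A and B drawn from a fixed universe of
screened TFs.  The 2x2 table a=|A∩B|, b=|A\\B|, c=|B\\A|, d=universe-|A∪B|
is tested one-tailed (greater) for excess sharing, with a joint adjustment
across all C(P,2) pairs.

"Regional enrichment" around a focal pathway ranks partner pathways by the
score p_adj / odds_ratio, ascending — the smallest score marks the partner
sharing the most regulators beyond chance.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from itertools import combinations

import networkx as nx
import pandas as pd

from .network import RegulatoryNetwork
from .stats import ContingencyTable, EnrichmentResult, adjust_pvalues, fisher_exact

logger = logging.getLogger(__name__)

#: TFs in the study-scale screen collection (assayed, not only detected).
DEFAULT_TF_UNIVERSE = 2039


@dataclass(frozen=True)
class PathwayPairResult:
    pathway_a: str
    pathway_b: str
    n_a: int
    n_b: int
    n_shared: int
    universe: int
    enrichment: EnrichmentResult
    regional_score: float = math.nan
    rank: int | None = None

    @property
    def partner_of(self):
        def _partner(focal: str) -> str:
            return self.pathway_b if self.pathway_a == focal else self.pathway_a

        return _partner


def _regional_score(result: EnrichmentResult) -> float:
    if not result.odds_ratio_defined:
        return math.nan
    if result.odds_ratio == 0:
        return math.inf
    return (result.p_adj if result.p_adj is not None else result.p_raw) / result.odds_ratio


def pairwise_pathway_sharing(
    network: RegulatoryNetwork,
    universe: int = DEFAULT_TF_UNIVERSE,
    adjust_method: str = "BH",
) -> list[PathwayPairResult]:
    """One-tailed sharing enrichment for all unordered pathway pairs.

    ``universe`` is the number of TFs screened (defaults to the assayed
    collection size, 2,039), and must cover the union of all pathway TF sets.
    """
    tf_sets = network.tfs_by_pathway()
    if len(tf_sets) < 2:
        warnings.warn("fewer than two annotated pathways; no pairs to test")
        return []
    all_tfs = set().union(*tf_sets.values())
    if universe < len(all_tfs):
        raise ValueError(
            f"universe ({universe}) smaller than number of detected TFs ({len(all_tfs)})"
        )
    results: list[PathwayPairResult] = []
    for pa, pb in combinations(sorted(tf_sets), 2):
        A, B = tf_sets[pa], tf_sets[pb]
        a = len(A & B)
        table = ContingencyTable(a, len(A) - a, len(B) - a, universe - len(A | B))
        res = fisher_exact(table, "greater")
        results.append(PathwayPairResult(pa, pb, len(A), len(B), a, universe, res))
    adj = adjust_pvalues([r.enrichment.p_raw for r in results], adjust_method)
    out = []
    for r, pa in zip(results, adj):
        enr = replace(r.enrichment, p_adj=pa, adjust_method=adjust_method)
        out.append(replace(r, enrichment=enr, regional_score=_regional_score(enr)))
    return out


def regional_enrichment_rank(
    results: list[PathwayPairResult], focal_pathway: str
) -> list[PathwayPairResult]:
    """Rank partner pathways of ``focal_pathway`` by ascending p_adj/OR.

    Ties break by larger shared-TF count, then lexicographic partner label.
    Pairs with an undefined odds ratio are excluded with a warning; OR = 0
    yields an infinite score and ranks last.
    """
    focal = [r for r in results if focal_pathway in (r.pathway_a, r.pathway_b)]
    if not focal:
        raise KeyError(f"no pairs involve pathway {focal_pathway!r}")
    kept = []
    for r in focal:
        if math.isnan(r.regional_score):
            warnings.warn(
                f"pair ({r.pathway_a}, {r.pathway_b}) has undefined odds ratio; excluded"
            )
        else:
            kept.append(r)
    kept.sort(key=lambda r: (r.regional_score, -r.n_shared, r.partner_of(focal_pathway)))
    return [replace(r, rank=i) for i, r in enumerate(kept, start=1)]


def sharing_graph(results: list[PathwayPairResult]) -> nx.Graph:
    """Pathway-pathway graph: node size = TF-set size, edge weight = shared TFs."""
    g = nx.Graph()
    for r in results:
        g.add_node(r.pathway_a, n_tfs=r.n_a)
        g.add_node(r.pathway_b, n_tfs=r.n_b)
        g.add_edge(
            r.pathway_a,
            r.pathway_b,
            weight=r.n_shared,
            p_adj=float(r.enrichment.p_adj if r.enrichment.p_adj is not None else math.nan),
        )
    return g


def to_dataframe(results: list[PathwayPairResult]) -> pd.DataFrame:
    rows = [
        {
            "pathway_a": r.pathway_a,
            "pathway_b": r.pathway_b,
            "n_a": r.n_a,
            "n_b": r.n_b,
            "n_shared": r.n_shared,
            "universe": r.universe,
            "odds_ratio": r.enrichment.odds_ratio,
            "p_raw": r.enrichment.p_raw,
            "p_adj": r.enrichment.p_adj,
            "regional_score": r.regional_score,
            "rank": r.rank,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
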