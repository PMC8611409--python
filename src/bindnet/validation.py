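"""Enrichment of network-predicted targets within differential-expression sets.

A TF-induction experiment (e.g. a dexamethasone-inducible GR fusion) yields a
set of differentially expressed genes (DEGs) against the universe of genes
tested for differential expression.  Overlap between the TF's predicted
binding targets and the DEG set is tested one-tailed (greater) with Fisher's
exact test; pathway-level and compartment-level variants ask whether a gene
group is over-represented among the DEGs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .network import _norm
from .stats import ContingencyTable, EnrichmentResult, adjust_pvalues, fisher_exact

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEGSet:
    contrast_id: str
    genes: frozenset[str]
    universe: frozenset[str]
    direction: str = "any"  # up / down / any

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "any"):
            raise ValueError(f"direction must be up/down/any: {self.direction!r}")
        if not self.genes <= self.universe:
            extra = sorted(self.genes - self.universe)[:5]
            raise ValueError(f"DEGs outside the tested universe: {extra}")


def read_deg_table(path: str | Path, universe: Iterable[str], contrast_id: str | None = None,
                   direction: str = "any") -> DEGSet:
    """TSV per contrast: columns ``gene_id``, ``direction``, ``significant``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    sig = df[df["significant"].astype(bool)]
    if direction != "any":
        sig = sig[sig["direction"] == direction]
    return DEGSet(
        contrast_id=contrast_id or Path(path).stem,
        genes=frozenset(_norm(g) for g in sig["gene_id"]),
        universe=frozenset(_norm(g) for g in universe),
        direction=direction,
    )


def _overlap_table(deg: DEGSet, gene_set: frozenset[str]) -> ContingencyTable:
    a = len(gene_set & deg.genes)
    b = len(gene_set - deg.genes)
    c = len(deg.genes - gene_set)
    d = len(deg.universe) - a - b - c
    return ContingencyTable(a, b, c, d)


def _restrict_to_universe(genes: Iterable[str], deg: DEGSet, label: str) -> frozenset[str]:
    genes = frozenset(_norm(g) for g in genes)
    dropped = genes - deg.universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} {label} genes outside the DE-tested universe dropped"
        )
    return genes & deg.universe


def target_deg_enrichment(deg: DEGSet, targets: Iterable[str]) -> EnrichmentResult:
    """One-tailed enrichment of a TF's predicted targets among its DEGs."""
    if not deg.universe:
        raise ValueError("empty DE universe")
    kept = _restrict_to_universe(targets, deg, "target")
    return fisher_exact(_overlap_table(deg, kept), "greater")


def pathway_deg_enrichment(
    deg: DEGSet, pathway_genes: Iterable[str]
) -> tuple[EnrichmentResult, float]:
    """Enrichment of a pathway's genes among DEGs, plus the recovered fraction
    (DE pathway genes / all pathway genes in the universe)."""
    if not deg.universe:
        raise ValueError("empty DE universe")
    kept = _restrict_to_universe(pathway_genes, deg, "pathway")
    if not kept:
        raise ValueError("no pathway genes fall inside the DE-tested universe")
    result = fisher_exact(_overlap_table(deg, kept), "greater")
    recovered = len(kept & deg.genes) / len(kept)
    return result, recovered


@dataclass(frozen=True)
class CompartmentDEGResult:
    compartment: str
    n_compartment: int
    n_compartment_deg: int
    enrichment: EnrichmentResult

    @property
    def significant_raw(self) -> bool:
        return self.enrichment.p_raw < 0.05

    @property
    def significant_adjusted(self) -> bool:
        return self.enrichment.p_adj is not None and self.enrichment.p_adj < 0.05


def compartment_deg_enrichment(
    deg: DEGSet,
    pathway_genes_by_compartment: Mapping[str, Iterable[str]],
    adjust_method: str = "BH",
) -> list[CompartmentDEGResult]:
    """Two-sided compartment-membership x DE-status tests within one pathway.

    The universe of each table is the pathway's genes (all compartments
    pooled), so the test asks whether the DE response concentrates in a
    particular compartment's isoforms.  Empty compartments are skipped.
    """
    comp_sets: dict[str, frozenset[str]] = {}
    for comp, genes in pathway_genes_by_compartment.items():
        kept = _restrict_to_universe(genes, deg, f"compartment {comp}")
        if not kept:
            warnings.warn(f"compartment {comp!r} has no genes in the universe; skipped")
            continue
        comp_sets[comp] = kept
    all_genes = frozenset().union(*comp_sets.values()) if comp_sets else frozenset()
    deg_in_pathway = all_genes & deg.genes
    results: list[CompartmentDEGResult] = []
    for comp in sorted(comp_sets):
        genes = comp_sets[comp]
        others = all_genes - genes
        a = len(genes & deg_in_pathway)
        table = ContingencyTable(
            a, len(genes) - a,
            len(others & deg_in_pathway), len(others - deg_in_pathway),
        )
        results.append(
            CompartmentDEGResult(comp, len(genes), a, fisher_exact(table, "two_sided"))
        )
    adj = adjust_pvalues([r.enrichment.p_raw for r in results], adjust_method)
    out = []
    for r, pa in zip(results, adj):
        from dataclasses import replace
        out.append(replace(r, enrichment=replace(r.enrichment, p_adj=pa, adjust_method=adjust_method)))
    return out


def to_dataframe(results: list[CompartmentDEGResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compartment": r.compartment,
                "n_genes": r.n_compartment,
                "n_deg": r.n_compartment_deg,
                "odds_ratio": r.enrichment.odds_ratio,
                "p_raw": r.enrichment.p_raw,
                "p_adj": r.enrichment.p_adj,
                "significant_raw": r.significant_raw,
                "significant_adjusted": r.significant_adjusted,
            }
            for r in results
        ]
    )
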