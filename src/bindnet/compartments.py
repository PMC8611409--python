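"""TF-family enrichment over enzyme-step x subcellular-compartment gene groups.

Plant central-metabolism enzymes (e.g. the TCA cycle's nine reaction steps)
occur as isoforms targeted to different compartments — mitochondrion, plastid,
peroxisome, cytosol.  Within a pathway subnetwork this module asks whether a
TF family's members preferentially bind the promoters of one (step,
compartment) isoform group, via a two-tailed Fisher exact test on family
membership x binding status, Holm-adjusted across all tested triples.

Localization calls are resolved from a flat annotation table (SUBA-style):
experimental evidence overrides consensus prediction; contradictory rows
within the winning evidence tier are an error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import pandas as pd

from .network import AnnotationError, RegulatoryNetwork, _norm
from .stats import ContingencyTable, EnrichmentResult, adjust_pvalues, fisher_exact

logger = logging.getLogger(__name__)

EVIDENCE_LEVELS = ("consensus_predicted", "experimental")


@dataclass(frozen=True)
class LocalizationCall:
    enzyme_step: str
    compartment: str
    evidence: str


@dataclass(frozen=True)
class FamilyCompartmentResult:
    family: str
    enzyme_step: str
    compartment: str
    n_family_binding: int
    n_family_total: int
    n_other_binding: int
    n_other_total: int
    enrichment: EnrichmentResult
    #: fraction of the family's subnetwork-active TFs binding this group
    family_binding_fraction: float

    @property
    def significant(self) -> bool:
        return self.enrichment.p_adj is not None and self.enrichment.p_adj < 0.05


def resolve_localization(table: pd.DataFrame) -> dict[str, LocalizationCall]:
    """Collapse a localization table to one (step, compartment) call per gene.

    Expects columns ``promoter_id``, ``enzyme_step``, ``compartment``,
    ``evidence`` (one of ``consensus_predicted`` / ``experimental``).
    Experimental rows take precedence over consensus-predicted ones;
    contradictory rows within the winning tier raise :class:`AnnotationError`.
    """
    required = {"promoter_id", "enzyme_step", "compartment", "evidence"}
    missing = required - set(table.columns)
    if missing:
        raise AnnotationError(f"localization table missing columns {sorted(missing)}")
    bad = set(table["evidence"]) - set(EVIDENCE_LEVELS)
    if bad:
        raise AnnotationError(f"unknown evidence levels: {sorted(bad)}")
    out: dict[str, LocalizationCall] = {}
    for gene, rows in table.groupby(table["promoter_id"].map(_norm)):
        exp = rows[rows["evidence"] == "experimental"]
        tier = exp if len(exp) else rows
        calls = {(str(s).upper(), str(c).lower()) for s, c in zip(tier["enzyme_step"], tier["compartment"])}
        if len(calls) > 1:
            raise AnnotationError(
                f"conflicting {'experimental' if len(exp) else 'consensus'} "
                f"localization for {gene}: {sorted(calls)}"
            )
        step, comp = calls.pop()
        out[gene] = LocalizationCall(step, comp, "experimental" if len(exp) else "consensus_predicted")
    return out


def family_compartment_enrichment(
    subnetwork: RegulatoryNetwork,
    families: Mapping[str, str],
    localization: Mapping[str, LocalizationCall] | None = None,
    *,
    adjust_method: str = "Holm",
    alpha: float = 0.05,
) -> list[FamilyCompartmentResult]:
    """Two-tailed family-membership x binding enrichment per (family, step,
    compartment) triple.

    ``families`` maps every TF in the assayed collection to its family label;
    this collection (not the subnetwork) is the test denominator.  Genes
    without a localization call are excluded with a warning.  Adjustment runs
    jointly across all triples with at least one annotated gene.
    """
    families = {_norm(t): f for t, f in families.items()}
    orphan_tfs = sorted(t for t in subnetwork.tf_ids if t not in families)
    if orphan_tfs:
        warnings.warn(f"{len(orphan_tfs)} subnetwork TFs absent from family table; skipped")

    if localization is None:
        localization = {
            p: LocalizationCall(rec.enzyme_step, rec.compartment, rec.localization_evidence or "consensus_predicted")
            for p, rec in subnetwork.promoter_index.items()
            if rec.enzyme_step and rec.compartment
        }
    localization = {_norm(g): call for g, call in localization.items()}
    missing = sorted(p for p in subnetwork.promoter_ids if p not in localization)
    if missing:
        warnings.warn(f"{len(missing)} subnetwork genes lack localization; excluded")

    # (step, compartment) -> genes in the subnetwork
    groups: dict[tuple[str, str], set[str]] = {}
    for g, call in localization.items():
        if g in subnetwork.promoter_ids:
            groups.setdefault((call.enzyme_step, call.compartment), set()).add(g)

    # TF -> bound genes (within subnetwork, localization-annotated only)
    bound: dict[str, set[str]] = {}
    for t, p in subnetwork.edges:
        if t in families and p in localization:
            bound.setdefault(t, set()).add(p)

    members: dict[str, set[str]] = {}
    for t, f in families.items():
        members.setdefault(f, set()).add(t)
    n_collection = len(families)

    results: list[FamilyCompartmentResult] = []
    for fam in sorted(members):
        fam_tfs = members[fam]
        fam_active = {t for t in fam_tfs if bound.get(t)}
        for (step, comp) in sorted(groups):
            genes = groups[(step, comp)]
            binders = {t for t, gs in bound.items() if gs & genes}
            a = len(binders & fam_tfs)
            b = len(fam_tfs) - a
            c = len(binders) - a
            d = n_collection - len(fam_tfs) - c
            res = fisher_exact(ContingencyTable(a, b, c, d), "two_sided")
            results.append(
                FamilyCompartmentResult(
                    family=fam,
                    enzyme_step=step,
                    compartment=comp,
                    n_family_binding=a,
                    n_family_total=len(fam_tfs),
                    n_other_binding=c,
                    n_other_total=n_collection - len(fam_tfs),
                    enrichment=res,
                    family_binding_fraction=a / len(fam_active) if fam_active else 0.0,
                )
            )
    adj = adjust_pvalues([r.enrichment.p_raw for r in results], adjust_method)
    return [
        replace(r, enrichment=replace(r.enrichment, p_adj=pa, adjust_method=adjust_method))
        for r, pa in zip(results, adj)
    ]


def to_dataframe(results: list[FamilyCompartmentResult]) -> pd.DataFrame:
    rows = [
        {
            "family": r.family,
            "enzyme_step": r.enzyme_step,
            "compartment": r.compartment,
            "a": r.n_family_binding,
            "b": r.n_family_total - r.n_family_binding,
            "c": r.n_other_binding,
            "d": r.n_other_total - r.n_other_binding,
            "family_binding_fraction": r.family_binding_fraction,
            "odds_ratio": r.enrichment.odds_ratio,
            "p_raw": r.enrichment.p_raw,
            "p_adj": r.enrichment.p_adj,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
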