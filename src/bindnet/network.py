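"""Bipartite transcription-factor / promoter network: data model, I/O, topology.

The central object is :class:`RegulatoryNetwork`, a deduplicated set of
(tf_id, promoter_id) edges from a protein--DNA interaction screen (e.g. an
enhanced yeast one-hybrid assay), with optional annotation joins: TF family,
promoter metabolic pathway membership, and enzyme-step / subcellular-compartment
labels for the promoter's downstream gene.

Identifiers are normalized to uppercase at read time (AGI locus convention).
The two node namespaces must be disjoint: an identifier appearing both as a TF
and as a promoter is rejected as a bipartiteness violation.
"""

from __future__ import annotations

import logging
import statistics
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

COMPARTMENTS = ("mitochondrion", "plastid", "peroxisome", "cytosol")
ENZYME_STEPS = ("PDH", "CSY", "ACO", "IDH", "OGD", "SCL", "SDH", "FUM", "MDH")


class NetworkFormatError(ValueError):
    """Malformed edge-list or annotation input."""


class BipartiteError(NetworkFormatError):
    """An identifier occurs in both the TF and the promoter namespace."""


class AnnotationError(ValueError):
    """Missing or contradictory annotation for a referenced gene."""


class PathwayLookupError(KeyError):
    """A pathway label absent from every promoter annotation."""


@dataclass(frozen=True)
class TFRecord:
    tf_id: str
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.tf_id:
            raise NetworkFormatError("tf_id must be nonempty")


@dataclass(frozen=True)
class PromoterRecord:
    promoter_id: str
    pathways: frozenset[str] = frozenset()
    enzyme_step: str | None = None
    compartment: str | None = None
    localization_evidence: str | None = None

    def __post_init__(self) -> None:
        if not self.promoter_id:
            raise NetworkFormatError("promoter_id must be nonempty")
        if self.enzyme_step is not None and self.compartment is None:
            raise AnnotationError(
                f"{self.promoter_id}: compartment required when enzyme_step is set"
            )


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Deduplicated bipartite edge set with per-node annotation indices.

    ``hit_free_promoters`` records promoters that were screened but produced no
    interaction; they are excluded from ``promoter_index`` and from all counts.
    """

    edges: frozenset[tuple[str, str]]
    tf_index: dict[str, TFRecord] = field(default_factory=dict)
    promoter_index: dict[str, PromoterRecord] = field(default_factory=dict)
    hit_free_promoters: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        tf_ids = {t for t, _ in self.edges}
        prom_ids = {p for _, p in self.edges}
        clash = tf_ids & prom_ids
        if clash:
            raise BipartiteError(
                f"identifiers in both TF and promoter roles: {sorted(clash)[:5]}"
            )
        for t in tf_ids:
            if t not in self.tf_index:
                raise NetworkFormatError(f"edge endpoint {t} missing from tf_index")
        for p in prom_ids:
            if p not in self.promoter_index:
                raise NetworkFormatError(f"edge endpoint {p} missing from promoter_index")

    # -- basic topology ----------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def tf_ids(self) -> set[str]:
        return {t for t, _ in self.edges}

    @property
    def promoter_ids(self) -> set[str]:
        return {p for _, p in self.edges}

    def promoter_degrees(self) -> dict[str, int]:
        deg = Counter(p for _, p in self.edges)
        return dict(deg)

    def tf_degrees(self) -> dict[str, int]:
        return dict(Counter(t for t, _ in self.edges))

    def targets_of(self, tf_id: str) -> set[str]:
        return {p for t, p in self.edges if t == tf_id}

    def pathway_labels(self) -> set[str]:
        out: set[str] = set()
        for rec in self.promoter_index.values():
            out |= rec.pathways
        return out

    def tfs_by_pathway(self) -> dict[str, set[str]]:
        """Distinct TFs bound to >=1 promoter of each pathway (set semantics)."""
        sets: dict[str, set[str]] = {}
        for t, p in self.edges:
            for pw in self.promoter_index[p].pathways:
                sets.setdefault(pw, set()).add(t)
        return sets

    def tf_pathway_spans(self) -> dict[str, set[str]]:
        """Per detected TF, the union of pathways of its bound promoters."""
        spans: dict[str, set[str]] = {}
        for t, p in self.edges:
            spans.setdefault(t, set()).update(self.promoter_index[p].pathways)
        return spans


@dataclass(frozen=True)
class NetworkSummary:
    n_edges: int
    n_tfs: int
    n_promoters: int
    n_hit_free_promoters: int
    promoter_degree_min: int
    promoter_degree_max: int
    promoter_degree_mean: float
    tf_pathway_multiplicity: dict[int, int]

    def to_dict(self) -> dict:
        d = {
            "n_edges": self.n_edges,
            "n_tfs": self.n_tfs,
            "n_promoters": self.n_promoters,
            "n_hit_free_promoters": self.n_hit_free_promoters,
            "promoter_degree_min": self.promoter_degree_min,
            "promoter_degree_max": self.promoter_degree_max,
            "promoter_degree_mean": self.promoter_degree_mean,
        }
        d.update({f"tfs_in_{k}_pathways": v for k, v in sorted(self.tf_pathway_multiplicity.items())})
        return d


# ---------------------------------------------------------------------------
# construction / I/O
# ---------------------------------------------------------------------------


def _norm(x: str) -> str:
    return str(x).strip().upper()


def build_network(
    edges: Iterable[tuple[str, str]],
    *,
    pathway_table: Mapping[str, Iterable[str]] | None = None,
    family_table: Mapping[str, str] | None = None,
    localization: Mapping[str, tuple[str, str, str]] | None = None,
    screened_promoters: Iterable[str] | None = None,
) -> RegulatoryNetwork:
    """Assemble a network from raw edge pairs plus optional annotation mappings.

    ``localization`` maps promoter_id -> (enzyme_step, compartment, evidence),
    typically the output of :func:`bindnet.compartments.resolve_localization`.
    Identifiers are uppercased; duplicate edges are collapsed (count logged).
    """
    raw = [(_norm(t), _norm(p)) for t, p in edges]
    dedup = frozenset(raw)
    n_dup = len(raw) - len(dedup)
    if n_dup:
        logger.info("collapsed %d duplicate edges (%d rows -> %d edges)", n_dup, len(raw), len(dedup))

    pathway_table = {_norm(k): frozenset(map(_norm, v)) for k, v in (pathway_table or {}).items()}
    family_table = {_norm(k): v for k, v in (family_table or {}).items()}
    localization = {_norm(k): v for k, v in (localization or {}).items()}

    tf_index = {t: TFRecord(t, family_table.get(t)) for t in {t for t, _ in dedup}}

    def _prom(p: str) -> PromoterRecord:
        step, comp, ev = localization.get(p, (None, None, None))
        return PromoterRecord(
            p,
            pathways=pathway_table.get(p, frozenset()),
            enzyme_step=step,
            compartment=comp,
            localization_evidence=ev,
        )

    hit = {p for _, p in dedup}
    promoter_index = {p: _prom(p) for p in hit}
    hit_free = frozenset(_norm(p) for p in (screened_promoters or [])) - hit
    return RegulatoryNetwork(dedup, tf_index, promoter_index, frozenset(hit_free))


def read_edge_list(
    path: str | Path,
    *,
    pathway_table: Mapping[str, Iterable[str]] | None = None,
    family_table: Mapping[str, str] | None = None,
    localization: Mapping[str, tuple[str, str, str]] | None = None,
    screened_promoters: Iterable[str] | None = None,
) -> RegulatoryNetwork:
    """Read a TSV edge list (header columns ``tf_id``, ``promoter_id``).

    An empty file yields an empty network; missing required columns raise
    :class:`NetworkFormatError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return build_network([], screened_promoters=screened_promoters)
    missing = {"tf_id", "promoter_id"} - set(df.columns)
    if missing:
        raise NetworkFormatError(f"{path}: missing required columns {sorted(missing)}")
    logger.info("read %d edge rows from %s", len(df), path)
    return build_network(
        zip(df["tf_id"], df["promoter_id"]),
        pathway_table=pathway_table,
        family_table=family_table,
        localization=localization,
        screened_promoters=screened_promoters,
    )


def read_pathway_table(path: str | Path) -> dict[str, set[str]]:
    """TSV ``promoter_id<TAB>pathway``, one membership per row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"promoter_id", "pathway"} - set(df.columns)
    if missing:
        raise NetworkFormatError(f"{path}: missing required columns {sorted(missing)}")
    out: dict[str, set[str]] = {}
    for pid, pw in zip(df["promoter_id"], df["pathway"]):
        out.setdefault(_norm(pid), set()).add(_norm(pw))
    return out


def read_family_table(path: str | Path) -> dict[str, str]:
    """TSV ``tf_id<TAB>family``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"tf_id", "family"} - set(df.columns)
    if missing:
        raise NetworkFormatError(f"{path}: missing required columns {sorted(missing)}")
    return {_norm(t): str(f) for t, f in zip(df["tf_id"], df["family"])}


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def summarize(network: RegulatoryNetwork) -> NetworkSummary:
    """Edge/node counts and the TF pathway-multiplicity spectrum.

    Only promoters with >=1 interaction enter ``n_promoters`` and the degree
    statistics; screened-but-hit-free promoters are reported separately.
    """
    degrees = list(network.promoter_degrees().values())
    spans = network.tf_pathway_spans()
    mult = Counter(len(s) for s in spans.values())
    return NetworkSummary(
        n_edges=network.n_edges,
        n_tfs=len(network.tf_ids),
        n_promoters=len(network.promoter_ids),
        n_hit_free_promoters=len(network.hit_free_promoters),
        promoter_degree_min=min(degrees) if degrees else 0,
        promoter_degree_max=max(degrees) if degrees else 0,
        promoter_degree_mean=statistics.fmean(degrees) if degrees else 0.0,
        tf_pathway_multiplicity=dict(sorted(mult.items())),
    )


def pathway_multiplicity_fraction(network: RegulatoryNetwork, k_min: int = 2) -> float:
    """Fraction of detected TFs whose bound promoters span >= k_min pathways."""
    unannotated = sorted(p for p in network.promoter_ids if not network.promoter_index[p].pathways)
    if unannotated:
        raise AnnotationError(f"promoters without pathway annotation: {unannotated[:10]}")
    spans = network.tf_pathway_spans()
    if not spans:
        return 0.0
    return sum(1 for s in spans.values() if len(s) >= k_min) / len(spans)


def extract_subnetwork(network: RegulatoryNetwork, pathway: str) -> RegulatoryNetwork:
    """Restrict to edges whose promoter is annotated to ``pathway``."""
    pathway = _norm(pathway)
    if pathway not in {_norm(x) for x in network.pathway_labels()}:
        raise PathwayLookupError(pathway)
    keep_p = {
        p for p, rec in network.promoter_index.items() if pathway in {_norm(x) for x in rec.pathways}
    }
    edges = frozenset((t, p) for t, p in network.edges if p in keep_p)
    tfs = {t for t, _ in edges}
    proms = {p for _, p in edges}
    return RegulatoryNetwork(
        edges,
        {t: network.tf_index[t] for t in tfs},
        {p: network.promoter_index[p] for p in proms},
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_network(network: RegulatoryNetwork, fmt: str, path: str | Path) -> None:
    """Write SIF (``tf<TAB>binds<TAB>promoter``) or GraphML with node attributes."""
    path = Path(path)
    fmt = fmt.upper()
    if fmt == "SIF":
        lines = [f"{t}\tbinds\t{p}" for t, p in sorted(network.edges)]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "GRAPHML":
        g = nx.Graph()
        for t in sorted(network.tf_ids):
            rec = network.tf_index[t]
            g.add_node(t, role="TF", family=rec.family or "")
        for p in sorted(network.promoter_ids):
            rec = network.promoter_index[p]
            g.add_node(
                p,
                role="promoter",
                pathways="|".join(sorted(rec.pathways)),
                enzyme_step=rec.enzyme_step or "",
                compartment=rec.compartment or "",
            )
        g.add_edges_from(sorted(network.edges))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unsupported export format: {fmt}")


def read_graphml(path: str | Path) -> RegulatoryNetwork:
    """Rebuild a network from a GraphML export (round-trip inverse of export)."""
    g = nx.read_graphml(path)
    roles = nx.get_node_attributes(g, "role")
    edges = []
    for u, v in g.edges():
        if roles.get(u) == "TF":
            edges.append((u, v))
        else:
            edges.append((v, u))
    fam = {
        n: (d.get("family") or None) for n, d in g.nodes(data=True) if d.get("role") == "TF"
    }
    pathways = {
        n: set(filter(None, d.get("pathways", "").split("|")))
        for n, d in g.nodes(data=True)
        if d.get("role") == "promoter"
    }
    loc = {
        n: (d.get("enzyme_step") or None, d.get("compartment") or None, None)
        for n, d in g.nodes(data=True)
        if d.get("role") == "promoter" and d.get("enzyme_step")
    }
    return build_network(
        edges,
        pathway_table=pathways,
        family_table={k: v for k, v in fam.items() if v},
        localization=loc,
    )


def write_edge_list(network: RegulatoryNetwork, path: str | Path) -> None:
    rows = sorted(network.edges)
    pd.DataFrame(rows, columns=["tf_id", "promoter_id"]).to_csv(path, sep="\t", index=False)
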