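"""Seeded generators for synthetic screen, expression, and DEG inputs.

The generators emit exactly the file formats and in-memory objects the
analysis stages consume, with controllable planted structure:

* a bipartite binding network over pathway-annotated promoters, with per-TF
  binding breadth (log-normal multiplier), a planted excess of TF sharing
  between chosen pathway pairs (a "co-regulator" subset of TFs whose binding
  probability to both pathways is boosted), and a planted TF-family bias
  toward an enzyme-step x compartment gene group;
* expression compendia in which chosen edges carry an exact population
  correlation in exactly one dataset (target = rho * z_tf + sqrt(1-rho^2) * eps)
  and are uncorrelated elsewhere;
* DEG sets whose overlap with a target set follows a planted odds ratio
  (Fisher noncentral hypergeometric draw conditioned on the DEG count).

The default scale mirrors a genome-scale yeast one-hybrid screen at roughly
quarter size — 500 TFs, 60 promoters across 12 metabolic pathways — so that a
full pipeline run stays within interactive test budgets.  Each generator call
draws from its own RNG stream derived from (seed, generator-name), so adding
a generator never perturbs the output of another.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import nchypergeom_fisher

from .coexpression import ExpressionDataset
from .network import RegulatoryNetwork, build_network
from .validation import DEGSet

logger = logging.getLogger(__name__)


class SimulationSpecError(ValueError):
    """Internally inconsistent or infeasible simulation specification."""


def _rng(seed: int, name: str) -> np.random.Generator:
    """Independent stream per (seed, generator-name)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# network generator
# ---------------------------------------------------------------------------

#: quarter-scale analogue of a 12-pathway central-metabolism promoter panel
DEFAULT_PATHWAY_SIZES: tuple[tuple[str, int], ...] = (
    ("TCA_CYCLE", 14),
    ("GLYCOLYSIS_GLUCONEOGENESIS", 16),
    ("PENTOSE_PHOSPHATE", 6),
    ("ALIPHATIC_GSL", 6),
    ("BCAA_BIOSYNTHESIS", 5),
    ("ASPARTATE_BIOSYNTHESIS", 3),
    ("CYSTEINE_BIOSYNTHESIS", 2),
    ("METHIONINE_BIOSYNTHESIS", 2),
    ("SERINE_BIOSYNTHESIS", 2),
    ("SHIKIMATE", 2),
    ("ARGININE_GLYCINE_BIOSYNTHESIS", 1),
    ("GS_GOGAT", 1),
)

#: (enzyme_step, compartment) per TCA-analogue gene: mitochondrial core with
#: duplicated PDH/MDH isoforms plus plastid and cytosol bypass isoforms.
DEFAULT_TCA_LOCALIZATION: tuple[tuple[str, str], ...] = (
    ("PDH", "mitochondrion"), ("PDH", "mitochondrion"), ("PDH", "mitochondrion"),
    ("CSY", "mitochondrion"), ("ACO", "mitochondrion"),
    ("IDH", "mitochondrion"), ("OGD", "mitochondrion"),
    ("SCL", "mitochondrion"), ("SDH", "mitochondrion"),
    ("FUM", "mitochondrion"), ("MDH", "mitochondrion"),
    ("PDH", "plastid"), ("MDH", "plastid"),
    ("ACO", "cytosol"),
)

DEFAULT_FAMILIES: tuple[str, ...] = (
    "LBD", "MYB", "BHLH", "WRKY", "NAC", "AP2_ERF", "BZIP", "C2H2", "GATA",
    "HD_ZIP", "MADS", "ARF", "GRAS", "TCP", "DOF", "HSF", "E2F", "TRIHELIX",
    "SBP", "CAMTA",
)


@dataclass
class NetworkSimSpec:
    n_tfs: int = 500
    pathways: tuple[tuple[str, int], ...] = DEFAULT_PATHWAY_SIZES
    #: extra genes annotated to more than one pathway
    overlap_genes: tuple[tuple[str, tuple[str, ...]], ...] = (
        ("BRIDGE_MDH_CYT", ("TCA_CYCLE", "GLYCOLYSIS_GLUCONEOGENESIS")),
        ("BRIDGE_SERAT", ("CYSTEINE_BIOSYNTHESIS", "SERINE_BIOSYNTHESIS")),
    )
    base_binding_prob: float = 0.04
    #: sigma of the per-TF log-normal breadth multiplier (mean normalized to 1)
    breadth_sigma: float = 0.6
    #: (pathway_a, pathway_b, per-gene probability boost for co-regulator TFs)
    planted_pairs: tuple[tuple[str, str, float], ...] = (
        ("ALIPHATIC_GSL", "METHIONINE_BIOSYNTHESIS", 12.0),
        ("ALIPHATIC_GSL", "CYSTEINE_BIOSYNTHESIS", 8.0),
    )
    #: fraction of TFs acting as co-regulators of each planted pair
    coreg_fraction: float = 0.1
    #: (family, enzyme_step, compartment, probability multiplier)
    planted_family_bias: tuple[tuple[str, str, str, float], ...] = (
        ("LBD", "PDH", "mitochondrion", 4.0),
    )
    family_labels: tuple[str, ...] = DEFAULT_FAMILIES
    #: sampling weight of the first family (planted families benefit from size)
    first_family_weight: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.base_binding_prob <= 1):
            raise SimulationSpecError("base_binding_prob must lie in [0, 1]")
        if any(n < 1 for _, n in self.pathways):
            raise SimulationSpecError("pathway gene counts must be >= 1")


@dataclass
class SimulatedNetwork:
    network: RegulatoryNetwork
    pathway_table: dict[str, set[str]]
    family_table: dict[str, str]
    localization_table: pd.DataFrame


def simulate_network(spec: NetworkSimSpec) -> SimulatedNetwork:
    """Draw a bipartite binding network with the planted structure of ``spec``.

    Edge (t, g) is Bernoulli with probability
    ``clip(base * breadth_t * boosts(t, g), 0, 1)``.  Deterministic per seed.
    """
    rng = _rng(spec.seed, "network")

    genes: list[str] = []
    pathway_of: dict[str, set[str]] = {}
    for label, n in spec.pathways:
        for i in range(n):
            g = f"{label[:12]}_G{i + 1:02d}"
            genes.append(g)
            pathway_of[g] = {label}
    for g, pws in spec.overlap_genes:
        genes.append(g.upper())
        pathway_of[g.upper()] = set(pws)
    gene_idx = {g: i for i, g in enumerate(genes)}

    # enzyme-step x compartment annotation for the first pathway's genes
    first_label = spec.pathways[0][0]
    tca_genes = [g for g in genes if first_label in pathway_of[g] and len(pathway_of[g]) == 1]
    loc_rows = []
    for g, (step, comp) in zip(tca_genes, DEFAULT_TCA_LOCALIZATION):
        loc_rows.append({"promoter_id": g, "enzyme_step": step, "compartment": comp,
                        "evidence": "consensus_predicted"})
    localization_table = pd.DataFrame(
        loc_rows, columns=["promoter_id", "enzyme_step", "compartment", "evidence"]
    )
    loc_of = {r["promoter_id"]: (r["enzyme_step"], r["compartment"]) for r in loc_rows}

    tfs = [f"TF{i + 1:04d}" for i in range(spec.n_tfs)]
    weights = np.asarray(
        [spec.first_family_weight] + [1.0] * (len(spec.family_labels) - 1), dtype=float
    )
    fam_draw = rng.choice(len(spec.family_labels), size=spec.n_tfs, p=weights / weights.sum())
    family_table = {t: spec.family_labels[k] for t, k in zip(tfs, fam_draw)}

    breadth = rng.lognormal(mean=-spec.breadth_sigma**2 / 2, sigma=spec.breadth_sigma,
                            size=spec.n_tfs)
    prob = spec.base_binding_prob * breadth[:, None] * np.ones((spec.n_tfs, len(genes)))

    for pa, pb, boost in spec.planted_pairs:
        pair_genes = [gene_idx[g] for g in genes if pathway_of[g] & {pa, pb}]
        if not pair_genes:
            raise SimulationSpecError(f"planted pair ({pa}, {pb}) matches no genes")
        n_coreg = max(1, round(spec.coreg_fraction * spec.n_tfs))
        coreg = rng.choice(spec.n_tfs, size=n_coreg, replace=False)
        prob[np.ix_(coreg, pair_genes)] *= boost

    for fam, step, comp, mult in spec.planted_family_bias:
        fam_idx = [i for i, t in enumerate(tfs) if family_table[t] == fam]
        grp = [gene_idx[g] for g, sc in loc_of.items() if sc == (step, comp)]
        if not fam_idx or not grp:
            raise SimulationSpecError(
                f"planted family bias ({fam}, {step}, {comp}) matches no TFs or genes"
            )
        prob[np.ix_(fam_idx, grp)] *= mult

    if np.all(prob >= 1):
        warnings.warn("all binding probabilities saturate at 1; boosts are infeasible")
    n_clipped = int((prob > 1).sum())
    if n_clipped:
        logger.debug("clipped %d binding probabilities to 1", n_clipped)
    prob = np.clip(prob, 0.0, 1.0)

    hits = rng.random(prob.shape) < prob
    ti, gi = np.nonzero(hits)
    edges = [(tfs[i], genes[j]) for i, j in zip(ti, gi)]

    network = build_network(
        edges,
        pathway_table=pathway_of,
        family_table=family_table,
        localization={g: (s, c, "consensus_predicted") for g, (s, c) in loc_of.items()},
        screened_promoters=genes,
    )
    logger.info("simulated network: %d edges, %d TFs, %d promoters",
                network.n_edges, len(network.tf_ids), len(network.promoter_ids))
    return SimulatedNetwork(network, pathway_of, family_table, localization_table)


# ---------------------------------------------------------------------------
# expression generator
# ---------------------------------------------------------------------------

DEFAULT_DATASETS: tuple[tuple[str, int], ...] = (
    ("development", 60),
    ("root", 48),
    ("pollen", 20),
    ("osmotic", 40),
    ("salt", 40),
)


@dataclass
class CoexprSimSpec:
    datasets: tuple[tuple[str, int], ...] = DEFAULT_DATASETS
    #: (tf_id, target_id, dataset_name, population_r); the edge must exist in
    #: the network, and a target may be planted at most once per dataset
    planted_edges: tuple[tuple[str, str, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 3 for _, n in self.datasets):
            raise SimulationSpecError("every dataset needs >= 3 samples")
        names = {n for n, _ in self.datasets}
        seen: set[tuple[str, str]] = set()
        for tf, tg, ds, rho in self.planted_edges:
            if ds not in names:
                raise SimulationSpecError(f"planted edge references unknown dataset {ds!r}")
            if not (-1 <= rho <= 1):
                raise SimulationSpecError(f"|population_r| must be <= 1, got {rho}")
            key = (tg, ds)
            if key in seen:
                raise SimulationSpecError(
                    f"gene {tg} planted twice in dataset {ds}: conflicting roles"
                )
            seen.add(key)


def simulate_coexpression(
    spec: CoexprSimSpec, network: RegulatoryNetwork
) -> list[ExpressionDataset]:
    """Gaussian expression compendia with exact planted edge correlations.

    All profiles are i.i.d. standard normal except planted targets, rewritten
    as ``rho * z_tf + sqrt(1 - rho^2) * eps`` in their planted dataset only, so
    the population correlation there is exactly rho and 0 elsewhere.
    """
    for tf, tg, ds, _ in spec.planted_edges:
        if (tf, tg) not in network.edges:
            raise SimulationSpecError(f"planted edge ({tf}, {tg}) not in the network")
    rng = _rng(spec.seed, "coexpression")
    ids = sorted(network.tf_ids) + sorted(network.promoter_ids)
    row = {g: i for i, g in enumerate(ids)}
    out = []
    for name, n_samples in spec.datasets:
        mat = rng.standard_normal((len(ids), n_samples))
        for tf, tg, ds, rho in spec.planted_edges:
            if ds != name:
                continue
            mat[row[tg]] = rho * mat[row[tf]] + np.sqrt(1 - rho**2) * mat[row[tg]]
        out.append(ExpressionDataset(name, pd.DataFrame(
            mat, index=ids, columns=[f"{name}_s{j + 1:03d}" for j in range(n_samples)]
        )))
    return out


def default_coexpression_spec(
    network: RegulatoryNetwork,
    seed: int = 0,
    n_planted_per_dataset: int = 8,
    rho: float = 0.95,
    datasets: tuple[tuple[str, int], ...] = DEFAULT_DATASETS,
) -> CoexprSimSpec:
    """Plant ``rho`` on disjoint edge subsets, each exclusive to one dataset."""
    rng = _rng(seed, "coexpression-plan")
    edges = sorted(network.edges)
    # one planting per target gene at most, to keep roles unambiguous
    by_target: dict[str, tuple[str, str]] = {}
    for t, g in edges:
        by_target.setdefault(g, (t, g))
    candidates = sorted(by_target.values())
    need = n_planted_per_dataset * len(datasets)
    if len(candidates) < need:
        raise SimulationSpecError(
            f"network offers {len(candidates)} plantable edges; need {need}"
        )
    chosen = rng.choice(len(candidates), size=need, replace=False)
    planted = []
    for k, idx in enumerate(chosen):
        tf, tg = candidates[idx]
        ds = datasets[k % len(datasets)][0]
        planted.append((tf, tg, ds, rho))
    return CoexprSimSpec(datasets=datasets, planted_edges=tuple(planted), seed=seed)


# ---------------------------------------------------------------------------
# DEG generator
# ---------------------------------------------------------------------------


def simulate_deg_set(
    universe_size: int,
    targets: int | Sequence[str],
    n_deg: int,
    odds_ratio: float,
    seed: int = 0,
    contrast_id: str = "synthetic_contrast",
) -> tuple[DEGSet, frozenset[str]]:
    """DEG set with a planted target-overlap odds ratio.

    The overlap count is a Fisher noncentral hypergeometric draw conditioned
    on ``n_deg``; membership within target / non-target strata is uniform.
    Returns (DEG set, target gene set).
    """
    if n_deg > universe_size:
        raise SimulationSpecError("n_deg exceeds the universe size")
    if odds_ratio <= 0:
        raise SimulationSpecError("odds_ratio must be > 0")
    rng = _rng(seed, "deg")
    universe = [f"GENE{i + 1:06d}" for i in range(universe_size)]
    if isinstance(targets, int):
        if targets > universe_size:
            raise SimulationSpecError("more targets than universe genes")
        target_ids = frozenset(universe[:targets])
    else:
        target_ids = frozenset(g.upper() for g in targets)
        if not target_ids <= set(universe):
            raise SimulationSpecError("explicit targets must be drawn from the universe")
    k = len(target_ids)
    a = int(nchypergeom_fisher.rvs(universe_size, k, n_deg, odds_ratio, random_state=rng))
    tlist = sorted(target_ids)
    rest = [g for g in universe if g not in target_ids]
    deg_genes = set(rng.choice(tlist, size=a, replace=False)) | set(
        rng.choice(rest, size=n_deg - a, replace=False)
    )
    return (
        DEGSet(contrast_id, frozenset(deg_genes), frozenset(universe)),
        target_ids,
    )


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------


def write_network_tables(sim: SimulatedNetwork, outdir: str | Path) -> dict[str, Path]:
    """Emit the TSV inputs the reading side of the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    edges = sorted(sim.network.edges)
    paths["edges"] = outdir / "edges.tsv"
    pd.DataFrame(edges, columns=["tf_id", "promoter_id"]).to_csv(
        paths["edges"], sep="\t", index=False
    )

    rows = [
        {"promoter_id": g, "pathway": pw}
        for g in sorted(sim.pathway_table)
        for pw in sorted(sim.pathway_table[g])
    ]
    paths["pathways"] = outdir / "pathways.tsv"
    pd.DataFrame(rows, columns=["promoter_id", "pathway"]).to_csv(
        paths["pathways"], sep="\t", index=False
    )

    paths["families"] = outdir / "families.tsv"
    pd.DataFrame(
        sorted(sim.family_table.items()), columns=["tf_id", "family"]
    ).to_csv(paths["families"], sep="\t", index=False)

    paths["localization"] = outdir / "localization.tsv"
    sim.localization_table.to_csv(paths["localization"], sep="\t", index=False)
    return paths


def write_expression(datasets: list[ExpressionDataset], outdir: str | Path) -> Path:
    """One TSV per compendium plus a YAML manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for ds in datasets:
        fname = f"expression_{ds.name}.tsv"
        ds.values.rename_axis("gene_id").to_csv(outdir / fname, sep="\t", float_format="%.6f")
        manifest[ds.name] = fname
    manifest_path = outdir / "expression_manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path


def write_deg_set(deg: DEGSet, targets: frozenset[str], outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    rows = [
        {"gene_id": g, "direction": "up", "significant": g in deg.genes}
        for g in sorted(deg.universe)
    ]
    paths["deg"] = outdir / f"deg_{deg.contrast_id}.tsv"
    pd.DataFrame(rows).to_csv(paths["deg"], sep="\t", index=False)
    paths["universe"] = outdir / "deg_universe.txt"
    paths["universe"].write_text("\n".join(sorted(deg.universe)) + "\n")
    paths["targets"] = outdir / "deg_targets.txt"
    paths["targets"].write_text("\n".join(sorted(targets)) + "\n")
    return paths
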