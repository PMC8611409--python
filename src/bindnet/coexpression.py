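"""Per-edge co-expression across expression compendia and conditionality calls.

For each TF-target edge of a (sub)network, the Pearson correlation of the two
genes' expression profiles is computed separately in each compendium (a
genes x samples matrix; e.g. development, root, pollen, osmotic- and
salt-stress atlases).  An edge is "supported" in a compendium when |r| meets
the threshold (default 0.8); the pattern of supporting compendia classifies
the edge as universal, conditional, or exclusive to a single dataset —
the Venn-style partition used to quantify conditional regulation.

Missing values (gene absent from a compendium, or a zero-variance profile)
are flagged as NaN and always count as not-passing; they are never imputed.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .network import NetworkFormatError, RegulatoryNetwork, _norm

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.8


@dataclass
class ExpressionDataset:
    """A named gene x sample matrix of normalized expression values."""

    name: str
    values: pd.DataFrame  # index: gene ids (uppercase), columns: samples

    def __post_init__(self) -> None:
        if self.values.shape[1] < 3:
            raise ValueError(f"dataset {self.name!r}: need >= 3 samples for correlation")
        self.values = self.values.copy()
        self.values.index = [_norm(g) for g in self.values.index]
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise ValueError(f"dataset {self.name!r}: duplicate gene rows {dups}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EdgeCorrelationProfile:
    tf_id: str
    target_id: str
    r_by_dataset: dict[str, float]  # NaN flags a missing/undefined correlation
    n_samples_by_dataset: dict[str, int]


@dataclass(frozen=True)
class ConditionalityPartition:
    threshold: float
    per_edge: dict[tuple[str, str], frozenset[str]]
    venn_counts: dict[frozenset[str], int]

    @property
    def n_pass_any(self) -> int:
        return sum(1 for s in self.per_edge.values() if s)

    def n_in_exactly(self, k: int) -> int:
        return sum(1 for s in self.per_edge.values() if len(s) == k)

    @property
    def n_exclusive(self) -> int:
        return self.n_in_exactly(1)

    def summary(self) -> dict[str, int]:
        return {
            "n_edges": len(self.per_edge),
            "n_pass_any": self.n_pass_any,
            "n_exclusive_one": self.n_exclusive,
            "n_in_two": self.n_in_exactly(2),
        }


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation; NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = math.sqrt(float(dx @ dx) * float(dy @ dy))
    if denom == 0:
        return math.nan
    return float(np.clip((dx @ dy) / denom, -1.0, 1.0))


def edge_correlations(
    network: RegulatoryNetwork, datasets: Sequence[ExpressionDataset]
) -> list[EdgeCorrelationProfile]:
    """One correlation profile per network edge, per dataset.

    An edge's r in a dataset is NaN when either gene is absent or has a
    zero-variance profile there.  Computed-vs-missing counts are logged.
    """
    if not datasets:
        raise ValueError("need at least one expression dataset")
    edges = sorted(network.edges)
    r_cols: dict[str, np.ndarray] = {}
    for ds in datasets:
        mat = ds.values.to_numpy(dtype=float)
        mean = mat.mean(axis=1, keepdims=True)
        centered = mat - mean
        norms = np.sqrt((centered**2).sum(axis=1))
        idx = {g: i for i, g in enumerate(ds.values.index)}
        rs = np.full(len(edges), np.nan)
        for e, (t, g) in enumerate(edges):
            it, ig = idx.get(t), idx.get(g)
            if it is None or ig is None or norms[it] == 0 or norms[ig] == 0:
                continue
            rs[e] = np.clip(centered[it] @ centered[ig] / (norms[it] * norms[ig]), -1.0, 1.0)
        r_cols[ds.name] = rs
        logger.info(
            "dataset %s: %d/%d edge correlations computed", ds.name,
            int(np.isfinite(rs).sum()), len(edges),
        )
    return [
        EdgeCorrelationProfile(
            tf_id=t,
            target_id=g,
            r_by_dataset={ds.name: float(r_cols[ds.name][e]) for ds in datasets},
            n_samples_by_dataset={ds.name: ds.n_samples for ds in datasets},
        )
        for e, (t, g) in enumerate(edges)
    ]


def classify_conditionality(
    profiles: Iterable[EdgeCorrelationProfile], threshold: float = DEFAULT_THRESHOLD
) -> ConditionalityPartition:
    """Partition edges by the exact set of datasets where |r| >= threshold."""
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1]: {threshold}")
    per_edge: dict[tuple[str, str], frozenset[str]] = {}
    for prof in profiles:
        passing = frozenset(
            name for name, r in prof.r_by_dataset.items()
            if not math.isnan(r) and abs(r) >= threshold
        )
        per_edge[(prof.tf_id, prof.target_id)] = passing
    venn = Counter(s for s in per_edge.values() if s)
    return ConditionalityPartition(threshold, per_edge, dict(venn))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path, name: str) -> ExpressionDataset:
    """TSV with a leading ``gene_id`` column and one column per sample."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise NetworkFormatError(f"{path}: first column must be gene_id")
    df = df.set_index("gene_id")
    return ExpressionDataset(name, df)


def read_manifest(path: str | Path) -> list[ExpressionDataset]:
    """YAML manifest mapping dataset name -> expression TSV path (relative ok)."""
    path = Path(path)
    spec = yaml.safe_load(path.read_text())
    if not isinstance(spec, dict) or not spec:
        raise NetworkFormatError(f"{path}: manifest must map dataset names to files")
    return [
        read_expression_matrix((path.parent / f) if not Path(f).is_absolute() else f, name)
        for name, f in spec.items()
    ]


def profiles_to_dataframe(
    profiles: list[EdgeCorrelationProfile], partition: ConditionalityPartition | None = None
) -> pd.DataFrame:
    names = list(profiles[0].r_by_dataset) if profiles else []
    rows = []
    for p in profiles:
        row = {"tf_id": p.tf_id, "target_id": p.target_id}
        row.update({f"r_{n}": p.r_by_dataset[n] for n in names})
        if partition is not None:
            row["pass_set"] = "|".join(sorted(partition.per_edge[(p.tf_id, p.target_id)]))
        rows.append(row)
    return pd.DataFrame(rows)


def venn_to_dataframe(partition: ConditionalityPartition) -> pd.DataFrame:
    rows = [
        {"dataset_set": "|".join(sorted(s)), "n_datasets": len(s), "n_edges": c}
        for s, c in sorted(partition.venn_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    ]
    return pd.DataFrame(rows, columns=["dataset_set", "n_datasets", "n_edges"])
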