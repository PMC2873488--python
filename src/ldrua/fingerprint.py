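"""Fingerprints: binary profiles, relative IF contributions and clustering.

A sample's fingerprint is its presence/absence vector over the probe set.
Fingerprints are compared across samples by hierarchical clustering with
Euclidean distance and Ward's agglomeration (the classical squared-Euclidean
Ward criterion; merge heights follow the scipy convention).  Relative IF
contributions — each probe's share of total intensity with sub-probes
excluded — approximate the relative abundance of the target groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform


class SchemaError(ValueError):
    """Profiles of mismatched length or probes missing an annotation."""


def binary_fingerprint(calls: pd.DataFrame, probe_order: Sequence[str] | None = None) -> pd.Series:
    """Presence/absence vector (0/1) of one call table, in fixed probe order."""
    if probe_order is None:
        probe_order = list(calls["probe_id"])
    by_probe = calls.set_index("probe_id")["present"]
    missing = [p for p in probe_order if p not in by_probe.index]
    if missing:
        raise SchemaError(f"calls missing probes: {missing}")
    return by_probe.reindex(probe_order).astype(int)


def relative_contributions(
    call_tables: Sequence[pd.DataFrame],
    annotation: pd.DataFrame,
) -> pd.Series:
    """Percent of total mean IF per probe, sub-probes excluded.

    ``call_tables`` holds one or two technical-replicate call tables for the
    same sample; per-probe mean IFs are averaged arithmetically across the
    replicates before normalization.
    """
    if not 1 <= len(call_tables) <= 2:
        raise ValueError("expected 1 or 2 replicate call tables")
    means = [t.set_index("probe_id")["mean_if"] for t in call_tables]
    avg = pd.concat(means, axis=1).mean(axis=1)
    unknown = [p for p in avg.index if p not in annotation.index]
    if unknown:
        raise SchemaError(f"probes without annotation: {unknown}")
    included = avg[~annotation.loc[avg.index, "sub_probe"].to_numpy(bool)]
    total = included.sum()
    if total <= 0:
        raise ValueError("degenerate sample: total IF is zero")
    return 100.0 * included / total


@dataclass
class FingerprintClustering:
    """Ward/Euclidean agglomeration of sample profiles."""

    linkage: np.ndarray
    sample_ids: list[str]
    leaf_order: list[str]
    newick: str
    variant: str = "ward-on-squared-euclidean (scipy heights on the euclidean scale)"


def _to_newick(node: hierarchy.ClusterNode, labels: Sequence[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_fingerprints(
    profiles: pd.DataFrame | Sequence[pd.Series],
) -> FingerprintClustering:
    """Hierarchical clustering of fingerprints (rows = samples).

    Euclidean metric, Ward linkage, deterministic tie-breaking by input
    sample order (scipy's ordered agglomeration on the condensed distance
    matrix).  Exports the tree in newick form and the dendrogram leaf order.
    """
    if not isinstance(profiles, pd.DataFrame):
        profiles = pd.DataFrame({s.name if s.name else i: s for i, s in enumerate(profiles)}).T
    if len(profiles) < 2:
        raise SchemaError("need at least two profiles")
    if profiles.isna().any().any():
        raise SchemaError("profiles have mismatched probe sets")
    X = profiles.to_numpy(dtype=float)
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    sample_ids = [str(s) for s in profiles.index]
    order = [sample_ids[i] for i in hierarchy.leaves_list(Z)]
    tree = hierarchy.to_tree(Z)
    newick = _to_newick(tree, sample_ids) + ";"
    return FingerprintClustering(
        linkage=Z, sample_ids=sample_ids, leaf_order=order, newick=newick
    )


def distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Euclidean distance matrix between sample profiles."""
    d = squareform(pdist(profiles.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def replicate_reproducibility(a: pd.Series | Sequence[int], b: pd.Series | Sequence[int]) -> float:
    """Percent of probes giving the same presence/absence response in both replicates."""
    x = np.asarray(a, dtype=int)
    y = np.asarray(b, dtype=int)
    if x.shape != y.shape:
        raise SchemaError(f"profile lengths differ: {x.shape} vs {y.shape}")
    return 100.0 * float((x == y).mean())


def group_contribution_summary(
    contributions: pd.Series,
    annotation: pd.DataFrame | Mapping[str, tuple[str, str]],
) -> dict[str, float]:
    """Total contribution percent per ecological grouping.

    Sums the per-probe contributions over the major-mutualist, minor-mutualist
    and opportunistic groupings; the three sums total 100%.
    """
    if isinstance(annotation, pd.DataFrame):
        grouping = annotation["grouping"]
    else:
        grouping = pd.Series({p: g for p, (_, g) in annotation.items()})
    missing = [p for p in contributions.index if p not in grouping.index]
    if missing:
        raise SchemaError(f"probes without ecological grouping: {missing}")
    sums = contributions.groupby(grouping.reindex(contributions.index)).sum()
    return {
        "major": float(sums.get("major", 0.0)),
        "minor": float(sums.get("minor", 0.0)),
        "opportunistic": float(sums.get("opportunistic", 0.0)),
    }
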