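"""Polar classification of environmental unigenes and ribotype assignment.

A unigene's biogeography is summarised by the shares ``a`` and ``s`` of its
summed relative abundance falling in arctic (>60N) and antarctic (<-55S,
south of the Polar Front) stations:

* Arctic      : a > 0.70
* Antarctic   : s > 0.70
* Bipolar     : a + s > 0.70 with a > 0.20 and s > 0.20
* Other       : everything else

All thresholds are strict, mirroring the ">70%"/">20%" wording of the
classification rules, and the single-pole labels take precedence over
Bipolar so the rare boundary case (e.g., a = 0.71, s = 0.21) resolves
deterministically to the single pole.  An alternative bipolar rule
(>35% at each pole) is selectable.

Ribotypes — environmental rRNA amplicons — are assigned to a cultured query
strain when they are at least 97% identical to it (inclusive) *and* sit
closer to the query in the reference tree than the nearest cultured
non-Arctic reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_formats import node_label

logger = logging.getLogger("polarconverge")

UNIGENE_CLASSES = ("Arctic", "Antarctic", "Bipolar", "Other")


# ---------------------------------------------------------------------------
# Unigene classification
# ---------------------------------------------------------------------------


def polar_shares(
    row: pd.Series, stations: pd.DataFrame
) -> tuple[float, float]:
    """Arctic and antarctic shares of a unigene's summed relative abundance."""
    values = row.reindex(stations["station_id"])
    if values.isna().any():
        missing = list(stations.loc[values.isna().to_numpy(), "station_id"][:5])
        raise ValueError(f"unigene row missing station(s): {missing}")
    total = float(values.sum())
    if total <= 0:
        raise ValueError("unigene has zero total abundance")
    region = stations["region"].to_numpy()
    a = float(values.to_numpy()[region == "arctic"].sum()) / total
    s = float(values.to_numpy()[region == "antarctic"].sum()) / total
    return a, s


def classify_shares(a: float, s: float, bipolar_rule: str = "methods") -> str:
    """Classify from the (arctic, antarctic) share pair.

    ``bipolar_rule="methods"`` uses >70% combined with >20% at each pole;
    ``"fig4"`` uses the >35%-at-each-pole variant.
    """
    if not (0 <= a <= 1 and 0 <= s <= 1 and a + s <= 1 + 1e-9):
        raise ValueError(f"invalid share pair a={a}, s={s}")
    if a > 0.70:
        return "Arctic"
    if s > 0.70:
        return "Antarctic"
    if bipolar_rule == "methods":
        if a + s > 0.70 and a > 0.20 and s > 0.20:
            return "Bipolar"
    elif bipolar_rule == "fig4":
        if a > 0.35 and s > 0.35:
            return "Bipolar"
    else:
        raise ValueError(f"unknown bipolar_rule {bipolar_rule!r}")
    return "Other"


def classify_unigene(
    row: pd.Series, stations: pd.DataFrame, bipolar_rule: str = "methods"
) -> str:
    """One of Arctic / Antarctic / Bipolar / Other for a positive-total row."""
    a, s = polar_shares(row, stations)
    return classify_shares(a, s, bipolar_rule=bipolar_rule)


def classify_all(
    abundance: pd.DataFrame, stations: pd.DataFrame, bipolar_rule: str = "methods"
) -> pd.Series:
    """Classify every unigene in the matrix; returns a Series of class labels."""
    return pd.Series(
        {
            uid: classify_unigene(abundance.loc[uid], stations, bipolar_rule)
            for uid in abundance.index
        },
        name="polar_class",
    )


def clade_station_profile(
    clade_of: Mapping[str, str],
    abundance: pd.DataFrame,
    stations: pd.DataFrame,
    depth_layers: Sequence[str] = ("SRF", "DCM"),
) -> dict[str, pd.DataFrame]:
    """Clade x station summed relative abundances, one table per depth layer.

    Unigenes without a clade assignment are ignored; a clade with no member
    unigenes yields an all-zero row.
    """
    clades = sorted(set(clade_of.values()))
    member_rows = {
        clade: [u for u, c in clade_of.items() if c == clade and u in abundance.index]
        for clade in clades
    }
    out = {}
    for layer in depth_layers:
        cols = stations.loc[stations["depth_layer"] == layer, "station_id"]
        table = pd.DataFrame(
            {
                clade: abundance.loc[members, cols].sum(axis=0)
                if members
                else pd.Series(0.0, index=cols)
                for clade, members in member_rows.items()
            }
        ).T
        table.index.name = "clade"
        out[layer] = table
    return out


# ---------------------------------------------------------------------------
# Ribotype assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RibotypeCandidate:
    ribotype_id: str
    pct_identity_to_query: float
    tree_distance_to_query: float
    tree_distance_to_nearest_nonarctic_ref: float
    accepted: bool


def leaf_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """All-pairs leaf distances: patristic when branch lengths exist, else edge counts."""
    labels = [node_label(l) for l in tree.leaf_node_iter()]
    lengths = [
        n.edge.length
        for n in tree.preorder_node_iter()
        if n is not tree.seed_node
    ]
    use_topological = any(l is None for l in lengths)
    if use_topological:
        logger.warning("tree lacks branch lengths; using topological distances")

    index = {label: i for i, label in enumerate(labels)}
    n = len(labels)
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        step = 1.0 if use_topological else float(node.edge.length)
        depth[id(node)] = depth[id(node.parent_node)] + step
    # distance(i, j) = depth_i + depth_j - 2 * depth(MRCA)
    leaf_depth = np.zeros(n)
    for leaf in tree.leaf_node_iter():
        leaf_depth[index[node_label(leaf)]] = depth[id(leaf)]
    mrca_depth = np.zeros((n, n))
    leaf_sets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leaf_sets[id(node)] = [index[node_label(node)]]
        else:
            children = [leaf_sets[id(c)] for c in node.child_nodes()]
            d = depth[id(node)]
            for ci in range(len(children)):
                for cj in range(ci + 1, len(children)):
                    for i in children[ci]:
                        for j in children[cj]:
                            mrca_depth[i, j] = mrca_depth[j, i] = d
            leaf_sets[id(node)] = [i for s in children for i in s]
    dist = leaf_depth[:, None] + leaf_depth[None, :] - 2 * mrca_depth
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=labels, columns=labels)


def assign_ribotypes(
    candidates: Sequence[str],
    identities: Mapping[str, float],
    tree: dendropy.Tree,
    query_id: str,
    reference_habitats: Mapping[str, str],
    min_identity: float = 97.0,
) -> list[RibotypeCandidate]:
    """Accept ribotypes by identity threshold + phylogenetic placement.

    ``reference_habitats`` maps cultured reference leaf ids to habitat
    labels; the comparison set is its non-Arctic members.  Acceptance
    requires pct identity >= ``min_identity`` (inclusive) and a smaller tree
    distance to the query than to the nearest non-Arctic reference.
    """
    dist = leaf_distances(tree)
    if query_id not in dist.index:
        raise ValueError(f"query {query_id!r} absent from tree")
    nonarctic = [
        r for r, h in reference_habitats.items() if h != "Arctic" and r in dist.index
    ]
    if not nonarctic:
        raise ValueError("need at least one non-Arctic cultured reference in the tree")
    results = []
    for rib in candidates:
        if rib not in dist.index:
            raise ValueError(f"candidate {rib!r} absent from tree")
        d_query = float(dist.loc[rib, query_id])
        d_ref = float(dist.loc[rib, nonarctic].min())
        identity = float(identities[rib])
        results.append(
            RibotypeCandidate(
                ribotype_id=rib,
                pct_identity_to_query=identity,
                tree_distance_to_query=d_query,
                tree_distance_to_nearest_nonarctic_ref=d_ref,
                accepted=identity >= min_identity and d_query < d_ref,
            )
        )
    return results


def ribotype_abundance_summary(
    accepted: set[str], samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample proportions of accepted-ribotype reads, plus grouped totals.

    ``samples`` columns: sample_id, ribotype_id, reads, total_reads,
    depth_layer, size_fraction; ``total_reads`` is the total marker-gene
    read count of the sample.  Returns (per-sample table with ``proportion``
    = accepted reads / total reads, totals grouped by depth layer and size
    fraction).
    """
    required = {"sample_id", "ribotype_id", "reads", "total_reads"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing column(s) {sorted(missing)}")
    acc = samples[samples["ribotype_id"].isin(accepted)]
    per_sample = (
        samples.groupby("sample_id")
        .agg(total_reads=("total_reads", "first"))
        .join(acc.groupby("sample_id")["reads"].sum().rename("accepted_reads"))
        .fillna({"accepted_reads": 0})
    )
    if (per_sample["total_reads"] <= 0).any():
        raise ValueError("total_reads must be positive for every sample")
    per_sample["proportion"] = per_sample["accepted_reads"] / per_sample["total_reads"]
    group_cols = [
        c for c in ("depth_layer", "size_fraction") if c in samples.columns
    ]
    if group_cols:
        totals = (
            acc.groupby(group_cols)["reads"].sum().rename("accepted_reads").reset_index()
        )
    else:
        totals = pd.DataFrame({"accepted_reads": [acc["reads"].sum()]})
    return per_sample, totals
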