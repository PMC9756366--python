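"""Arctic association scoring per PFAM family.

Two independent signals are combined per family:

* **presence enrichment** — a two-tailed Pearson chi-squared (no continuity
  correction) on the 2x2 table of strains carrying / not carrying the family,
  Arctic vs non-Arctic (Antarctic and Other pooled), over marine
  photosynthetic strains;
* **expansion / contraction enrichment** — copy-number changes along the
  species tree (from a CAFE-style change table, or from the built-in Wagner
  linear-cost parsimony), with expansions (signed change > 0) and
  contractions (< 0) each tested by the same chi-squared recipe on terminal
  branches, Arctic vs non-Arctic.

The scatter coordinates per family are x = sign * (-log10 p_presence) and
y = (-log10 p_expansion) - (-log10 p_contraction); a family is called
arctic-associated when it passes the candidate filter (present in at least
one Arctic genome and one Arctic transcriptome) with p_presence < 1e-5 and
positive sign, arctic-expanded when y > 5 and arctic-contracted when y < -5.
p-values are floored at 1e-300 before taking logs.

Enrichment counting is restricted to terminal branches because habitat
labels exist only for tips; internal-branch events are reported separately.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import StrainRecord, node_label

logger = logging.getLogger("polarconverge")

P_FLOOR = 1e-300
PRESENCE_P_CUTOFF = 1e-5
COMPOSITE_Y_CUTOFF = 5.0


# ---------------------------------------------------------------------------
# 2x2 Pearson chi-squared
# ---------------------------------------------------------------------------


def chi2_2x2(
    k1: int, n1: int, k2: int, n2: int, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared for the 2x2 table [[k1, n1-k1], [k2, n2-k2]].

    No Yates continuity correction by default (selectable).  A zero margin
    (no positives anywhere, positives everywhere, or an empty group) leaves
    the statistic undefined: returns (0, 1).
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n in both groups")
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if correction:
        diff = max(diff - n / 2.0, 0.0)
    chi2 = n * diff**2 / (r1 * r2 * c1 * c2)
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def _chi2_arrays(
    k1: np.ndarray, n1: int, k2: np.ndarray, n2: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised uncorrected chi-squared over many 2x2 tables."""
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    n = n1 + n2
    c1 = a + c
    c2 = b + d
    valid = (n1 > 0) & (n2 > 0) & (c1 > 0) & (c2 > 0)
    chi2 = np.zeros(len(np.atleast_1d(a)), dtype=float)
    np.divide(
        n * (a * d - b * c).astype(float) ** 2,
        (float(n1) * n2 * c1 * c2),
        out=chi2,
        where=valid,
    )
    p = np.where(valid, stats.chi2.sf(chi2, 1), 1.0)
    return chi2, p


# ---------------------------------------------------------------------------
# Presence enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PresenceTest:
    pfam: str
    k_arctic: int
    n_arctic: int
    k_other: int
    n_other: int
    ratio: float | None  # (k_a/n_a) / (k_o/n_o); None when undefined
    chi2: float
    p: float
    sign: int  # +1 Arctic-enriched, -1 depleted, 0 equal frequencies
    degenerate: bool = False  # a zero table margin


def _eligible(strains: Sequence[StrainRecord]) -> list[StrainRecord]:
    return [s for s in strains if s.water == "marine" and s.photosynthetic]


def presence_test(
    matrix: pd.DataFrame,
    strains: Sequence[StrainRecord],
    pfam: str,
    correction: bool = False,
) -> PresenceTest:
    """Arctic vs non-Arctic presence chi-squared for one family."""
    eligible = _eligible(strains)
    arctic = [s.strain_id for s in eligible if s.habitat == "Arctic"]
    other = [s.strain_id for s in eligible if s.habitat != "Arctic"]
    if not arctic or not other:
        raise ValueError("need at least one Arctic and one non-Arctic eligible strain")
    col = matrix[pfam]
    k_a = int((col.loc[arctic] > 0).sum())
    k_o = int((col.loc[other] > 0).sum())
    chi2, p = chi2_2x2(k_a, len(arctic), k_o, len(other), correction=correction)
    f_a, f_o = k_a / len(arctic), k_o / len(other)
    degenerate = (k_a + k_o == 0) or (k_a == len(arctic) and k_o == len(other))
    ratio = (f_a / f_o) if (f_o > 0 and not degenerate) else None
    sign = 0 if f_a == f_o else (1 if f_a > f_o else -1)
    return PresenceTest(
        pfam=pfam,
        k_arctic=k_a,
        n_arctic=len(arctic),
        k_other=k_o,
        n_other=len(other),
        ratio=ratio,
        chi2=chi2,
        p=p,
        sign=sign,
        degenerate=degenerate,
    )


def presence_tests(matrix: pd.DataFrame, strains: Sequence[StrainRecord]) -> pd.DataFrame:
    """Vectorised presence chi-squared for every family in the matrix."""
    eligible = _eligible(strains)
    arctic = [s.strain_id for s in eligible if s.habitat == "Arctic"]
    other = [s.strain_id for s in eligible if s.habitat != "Arctic"]
    if not arctic or not other:
        raise ValueError("need at least one Arctic and one non-Arctic eligible strain")
    k_a = (matrix.loc[arctic] > 0).sum(axis=0).to_numpy()
    k_o = (matrix.loc[other] > 0).sum(axis=0).to_numpy()
    chi2, p = _chi2_arrays(k_a, len(arctic), k_o, len(other))
    f_a = k_a / len(arctic)
    f_o = k_o / len(other)
    return pd.DataFrame(
        {
            "k_arctic": k_a,
            "n_arctic": len(arctic),
            "k_other": k_o,
            "n_other": len(other),
            "chi2": chi2,
            "p": p,
            "sign": np.sign(f_a - f_o).astype(int),
        },
        index=matrix.columns,
    )


def candidate_filter(
    pfam: str,
    genome_matrix: pd.DataFrame,
    transcriptome_matrix: pd.DataFrame,
    strains: Sequence[StrainRecord],
) -> bool:
    """True iff the family occurs in >=1 Arctic genome and >=1 Arctic transcriptome."""
    return bool(
        candidate_mask(genome_matrix, transcriptome_matrix, strains).get(pfam, False)
    )


def candidate_mask(
    genome_matrix: pd.DataFrame,
    transcriptome_matrix: pd.DataFrame,
    strains: Sequence[StrainRecord],
) -> pd.Series:
    """Candidate filter over the union of families of both matrices."""
    arctic_g = [
        s.strain_id
        for s in strains
        if s.habitat == "Arctic" and s.library_type == "genome"
        and s.strain_id in genome_matrix.index
    ]
    arctic_t = [
        s.strain_id
        for s in strains
        if s.habitat == "Arctic" and s.library_type == "transcriptome"
        and s.strain_id in transcriptome_matrix.index
    ]
    families = genome_matrix.columns.union(transcriptome_matrix.columns)
    in_g = (
        (genome_matrix.reindex(columns=families, fill_value=0).loc[arctic_g] > 0)
        .any(axis=0)
        if arctic_g
        else pd.Series(False, index=families)
    )
    in_t = (
        (transcriptome_matrix.reindex(columns=families, fill_value=0).loc[arctic_t] > 0)
        .any(axis=0)
        if arctic_t
        else pd.Series(False, index=families)
    )
    return in_g & in_t


# ---------------------------------------------------------------------------
# High-frequency family decomposition
# ---------------------------------------------------------------------------


def high_frequency_pfams(matrix: pd.DataFrame, threshold: int = 100) -> set[str]:
    """Families whose per-strain count range (max - min) exceeds the threshold.

    Such families (the default range is > 100 copies across the dataset) are
    too heterogeneous for family-level change calling and are decomposed
    into orthogroups first.
    """
    spread = matrix.max(axis=0) - matrix.min(axis=0)
    return set(matrix.columns[spread > threshold])


@dataclass(frozen=True)
class Orthogroup:
    orthogroup_id: str
    members: tuple[tuple[str, str], ...]  # (strain_id, gene_id)
    frequencies: Mapping[str, int]  # per-strain member counts (zero-filled)
    pfam_presence: bool  # >=10% of member proteins carry the focal PFAM


def decompose(
    proteins: pd.DataFrame,
    clusterer: pd.DataFrame | Callable[[pd.DataFrame], pd.DataFrame],
    strain_ids: Sequence[str],
    presence_threshold: float = 0.10,
    range_threshold: int = 2,
) -> list[Orthogroup]:
    """Split the proteins of a high-frequency family into orthogroups.

    ``proteins`` has columns (strain_id, gene_id, has_pfam); the clusterer is
    pluggable — either a precomputed table (strain_id, gene_id,
    orthogroup_id) e.g. from OrthoFinder, or a callable returning one (the
    built-in stand-in is :func:`single_linkage_orthogroups`).  Orthogroups
    whose per-strain frequency range is <= ``range_threshold`` are dropped as
    uninformative, and family presence is called per orthogroup when at
    least ``presence_threshold`` of its member proteins carry the domain.
    """
    assignment = clusterer(proteins) if callable(clusterer) else clusterer
    keys = {"strain_id", "gene_id", "orthogroup_id"}
    if not keys.issubset(assignment.columns):
        raise ValueError(f"clusterer output needs columns {sorted(keys)}")
    known = set(zip(proteins["strain_id"], proteins["gene_id"]))
    referenced = set(zip(assignment["strain_id"], assignment["gene_id"]))
    unknown = sorted(referenced - known)
    if unknown:
        raise ValueError(f"clusterer references unknown genes: {unknown[:5]}")

    merged = assignment.merge(proteins, on=["strain_id", "gene_id"], how="left")
    groups = []
    for og_id, members in merged.groupby("orthogroup_id", sort=True):
        freqs = (
            members.groupby("strain_id").size().reindex(strain_ids, fill_value=0)
        )
        if freqs.max() - freqs.min() <= range_threshold:
            continue
        carrying = float(members["has_pfam"].astype(bool).mean())
        groups.append(
            Orthogroup(
                orthogroup_id=str(og_id),
                members=tuple(zip(members["strain_id"], members["gene_id"])),
                frequencies=freqs.to_dict(),
                pfam_presence=carrying >= presence_threshold,
            )
        )
    return groups


def single_linkage_orthogroups(
    alignment: Mapping[str, str], min_identity: float = 0.5
) -> pd.DataFrame:
    """Built-in orthogroup stand-in: connected components at >=50% identity.

    Sequence ids must be ``strain|gene``; identity is computed over mutually
    ungapped alignment columns.  Single-linkage: an edge between any two
    members joins their components.
    """
    from .hgt_screen import pairwise_identity

    ids = list(alignment)
    parent = {i: i for i in ids}

    def find(i: str) -> str:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in itertools.combinations(ids, 2):
        try:
            identity, _ = pairwise_identity(alignment[a], alignment[b])
        except ValueError:  # no mutually ungapped overlap: no edge
            continue
        if identity >= min_identity:
            parent[find(a)] = find(b)

    roots = sorted({find(i) for i in ids})
    og_index = {root: f"OG{k:04d}" for k, root in enumerate(roots)}
    rows = []
    for seq_id in ids:
        strain_id, _, gene_id = seq_id.partition("|")
        if not gene_id:
            raise ValueError(f"sequence id {seq_id!r} is not 'strain|gene'")
        rows.append((strain_id, gene_id, og_index[find(seq_id)]))
    return pd.DataFrame(rows, columns=["strain_id", "gene_id", "orthogroup_id"])


# ---------------------------------------------------------------------------
# Wagner (Farris-interval) linear-cost parsimony
# ---------------------------------------------------------------------------


def wagner_changes(
    tree: dendropy.Tree,
    leaf_sizes: Mapping[str, int],
    family_id: str = "family",
) -> pd.DataFrame:
    """Per-branch signed copy-number changes under linear-cost parsimony.

    Bottom-up, each node gets a Farris state interval (for children intervals
    the optimal set is the median interval of the 2c sorted endpoints);
    top-down, the root takes its interval minimum and every child takes the
    interval point nearest its parent's state (clamping — with the tie rule
    nearest-to-parent, then smaller state).  The resulting total |change| is
    the parsimony minimum.  Branches are keyed by child-node label.
    """
    table = wagner_changes_matrix(
        tree, pd.DataFrame({family_id: pd.Series(leaf_sizes)})
    )
    return table


def wagner_changes_matrix(tree: dendropy.Tree, sizes: pd.DataFrame) -> pd.DataFrame:
    """Vectorised Wagner parsimony for many families at once.

    ``sizes`` is leaf x family (integers).  Returns a long table
    (family_id, branch_id, signed_change) containing only non-zero changes.
    """
    leaves = [node_label(l) for l in tree.leaf_node_iter()]
    missing = sorted(set(leaves) - set(sizes.index))
    if missing:
        raise ValueError(f"missing leaf sizes for: {missing}")
    values = sizes.loc[leaves].to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(values == np.round(values)):
            raise ValueError("family sizes must be integers")
        values = values.astype(np.int64)
    leaf_index = {label: i for i, label in enumerate(leaves)}

    lo: dict[int, np.ndarray] = {}
    hi: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            row = values[leaf_index[node_label(node)]]
            lo[id(node)] = row
            hi[id(node)] = row
        else:
            children = node.child_nodes()
            endpoints = np.sort(
                np.stack(
                    [lo[id(c)] for c in children] + [hi[id(c)] for c in children]
                ),
                axis=0,
            )
            c = len(children)
            lo[id(node)] = endpoints[c - 1]
            hi[id(node)] = endpoints[c]

    state: dict[int, np.ndarray] = {}
    rows = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            state[id(node)] = lo[id(node)]
            continue
        parent_state = state[id(node.parent_node)]
        s = np.clip(parent_state, lo[id(node)], hi[id(node)])
        state[id(node)] = s
        change = s - parent_state
        branch = node_label(node)
        nz = np.nonzero(change)[0]
        for j in nz:
            rows.append((sizes.columns[j], branch, int(change[j])))
    return pd.DataFrame(rows, columns=["family_id", "branch_id", "signed_change"])


# ---------------------------------------------------------------------------
# Expansion / contraction enrichment and the composite score
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChangeEnrichment:
    pfam: str
    exp_arctic: int
    exp_other: int
    con_arctic: int
    con_other: int
    n_arctic: int
    n_other: int
    p_exp: float
    p_con: float
    internal_expansions: int
    internal_contractions: int
    no_signal: bool  # no terminal events at all


@dataclass(frozen=True)
class AssociationScore:
    pfam: str
    x: float  # sign * -log10 p_presence
    y: float  # -log10 p_exp - (-log10 p_con)
    candidate: bool
    arctic_associated: bool
    arctic_expanded: bool
    arctic_contracted: bool
    no_signal: bool


def change_enrichment(
    change_table: pd.DataFrame,
    strains: Sequence[StrainRecord],
    pfam: str,
    correction: bool = False,
) -> ChangeEnrichment:
    """Arctic-vs-non-Arctic chi-squared on terminal expansions and contractions.

    Branches are identified by child-node label; terminal branches are those
    whose label is an eligible strain id.  A branch absent from the table
    counts as zero change.  Internal-branch events are tallied separately
    (habitat labels exist only for tips).
    """
    eligible = _eligible(strains)
    arctic = {s.strain_id for s in eligible if s.habitat == "Arctic"}
    other = {s.strain_id for s in eligible if s.habitat != "Arctic"}
    if not arctic or not other:
        raise ValueError("need at least one Arctic and one non-Arctic eligible strain")
    mine = change_table[change_table["family_id"] == pfam]
    terminal = mine[mine["branch_id"].isin(arctic | other)]
    internal = mine[~mine["branch_id"].isin(arctic | other)]

    exp_branches = set(terminal.loc[terminal["signed_change"] > 0, "branch_id"])
    con_branches = set(terminal.loc[terminal["signed_change"] < 0, "branch_id"])
    exp_a, exp_o = len(exp_branches & arctic), len(exp_branches & other)
    con_a, con_o = len(con_branches & arctic), len(con_branches & other)
    _, p_exp = chi2_2x2(exp_a, len(arctic), exp_o, len(other), correction=correction)
    _, p_con = chi2_2x2(con_a, len(arctic), con_o, len(other), correction=correction)
    return ChangeEnrichment(
        pfam=pfam,
        exp_arctic=exp_a,
        exp_other=exp_o,
        con_arctic=con_a,
        con_other=con_o,
        n_arctic=len(arctic),
        n_other=len(other),
        p_exp=p_exp,
        p_con=p_con,
        internal_expansions=int((internal["signed_change"] > 0).sum()),
        internal_contractions=int((internal["signed_change"] < 0).sum()),
        no_signal=not (exp_branches or con_branches),
    )


def composite(
    presence: PresenceTest,
    change: ChangeEnrichment,
    candidate: bool,
    p_cutoff: float = PRESENCE_P_CUTOFF,
    y_cutoff: float = COMPOSITE_Y_CUTOFF,
) -> AssociationScore:
    """Scatter coordinates and flags for one family."""
    x = presence.sign * -np.log10(max(presence.p, P_FLOOR))
    y = 0.0 if change.no_signal else float(
        -np.log10(max(change.p_exp, P_FLOOR)) + np.log10(max(change.p_con, P_FLOOR))
    )
    return AssociationScore(
        pfam=presence.pfam,
        x=float(x),
        y=y,
        candidate=candidate,
        arctic_associated=bool(candidate and presence.p < p_cutoff and presence.sign > 0),
        arctic_expanded=bool(y > y_cutoff),
        arctic_contracted=bool(y < -y_cutoff),
        no_signal=change.no_signal,
    )


def association_scores(
    genome_matrix: pd.DataFrame,
    transcriptome_matrix: pd.DataFrame,
    strains: Sequence[StrainRecord],
    tree: dendropy.Tree | None = None,
    changes: pd.DataFrame | None = None,
    p_cutoff: float = PRESENCE_P_CUTOFF,
    y_cutoff: float = COMPOSITE_Y_CUTOFF,
    correction: bool = False,
) -> pd.DataFrame:
    """Full per-family association table (the scatter-plot table).

    Presence tests pool all eligible libraries across both matrices;
    candidate status needs the family in Arctic libraries of both types.
    Copy-number changes come from the supplied CAFE-style table or, when a
    tree is given instead, from the internal Wagner parsimony on the
    combined matrix.  A Benjamini-Hochberg column over the presence p-values
    is appended for the user; the association flag itself uses the raw
    ``p_cutoff``.
    """
    if (changes is None) == (tree is None):
        raise ValueError("supply exactly one of `changes` or `tree`")
    families = genome_matrix.columns.union(transcriptome_matrix.columns)
    combined = pd.concat(
        [
            genome_matrix.reindex(columns=families, fill_value=0),
            transcriptome_matrix.reindex(columns=families, fill_value=0),
        ]
    )
    if combined.index.duplicated().any():
        raise ValueError("genome and transcriptome matrices share strain ids")

    ptests = presence_tests(combined, strains)
    cand = candidate_mask(genome_matrix, transcriptome_matrix, strains)
    if changes is None:
        changes = wagner_changes_matrix(tree, combined)

    eligible = _eligible(strains)
    arctic = {s.strain_id for s in eligible if s.habitat == "Arctic"}
    other = {s.strain_id for s in eligible if s.habitat != "Arctic"}
    terminal = changes[changes["branch_id"].isin(arctic | other)]
    pos = terminal[terminal["signed_change"] > 0]
    neg = terminal[terminal["signed_change"] < 0]
    exp_a = pos[pos["branch_id"].isin(arctic)].groupby("family_id").size()
    exp_o = pos[pos["branch_id"].isin(other)].groupby("family_id").size()
    con_a = neg[neg["branch_id"].isin(arctic)].groupby("family_id").size()
    con_o = neg[neg["branch_id"].isin(other)].groupby("family_id").size()

    def counts(series: pd.Series) -> np.ndarray:
        return series.reindex(families, fill_value=0).to_numpy()

    ea, eo, ca, co = counts(exp_a), counts(exp_o), counts(con_a), counts(con_o)
    if correction:
        p_exp = np.array(
            [chi2_2x2(a, len(arctic), o, len(other), True)[1] for a, o in zip(ea, eo)]
        )
        p_con = np.array(
            [chi2_2x2(a, len(arctic), o, len(other), True)[1] for a, o in zip(ca, co)]
        )
    else:
        _, p_exp = _chi2_arrays(ea, len(arctic), eo, len(other))
        _, p_con = _chi2_arrays(ca, len(arctic), co, len(other))
    no_signal = (ea + eo + ca + co) == 0

    p_presence = ptests["p"].to_numpy()
    sign = ptests["sign"].to_numpy()
    x = sign * -np.log10(np.maximum(p_presence, P_FLOOR))
    y = np.where(
        no_signal,
        0.0,
        -np.log10(np.maximum(p_exp, P_FLOOR)) + np.log10(np.maximum(p_con, P_FLOOR)),
    )
    candidate = cand.reindex(families, fill_value=False).to_numpy()
    table = pd.DataFrame(
        {
            "k_arctic": ptests["k_arctic"],
            "n_arctic": ptests["n_arctic"],
            "k_other": ptests["k_other"],
            "n_other": ptests["n_other"],
            "p_presence": p_presence,
            "sign": sign,
            "exp_arctic": ea,
            "exp_other": eo,
            "con_arctic": ca,
            "con_other": co,
            "p_expansion": p_exp,
            "p_contraction": p_con,
            "x": x,
            "y": y,
            "candidate": candidate,
            "arctic_associated": candidate & (p_presence < p_cutoff) & (sign > 0),
            "arctic_expanded": y > y_cutoff,
            "arctic_contracted": y < -y_cutoff,
            "no_signal": no_signal,
            "p_presence_bh": stats.false_discovery_control(
                np.clip(p_presence, P_FLOOR, 1.0), method="bh"
            ),
        },
        index=families,
    )
    table.index.name = "pfam"
    return table
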