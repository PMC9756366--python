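"""Habitat-stratified PFAM-profile similarity and phylogenetically aware PCA.

The convergence question: are the domain repertoires of Arctic strains more
alike than expected given phylogeny?  Similarity is measured pairwise
between strains of *different* major taxonomic groups (so phylogenetic
proximity cannot masquerade as convergence), restricted to marine
photosynthetic strains, and never mixing genome with transcriptome
libraries.  Three complementary metrics are used: Bray-Curtis similarity of
the raw count profiles, Spearman rank correlation (robust to extreme
single-family expansions), and the number of shared PFAMs normalised by
BUSCO completeness (robust to unequal library completeness).  Category means
are compared by one-way fixed-effects ANOVA against the Arctic-Arctic
reference, one category at a time, matching how per-category p-values are
conventionally reported for this design.

The phylogenetic PCA removes Brownian-motion covariance implied by a dated
species tree before eigendecomposition: with trait matrix X (strains x
PFAMs) and C the matrix of shared root-to-MRCA path lengths,

    a = (1' C^-1 1)^-1 1' C^-1 X          (GLS root mean per PFAM)
    R = (X - 1a)' C^-1 (X - 1a) / (n - 1) (evolutionary covariance)

and the loadings/eigenvalues are those of R, with scores (X - 1a) V.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import StrainRecord, node_label

logger = logging.getLogger("polarconverge")

#: habitat ordering used to canonicalise unordered pair categories
_HABITAT_ORDER = {"Arctic": 0, "Antarctic": 1, "Other": 2}

PAIR_CATEGORIES = (
    "Arctic-Arctic",
    "Arctic-Antarctic",
    "Arctic-Other",
    "Antarctic-Antarctic",
    "Antarctic-Other",
    "Other-Other",
)


def pair_category(habitat_a: str, habitat_b: str) -> str:
    first, second = sorted((habitat_a, habitat_b), key=_HABITAT_ORDER.__getitem__)
    return f"{first}-{second}"


# ---------------------------------------------------------------------------
# Pair selection
# ---------------------------------------------------------------------------


def eligible_pairs(
    strains: Sequence[StrainRecord], library_type: str
) -> list[tuple[StrainRecord, StrainRecord]]:
    """All comparable unordered strain pairs for one library type.

    Eligible strains are marine and photosynthetic, of the requested library
    type; a pair must span two different taxonomic groups.  Freshwater and
    obligately non-photosynthetic strains therefore never appear, and
    genomes are never compared with transcriptomes.
    """
    eligible = [
        s
        for s in strains
        if s.water == "marine"
        and s.photosynthetic
        and s.library_type == library_type
    ]
    if len(eligible) < 2:
        logger.warning(
            "fewer than 2 eligible %s strains: no pairs", library_type
        )
        return []
    return [
        (a, b)
        for a, b in itertools.combinations(eligible, 2)
        if a.taxonomic_group != b.taxonomic_group
    ]


# ---------------------------------------------------------------------------
# Similarity metrics
# ---------------------------------------------------------------------------


def bray_curtis(x: np.ndarray, y: np.ndarray, presence_only: bool = False) -> float:
    """Bray-Curtis similarity 1 - sum|x-y| / sum(x+y) on count profiles.

    Computed on raw counts by default, so copy-number expansions count;
    ``presence_only=True`` collapses to 0/1 profiles first.  Identical
    profiles give 1, disjoint supports give 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("profiles must be non-negative")
    if presence_only:
        x = (x > 0).astype(float)
        y = (y > 0).astype(float)
    total = float(np.sum(x + y))
    if total == 0:
        raise ValueError("Bray-Curtis undefined: both profiles are all-zero")
    return 1.0 - float(np.sum(np.abs(x - y))) / total


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman undefined for a constant vector")
    rx = stats.rankdata(x)  # mid-ranks: ties get average rank
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def busco_norm_shared(
    x: np.ndarray, y: np.ndarray, busco_a_pct: float, busco_b_pct: float
) -> float:
    """Number of PFAMs present in both strains, normalised by mean BUSCO %.

    Normalisation divides by mean(busco_a, busco_b)/100, so two complete
    libraries (100%) report the raw shared count.
    """
    if not (0 < busco_a_pct <= 100 and 0 < busco_b_pct <= 100):
        raise ValueError("BUSCO completeness must be in (0, 100]")
    x = np.asarray(x)
    y = np.asarray(y)
    shared = int(np.sum((x > 0) & (y > 0)))
    return shared / ((busco_a_pct + busco_b_pct) / 2.0 / 100.0)


@dataclass(frozen=True)
class PairSimilarity:
    strain_a: str
    strain_b: str
    category: str
    bray_curtis: float
    spearman_rho: float
    busco_norm_shared: float


def pair_similarities(
    matrix: pd.DataFrame,
    strains: Sequence[StrainRecord],
    library_type: str,
    presence_only: bool = False,
) -> list[PairSimilarity]:
    """All three similarity metrics for every eligible pair of one library type.

    PFAM columns absent from one strain are explicit zeros (the matrix holds
    the union of columns), not dropped.
    """
    by_id = {s.strain_id: s for s in strains}
    missing = [s for s in by_id if s not in matrix.index]
    if missing:
        raise ValueError(f"strains absent from matrix: {sorted(missing)}")
    results = []
    for a, b in eligible_pairs(strains, library_type):
        x = matrix.loc[a.strain_id].to_numpy()
        y = matrix.loc[b.strain_id].to_numpy()
        results.append(
            PairSimilarity(
                strain_a=a.strain_id,
                strain_b=b.strain_id,
                category=pair_category(a.habitat, b.habitat),
                bray_curtis=bray_curtis(x, y, presence_only=presence_only),
                spearman_rho=spearman_rho(x, y),
                busco_norm_shared=busco_norm_shared(
                    x, y, a.busco_complete_pct, b.busco_complete_pct
                ),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Category summaries and ANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategorySummary:
    category: str
    library_type: str
    n_pairs: int
    mean: float
    values: tuple[float, ...] = field(repr=False)
    anova_F: float | None = None
    anova_p: float | None = None


def one_way_anova(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Classical one-way fixed-effects F-test between two groups.

    Identical group contents give F = 0, p = 1; zero within-group variance
    with distinct means gives F = inf, p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    n = len(a) + len(b)
    grand = (a.sum() + b.sum()) / n
    ss_between = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ss_within = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
    df_between, df_within = 1, n - 2
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return float(F), p


def summarize_categories(
    pairs: Sequence[PairSimilarity],
    library_type: str,
    metric: str = "bray_curtis",
    reference: str = "Arctic-Arctic",
) -> list[CategorySummary]:
    """Per-category means of a similarity metric, with ANOVA vs the reference.

    Each non-reference category with at least two pairs is tested against the
    reference in a two-group one-way ANOVA (per-category p-values, not one
    omnibus test); underpowered categories are skipped with a warning.
    """
    values: dict[str, list[float]] = {}
    for pair in pairs:
        values.setdefault(pair.category, []).append(getattr(pair, metric))
    if reference not in values:
        raise ValueError(f"no pairs in reference category {reference!r}")
    ref_values = values[reference]
    summaries = []
    for category in PAIR_CATEGORIES:
        if category not in values:
            continue
        vals = values[category]
        F = p = None
        if category != reference:
            if len(vals) >= 2 and len(ref_values) >= 2:
                F, p = one_way_anova(ref_values, vals)
            else:
                logger.warning(
                    "category %s: n < 2, ANOVA vs %s skipped", category, reference
                )
        summaries.append(
            CategorySummary(
                category=category,
                library_type=library_type,
                n_pairs=len(vals),
                mean=float(np.mean(vals)),
                values=tuple(vals),
                anova_F=F,
                anova_p=p,
            )
        )
    return summaries


def category_means_from_tables(
    matrix: pd.DataFrame,
    strains: Sequence[StrainRecord],
    metric: str = "bray_curtis",
) -> dict[str, dict[str, float]]:
    """Category mean similarities per library type, straight from the inputs.

    This is the end-to-end reproduction path for published category means:
    per-strain PFAM vectors + strain metadata in, mean Bray-Curtis (or other
    metric) per habitat-pair category out, separately for genomes and
    transcriptomes.
    """
    out: dict[str, dict[str, float]] = {}
    for library_type in ("genome", "transcriptome"):
        pairs = pair_similarities(matrix, strains, library_type)
        if not pairs:
            continue
        summaries = summarize_categories(pairs, library_type, metric=metric)
        out[library_type] = {s.category: s.mean for s in summaries}
    return out


# ---------------------------------------------------------------------------
# Phylogenetically aware PCA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhyloPcaResult:
    strains: tuple[str, ...]
    pfams: tuple[str, ...]
    eigenvalues: np.ndarray  # non-increasing
    loadings: np.ndarray  # pfams x components
    scores: np.ndarray  # strains x components
    gls_root_means: np.ndarray  # per PFAM


def brownian_covariance(tree: dendropy.Tree, leaf_order: Sequence[str]) -> np.ndarray:
    """Expected trait covariance under Brownian motion: C[i,j] = depth of MRCA.

    Depth is the path length from the root; the diagonal is each leaf's
    root-to-tip distance.  Requires branch lengths on all edges.
    """
    index = {label: i for i, label in enumerate(leaf_order)}
    n = len(leaf_order)
    C = np.zeros((n, n))

    # depth-first: node depth = parent depth + edge length
    depths: dict[int, float] = {id(tree.seed_node): 0.0}
    leaf_sets: dict[int, list[int]] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            length = node.edge.length
            if length is None:
                raise ValueError("phylogenetic PCA requires branch lengths on all edges")
            depths[id(node)] = depths[id(node.parent_node)] + float(length)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node_label(node)
            if label not in index:
                raise ValueError(f"tree leaf {label!r} not in matrix strains")
            i = index[label]
            leaf_sets[id(node)] = [i]
            C[i, i] = depths[id(node)]
        else:
            children = [leaf_sets[id(c)] for c in node.child_nodes()]
            d = depths[id(node)]
            for a_set, b_set in itertools.combinations(children, 2):
                for i in a_set:
                    for j in b_set:
                        C[i, j] = C[j, i] = d
            leaf_sets[id(node)] = [i for s in children for i in s]
    return C


def phylo_pca(matrix: pd.DataFrame, tree: dendropy.Tree) -> PhyloPcaResult:
    """GLS-centred PCA of the count matrix under Brownian tree covariance.

    The decomposition runs through a Cholesky whitening (C = L L', Y =
    L^-1 (X - 1a)) and an SVD of Y, which is algebraically identical to
    eigendecomposing R = Y'Y/(n-1) but stable for many more PFAMs than
    strains.  A singular C (e.g., zero-length branches leaving two leaves at
    identical positions) is an error naming the offending leaves.
    """
    leaves = {node_label(l) for l in tree.leaf_node_iter()}
    if leaves != set(matrix.index):
        raise ValueError(
            "tree leaves and matrix strains differ: "
            f"only-in-tree={sorted(leaves - set(matrix.index))} "
            f"only-in-matrix={sorted(set(matrix.index) - leaves)}"
        )
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    C = brownian_covariance(tree, list(matrix.index))
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        offenders = [
            (matrix.index[i], matrix.index[j])
            for i in range(n)
            for j in range(i + 1, n)
            if np.allclose(C[i], C[j])
        ]
        raise ValueError(
            f"singular Brownian covariance; identical-position leaves: {offenders}"
        ) from None
    ones = np.ones((n, 1))
    Ci_ones = np.linalg.solve(C, ones)
    a = (Ci_ones.T @ X) / (ones.T @ Ci_ones).item()  # 1 x p GLS root means
    centred = X - ones @ a
    Y = np.linalg.solve(L, centred)
    _, singular, Vt = np.linalg.svd(Y, full_matrices=False)
    eigenvalues = singular**2 / (n - 1)
    loadings = Vt.T
    scores = centred @ loadings
    return PhyloPcaResult(
        strains=tuple(matrix.index),
        pfams=tuple(matrix.columns),
        eigenvalues=eigenvalues,
        loadings=loadings,
        scores=scores,
        gls_root_means=a.ravel(),
    )
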