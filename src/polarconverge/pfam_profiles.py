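"""Per-strain PFAM count vectors and genome summary statistics.

A "PFAM count" here is the number of distinct genes of a strain carrying the
domain, not the number of domain instances within genes: per-gene annotation
tables list each (gene, domain) pair once, and isoform tallies in the
literature (e.g., 100 ice-binding-protein genes in a single transcriptome)
count genes.  Counting domain instances instead is available via
``count_instances=True`` for annotation tables that repeat a pair per
instance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io_formats import StrainRecord

logger = logging.getLogger("polarconverge")


def build_matrix(
    annotations: pd.DataFrame,
    strains: Sequence[StrainRecord],
    count_instances: bool = False,
) -> pd.DataFrame:
    """Build the strain x PFAM count matrix from an annotation table.

    ``counts[s, p]`` = number of distinct genes of strain ``s`` annotated
    with PFAM ``p``.  Row order follows ``strains``; strains with no
    annotations keep an all-zero row (logged), but PFAM columns that are zero
    everywhere are dropped.  Annotation rows naming a strain absent from
    ``strains`` are a hard error listing the offenders.
    """
    strain_ids = [s.strain_id for s in strains]
    unknown = sorted(set(annotations["strain_id"]) - set(strain_ids))
    if unknown:
        raise ValueError(f"annotations reference unknown strain_id(s): {unknown}")
    rows = annotations if count_instances else annotations.drop_duplicates(
        subset=["strain_id", "gene_id", "pfam_acc"]
    )
    matrix = (
        rows.groupby(["strain_id", "pfam_acc"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=strain_ids, fill_value=0)
    )
    matrix = matrix.loc[:, matrix.sum(axis=0) > 0].astype(int)
    matrix.columns.name = None
    matrix.index.name = "strain_id"
    empty = matrix.index[(matrix == 0).all(axis=1)]
    if len(empty):
        logger.warning("strain(s) with no PFAM annotations: %s", list(empty))
    return matrix


@dataclass(frozen=True)
class StrainSummary:
    """Headline per-strain numbers: gene:PFAM ratio and repeat content."""

    strain_id: str
    n_genes: int
    n_genes_with_pfam: int
    gene_pfam_ratio: float
    assembly_mbp: float | None = None
    repeat_mbp: float | None = None
    repeat_pct: float | None = None
    repeat_pct_consistent: bool | None = None


def gene_pfam_ratio(
    n_genes: int,
    n_genes_with_pfam: int,
    n_distinct_pfams: int | None = None,
    denominator: str = "genes_with_pfam",
) -> float:
    """Ratio of total genes to genes with at least one known PFAM.

    A high ratio reads as a large share of genes of unknown function.  The
    published methods leave the denominator ambiguous, so the alternative
    reading (total genes over *distinct PFAMs* in the strain) is selectable
    with ``denominator="distinct_pfams"`` and ``n_distinct_pfams``.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if denominator == "genes_with_pfam":
        denom = n_genes_with_pfam
    elif denominator == "distinct_pfams":
        if n_distinct_pfams is None:
            raise ValueError("denominator='distinct_pfams' needs n_distinct_pfams")
        denom = n_distinct_pfams
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom <= 0:
        raise ValueError("zero annotated genes: ratio undefined")
    if denominator == "genes_with_pfam" and n_genes_with_pfam > n_genes:
        raise ValueError("n_genes_with_pfam exceeds n_genes")
    return n_genes / denom


def group_mean_ratio(summaries: Sequence[StrainSummary]) -> float:
    """Arithmetic mean gene:PFAM ratio; strains without a ratio are skipped."""
    values = [s.gene_pfam_ratio for s in summaries if s.gene_pfam_ratio is not None]
    if not values:
        raise ValueError("no strains with a defined gene:PFAM ratio")
    skipped = len(summaries) - len(values)
    if skipped:
        logger.warning("excluded %d strain(s) without annotated genes", skipped)
    return float(sum(values) / len(values))


def size_ratio(a_mbp: float, b_mbp: float) -> float:
    """Genome-size ratio a/b, reported to 1 decimal place."""
    if b_mbp <= 0:
        raise ValueError("denominator assembly size must be positive")
    return round(a_mbp / b_mbp, 1)


def repeat_fraction(repeat_mbp: float, assembly_mbp: float) -> float:
    """Repeat space as a percentage of assembly length, to 1 decimal place."""
    if assembly_mbp <= 0:
        raise ValueError("assembly size must be positive")
    if repeat_mbp < 0:
        raise ValueError("repeat space cannot be negative")
    return round(100.0 * repeat_mbp / assembly_mbp, 1)


def check_repeat_consistency(
    repeat_mbp: float, assembly_mbp: float, reported_pct: float
) -> bool:
    """Does a reported repeat %% agree (to 1 dp) with repeat/assembly sizes?

    Published genome tables occasionally carry mutually inconsistent repeat
    values; such rows are flagged rather than silently corrected.
    """
    return abs(repeat_fraction(repeat_mbp, assembly_mbp) - round(reported_pct, 1)) < 0.05


def summarize_strain(
    strain: StrainRecord,
    annotations: pd.DataFrame,
    assembly_mbp: float | None = None,
    repeat_mbp: float | None = None,
    reported_repeat_pct: float | None = None,
) -> StrainSummary:
    """Assemble a ``StrainSummary`` for one strain from its annotation rows."""
    mine = annotations[annotations["strain_id"] == strain.strain_id]
    n_with = int(mine["gene_id"].nunique())
    ratio = gene_pfam_ratio(strain.gene_count, n_with) if n_with else float("nan")
    pct = None
    consistent = None
    if repeat_mbp is not None and assembly_mbp is not None:
        pct = repeat_fraction(repeat_mbp, assembly_mbp)
        if reported_repeat_pct is not None:
            consistent = check_repeat_consistency(
                repeat_mbp, assembly_mbp, reported_repeat_pct
            )
            if not consistent:
                logger.warning(
                    "strain %s: reported repeat %% (%s) inconsistent with "
                    "repeat/assembly sizes (%s)",
                    strain.strain_id,
                    reported_repeat_pct,
                    pct,
                )
    return StrainSummary(
        strain_id=strain.strain_id,
        n_genes=strain.gene_count,
        n_genes_with_pfam=n_with,
        gene_pfam_ratio=ratio,
        assembly_mbp=assembly_mbp,
        repeat_mbp=repeat_mbp,
        repeat_pct=pct,
        repeat_pct_consistent=consistent,
    )
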