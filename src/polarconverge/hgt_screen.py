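"""Within-alignment best-hit screen for geography-incongruent gene sharing.

Horizontal transfer between co-occurring algae leaves a fingerprint: a
species' closest relatives *for one gene family* are determined by shared
geography rather than by the species phylogeny.  Given one multiple
alignment of a family (e.g., ice-binding proteins), each sequence's best hit
among sequences of *other* species is found by pairwise identity over
mutually ungapped columns — the alignment-native analogue of a local BLAST
identity (an external BLAST-tabular hit file may be supplied instead).  A
species with more than 5 best hits of which >70% land on Arctic-or-Boreal
strains is called arctic-affiliated; <10% calls it antarctic-affiliated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger("polarconverge")

GEOGRAPHY_LABELS = ("Arctic", "Boreal", "Antarctic", "Other")

GAP_CHARS = frozenset("-.")


def pairwise_identity(aligned_a: str, aligned_b: str) -> tuple[float, int]:
    """Identity fraction over columns where neither sequence has a gap.

    Returns (identity, number of comparable columns); no comparable column
    at all is an error.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    matches = 0
    comparable = 0
    for x, y in zip(aligned_a, aligned_b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        comparable += 1
        if x == y:
            matches += 1
    if comparable == 0:
        raise ValueError("no mutually ungapped columns: identity undefined")
    return matches / comparable, comparable


@dataclass(frozen=True)
class BestHit:
    query_species: str
    query_id: str
    subject_species: str
    subject_id: str
    identity: float  # fraction in [0, 1]
    overlap: int  # comparable (mutually ungapped) columns


def best_hits(
    alignment: Mapping[str, str], species_of: Mapping[str, str]
) -> list[BestHit]:
    """Best non-same-species hit for every sequence in the alignment.

    Ties on identity are broken by larger ungapped overlap, then by
    lexicographically smaller subject id, so the result is independent of
    input ordering.  With only one species present there is nothing to
    compare: returns an empty list with a warning.
    """
    missing = sorted(set(alignment) - set(species_of))
    if missing:
        raise ValueError(f"species map missing sequence(s): {missing[:5]}")
    ids = sorted(alignment)
    if len({species_of[i] for i in ids}) < 2:
        logger.warning("only one species in alignment: no best hits")
        return []
    hits = []
    for query in ids:
        best: tuple[float, int, str] | None = None
        for subject in ids:
            if subject == query or species_of[subject] == species_of[query]:
                continue
            try:
                identity, overlap = pairwise_identity(
                    alignment[query], alignment[subject]
                )
            except ValueError:
                continue  # no shared ungapped columns with this subject
            # maximise identity, then overlap, then prefer smaller id:
            key = (identity, overlap, _ReverseStr(subject))
            if best is None or key > best:
                best = key
        if best is None:
            logger.warning("sequence %s has no comparable subject", query)
            continue
        identity, overlap, subject = best[0], best[1], best[2].value
        hits.append(
            BestHit(
                query_species=species_of[query],
                query_id=query,
                subject_species=species_of[subject],
                subject_id=subject,
                identity=identity,
                overlap=overlap,
            )
        )
    return hits


class _ReverseStr:
    """Orders strings reversed, so max() prefers the lexicographically smaller."""

    __slots__ = ("value",)

    def __init__(self, value: str):
        self.value = value

    def __lt__(self, other: "_ReverseStr") -> bool:
        return self.value > other.value

    def __gt__(self, other: "_ReverseStr") -> bool:
        return self.value < other.value

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _ReverseStr) and self.value == other.value


def best_hits_from_table(
    hits: pd.DataFrame, species_of: Mapping[str, str]
) -> list[BestHit]:
    """Best non-same-species hits from an external BLAST-tabular hit file.

    Self-species rows are discarded; per query, the row with the highest
    percent identity wins (ties: longer aligned length, then smaller
    subject id).  Identity is rescaled from percent to a fraction.
    """
    known = set(species_of)
    unknown = sorted((set(hits["qseqid"]) | set(hits["sseqid"])) - known)
    if unknown:
        raise ValueError(f"species map missing sequence(s): {unknown[:5]}")
    out = []
    for query, rows in hits.groupby("qseqid", sort=True):
        rows = rows[
            (rows["sseqid"] != query)
            & (rows["sseqid"].map(species_of) != species_of[query])
        ]
        if rows.empty:
            continue
        rows = rows.sort_values(
            ["pident", "length", "sseqid"], ascending=[False, False, True]
        )
        top = rows.iloc[0]
        out.append(
            BestHit(
                query_species=species_of[query],
                query_id=str(query),
                subject_species=species_of[top["sseqid"]],
                subject_id=str(top["sseqid"]),
                identity=float(top["pident"]) / 100.0,
                overlap=int(top["length"]),
            )
        )
    return out


@dataclass(frozen=True)
class AffiliationSummary:
    species: str
    n_sequences: int
    frac_besthits_arctic_boreal: float
    frac_besthits_antarctic: float
    affiliation: str  # arctic_affiliated | antarctic_affiliated | unclassified


def affiliate(
    hits: Sequence[BestHit], geography: Mapping[str, str]
) -> list[AffiliationSummary]:
    """Species-level geographic affiliation calls from best-hit fractions.

    Requires strictly more than 5 sequences with best hits; the fraction of
    those hits landing on Arctic-or-Boreal subjects must exceed 0.70 for an
    arctic call or fall below 0.10 for an antarctic call.
    """
    bad = sorted(
        {h.subject_species for h in hits} - set(geography)
        | {h.query_species for h in hits} - set(geography)
    )
    if bad:
        raise ValueError(f"geography map missing species: {bad[:5]}")
    per_species: dict[str, list[BestHit]] = {}
    for hit in hits:
        per_species.setdefault(hit.query_species, []).append(hit)
    summaries = []
    for species in sorted(per_species):
        mine = per_species[species]
        n = len(mine)
        frac_ab = sum(
            geography[h.subject_species] in ("Arctic", "Boreal") for h in mine
        ) / n
        frac_ant = sum(geography[h.subject_species] == "Antarctic" for h in mine) / n
        if n > 5 and frac_ab > 0.70:
            call = "arctic_affiliated"
        elif n > 5 and frac_ab < 0.10:
            call = "antarctic_affiliated"
        else:
            call = "unclassified"
        summaries.append(
            AffiliationSummary(
                species=species,
                n_sequences=n,
                frac_besthits_arctic_boreal=frac_ab,
                frac_besthits_antarctic=frac_ant,
                affiliation=call,
            )
        )
    return summaries
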