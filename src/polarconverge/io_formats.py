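"""Readers and writers for every external format the pipeline touches.

All tabular formats are TSV (tab-separated, UTF-8, with a header row); no CSV
sniffing is attempted, so files round-trip byte-stably.  Trees are Newick
(read through dendropy), alignments are FASTA (read through Biopython), and
sequence-similarity hit files use the 12-column BLAST tabular layout.

Numeric TSV round-trips are lossless at 12 significant digits
(``FLOAT_FORMAT``).  Internal tree nodes that arrive unlabelled are
auto-named deterministically by post-order index so that change tables keyed
on branch (child-node) labels are stable across runs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("polarconverge")

PFAM_RE = re.compile(r"^PF\d{5}$")

#: The eight algal groups with at least one Arctic representative in the
#: pan-algal panel, plus a catch-all.
TAXONOMIC_GROUPS = (
    "chlorophytes",
    "cryptomonads",
    "chrysophytes",
    "diatoms",
    "dictyochophytes",
    "dinoflagellates",
    "haptophytes",
    "pelagophytes",
    "other",
)

HABITATS = ("Arctic", "Antarctic", "Other")
LIBRARY_TYPES = ("genome", "transcriptome")
WATER_TYPES = ("marine", "nonmarine")

#: printf-style format giving 12 significant digits; enough for a lossless
#: text round trip of the abundances and similarity values handled here.
FLOAT_FORMAT = "%.12g"


class FormatError(ValueError):
    """A file violated the format contract (bad column, bad value, bad row)."""


# ---------------------------------------------------------------------------
# Strain metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrainRecord:
    """Metadata for one library in the panel.

    ``habitat`` is an input label (Arctic = isolated >60N within Arctic water
    masses; Antarctic = south of the Polar Front, the 6 degC sea-surface
    isotherm), never computed from coordinates here.
    """

    strain_id: str
    taxonomic_group: str
    habitat: str
    library_type: str
    water: str
    photosynthetic: bool
    busco_complete_pct: float
    gene_count: int

    def __post_init__(self) -> None:
        if self.taxonomic_group not in TAXONOMIC_GROUPS:
            raise FormatError(
                f"strain {self.strain_id!r}: unknown taxonomic_group "
                f"{self.taxonomic_group!r} (expected one of {TAXONOMIC_GROUPS})"
            )
        if self.habitat not in HABITATS:
            raise FormatError(
                f"strain {self.strain_id!r}: unknown habitat {self.habitat!r}"
            )
        if self.library_type not in LIBRARY_TYPES:
            raise FormatError(
                f"strain {self.strain_id!r}: unknown library_type "
                f"{self.library_type!r}"
            )
        if self.water not in WATER_TYPES:
            raise FormatError(
                f"strain {self.strain_id!r}: unknown water {self.water!r}"
            )
        if not 0.0 <= self.busco_complete_pct <= 100.0:
            raise FormatError(
                f"strain {self.strain_id!r}: busco_complete_pct "
                f"{self.busco_complete_pct} outside [0, 100]"
            )
        if self.gene_count < 0:
            raise FormatError(
                f"strain {self.strain_id!r}: negative gene_count"
            )


STRAIN_COLUMNS = (
    "strain_id",
    "taxonomic_group",
    "habitat",
    "library_type",
    "water",
    "photosynthetic",
    "busco_complete_pct",
    "gene_count",
)


def read_strain_table(path: str | Path) -> list[StrainRecord]:
    """Read a strain metadata TSV into a list of validated ``StrainRecord``."""
    df = _read_tsv(path, STRAIN_COLUMNS)
    records = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.strain_id in seen:
            raise FormatError(f"{path}: duplicate strain_id {row.strain_id!r}")
        seen.add(row.strain_id)
        records.append(
            StrainRecord(
                strain_id=str(row.strain_id),
                taxonomic_group=str(row.taxonomic_group),
                habitat=str(row.habitat),
                library_type=str(row.library_type),
                water=str(row.water),
                photosynthetic=_parse_bool(row.photosynthetic),
                busco_complete_pct=float(row.busco_complete_pct),
                gene_count=int(row.gene_count),
            )
        )
    return records


def write_strain_table(strains: Sequence[StrainRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(s) for s in strains], columns=list(STRAIN_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise FormatError(f"cannot parse boolean value {value!r}")


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ("strain_id", "gene_id", "pfam_acc")


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read a per-gene PFAM annotation TSV.

    Rows are (strain_id, gene_id, pfam_acc) triples.  Duplicated triples are
    collapsed with a logged warning count; a syntactically invalid PFAM
    accession (anything but ``PF`` + five digits) is a hard error naming the
    offending row.
    """
    df = _read_tsv(path, ANNOTATION_COLUMNS, dtype=str)
    for i, acc in enumerate(df["pfam_acc"]):
        if not PFAM_RE.match(str(acc)):
            # +2: header line plus 1-based numbering
            raise FormatError(
                f"{path}: malformed PFAM accession {acc!r} at row {i + 2}"
            )
    n_raw = len(df)
    df = df.drop_duplicates(ignore_index=True)
    n_dupes = n_raw - len(df)
    if n_dupes:
        logger.warning(
            "%s: collapsed %d duplicated annotation triple(s)", path, n_dupes
        )
    df.attrs["n_duplicates_collapsed"] = n_dupes
    return df


def write_annotation_table(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.loc[:, list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree.

    Leaf labels must be unique.  Unlabelled internal nodes are auto-named
    ``N<i>`` by post-order index (the index runs over *all* nodes in
    post-order, so labels are stable however many nodes already carry names);
    auto-named nodes are marked so writers can suppress the synthetic labels.
    A trifurcating (unrooted-style) root is accepted but flagged with a
    warning.
    """
    text = Path(source).read_text() if _looks_like_path(source) else str(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise FormatError(f"duplicate leaf label(s): {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise FormatError(f"duplicate leaf label(s): {sorted(dupes)}")
    if len(tree.seed_node.child_nodes()) > 2:
        logger.warning(
            "tree root has %d children (unrooted-style trifurcation accepted)",
            len(tree.seed_node.child_nodes()),
        )
        tree.is_rooted = True
    for index, node in enumerate(tree.postorder_node_iter()):
        node.postorder_index = index
        if node.is_leaf():
            continue
        label = node.taxon.label if node.taxon else node.label
        if not label:
            node.label = f"N{index}"
            node.auto_named = True
    return tree


def _looks_like_path(source: str | Path) -> bool:
    if isinstance(source, Path):
        return True
    stripped = source.strip()
    return not (stripped.startswith("(") and stripped.endswith(";"))


def node_label(node: dendropy.Node) -> str | None:
    """The display label of a node: its taxon label, else its bare label."""
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree to Newick with %g branch lengths.

    Branch lengths are emitted with 12 significant digits and no trailing
    zeros, so ``((A:1,B:2):0.5,C:3);`` survives a read/write cycle verbatim.
    Auto-assigned internal labels (from :func:`read_newick`) are suppressed.
    """

    def render(node: dendropy.Node) -> str:
        if node.is_leaf():
            text = node_label(node) or ""
        else:
            inner = ",".join(render(c) for c in node.child_nodes())
            label = "" if getattr(node, "auto_named", False) else (node_label(node) or "")
            text = f"({inner}){label}"
        if node.edge.length is not None:
            text += ":" + (FLOAT_FORMAT % node.edge.length)
        return text

    return render(tree.seed_node) + ";"


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Change tables (CAFE-style, or from the internal Wagner parsimony)
# ---------------------------------------------------------------------------

CHANGE_COLUMNS = ("family_id", "branch_id", "signed_change")


def read_change_table(
    path: str | Path, tree: dendropy.Tree | None = None
) -> pd.DataFrame:
    """Read per-family per-branch signed copy-number changes.

    ``branch_id`` is the child-node label of the branch.  When a tree is
    supplied every branch_id must resolve against it.
    """
    df = _read_tsv(path, CHANGE_COLUMNS)
    try:
        df["signed_change"] = df["signed_change"].astype(int)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-integer signed_change: {exc}") from exc
    if tree is not None:
        known = {node_label(n) for n in tree.preorder_node_iter()}
        unknown = sorted(set(df["branch_id"].astype(str)) - known)
        if unknown:
            raise FormatError(
                f"{path}: branch_id(s) not resolvable in tree: {unknown}"
            )
    return df


def write_change_table(changes: pd.DataFrame, path: str | Path) -> None:
    changes.loc[:, list(CHANGE_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count / abundance matrices
# ---------------------------------------------------------------------------


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a strain x PFAM count matrix (row index in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values in count matrix")
    try:
        df = df.astype(int)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-integer counts: {exc}") from exc
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative counts")
    return df


def write_count_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_abundance_matrix(path: str | Path) -> pd.DataFrame:
    """Read a unigene x station relative-abundance matrix.

    Values must be numeric and non-negative; every unigene (row) must have at
    least one non-zero entry.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric abundance: {exc}") from exc
    if df.isna().any().any():
        raise FormatError(f"{path}: missing abundance values")
    if (df.to_numpy() < 0).any():
        bad = df.index[(df < 0).any(axis=1)][0]
        raise FormatError(f"{path}: negative abundance for unigene {bad!r}")
    zero_rows = df.index[(df == 0).all(axis=1)]
    if len(zero_rows):
        raise FormatError(
            f"{path}: all-zero abundance row(s): {list(zero_rows[:5])}"
        )
    return df


def write_abundance_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Station tables
# ---------------------------------------------------------------------------

STATION_COLUMNS = ("station_id", "latitude", "region", "depth_layer", "size_fraction")
DEPTH_LAYERS = ("SRF", "DCM", "MES")
REGIONS = ("arctic", "antarctic", "other")


def derive_region(latitude: float) -> str:
    """Polar region from latitude: arctic iff lat > 60, antarctic iff lat < -55.

    Both bounds are strict, so 60.0 N and -55.0 S are "other".  Water-mass
    corrections are applied as manual overrides in the station table, not
    here.
    """
    if latitude > 60.0:
        return "arctic"
    if latitude < -55.0:
        return "antarctic"
    return "other"


def read_station_table(path: str | Path) -> pd.DataFrame:
    """Read station metadata; blank regions are auto-derived from latitude."""
    df = _read_tsv(path, STATION_COLUMNS, dtype=str)
    df["latitude"] = df["latitude"].astype(float)
    if (df["latitude"].abs() > 90).any():
        raise FormatError(f"{path}: latitude outside [-90, 90]")
    region = df["region"].fillna("").astype(str)
    derived = df["latitude"].map(derive_region)
    df["region"] = region.where(region.str.len() > 0, derived)
    bad_region = sorted(set(df["region"]) - set(REGIONS))
    if bad_region:
        raise FormatError(f"{path}: unknown region(s) {bad_region}")
    bad_layer = sorted(set(df["depth_layer"]) - set(DEPTH_LAYERS))
    if bad_layer:
        raise FormatError(f"{path}: unknown depth_layer(s) {bad_layer}")
    if df["station_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate station_id")
    return df


def write_station_table(stations: pd.DataFrame, path: str | Path) -> None:
    stations.loc[:, list(STATION_COLUMNS)].to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


# ---------------------------------------------------------------------------
# BLAST-tabular hit files and FASTA alignments
# ---------------------------------------------------------------------------

HIT_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a headerless 12-column BLAST tabular (outfmt 6) hit file."""
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] != 12:
        raise FormatError(
            f"{path}: expected 12 BLAST-tabular columns, found {df.shape[1]}"
        )
    df.columns = list(HIT_COLUMNS)
    df["pident"] = df["pident"].astype(float)
    df["bitscore"] = df["bitscore"].astype(float)
    return df


def read_fasta_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into an ordered {id: sequence} mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"{path}: empty FASTA")
    lengths = {len(s) for s in records.values()}
    if len(lengths) > 1:
        raise FormatError(
            f"{path}: sequences have unequal aligned lengths {sorted(lengths)}"
        )
    return records


def write_fasta_alignment(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Report bundles
# ---------------------------------------------------------------------------


def write_report(tables: Mapping[str, pd.DataFrame], path: str | Path) -> None:
    """Write a dict of DataFrames as ``<path>/<name>.tsv`` files."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.to_csv(out / f"{name}.tsv", sep="\t", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _read_tsv(
    path: str | Path,
    required_columns: Iterable[str],
    dtype: object | None = None,
) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=dtype)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


def newick_string_roundtrip(text: str) -> str:
    """Parse then re-serialise a Newick string (used by round-trip tests)."""
    return tree_to_newick(read_newick(text))
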