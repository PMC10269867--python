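"""Readers, writers and cross-validation for the pipeline's four input kinds.

Trees are handled as :class:`skbio.TreeNode` (rooted, branch lengths in
arbitrary units), feature tables as pandas DataFrames with samples in rows
and ASVs in columns (non-negative integers), metadata as a DataFrame indexed
by sample id, and distance matrices as :class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

REQUIRED_METADATA_COLUMNS = ("sample_id", "species", "body_site", "mass_g")

BODY_SITES = ("blood", "buccal", "gizzard", "intestine", "cloaca", "liver", "spleen")


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class ValidationError(ValueError):
    """Raised for inputs that parse but violate an invariant."""


def normalize_species_name(name: str) -> str:
    """Canonicalise a species label: trim and use underscores, the Newick
    convention for tip labels (e.g. ``"Passer domesticus"`` ->
    ``"Passer_domesticus"``). Matching is exact and case-sensitive after this."""
    return name.strip().replace(" ", "_")


def _validate_tree(tree: TreeNode) -> TreeNode:
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        dupes = sorted({t for t in tips if tips.count(t) > 1})
        raise ValidationError(f"duplicate tip labels: {dupes[:10]}")
    # unnamed internal nodes get synthetic ids so every node is addressable
    k = 0
    for node in tree.non_tips(include_self=True):
        if node.name is None:
            node.name = f"_node{k}"
            k += 1
        if node.length is not None and node.length < 0:
            raise ValidationError(f"negative branch length at node {node.name!r}")
    for tip in tree.tips():
        if tip.length is not None and tip.length < 0:
            raise ValidationError(f"negative branch length at tip {tip.name!r}")
    return tree


def read_newick(path_or_buffer) -> TreeNode:
    """Read a rooted tree from a Newick file.

    Unlabelled internal nodes are assigned synthetic ids; duplicate tip
    labels or negative branch lengths raise :class:`ValidationError`.
    """
    try:
        tree = TreeNode.read(path_or_buffer, format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return _validate_tree(tree)


def parse_newick(newick: str) -> TreeNode:
    """Parse a Newick string (convenience wrapper around :func:`read_newick`)."""
    return read_newick(io.StringIO(newick))


def write_newick(tree: TreeNode, path) -> None:
    tree.write(path, format="newick")


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def read_feature_table(path_or_buffer) -> pd.DataFrame:
    """Read a samples x ASVs count table from TSV.

    First column holds sample ids, header row holds ASV ids. Counts must be
    non-negative integers; an empty table is an error.
    """
    df = pd.read_csv(path_or_buffer, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError("empty feature table")
    if df.index.has_duplicates:
        raise ValidationError("duplicate sample ids in feature table")
    if df.columns.has_duplicates:
        raise ValidationError("duplicate ASV ids in feature table")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("non-numeric entries in feature table")
    if np.any(values < 0):
        raise ValidationError("negative counts in feature table")
    if not np.allclose(values, np.round(values)):
        raise ValidationError("non-integer counts in feature table")
    df = df.astype(np.int64)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    df.columns = df.columns.astype(str)
    return df


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path_or_buffer) -> pd.DataFrame:
    """Read per-sample metadata from TSV; requires columns
    ``sample_id, species, body_site, mass_g``.

    Species names are canonicalised to underscore form. An optional
    ``species_mass_g`` column provides a species-level fallback mass for
    individuals lacking a field measurement; missing masses are left missing,
    never invented.
    """
    meta = pd.read_csv(path_or_buffer, sep="\t", dtype={"sample_id": str})
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    bad_site = sorted(set(meta["body_site"]) - set(BODY_SITES))
    if bad_site:
        raise ValidationError(f"unknown body_site values: {bad_site[:10]}")
    mass = pd.to_numeric(meta["mass_g"], errors="coerce")
    if (mass <= 0).any():
        raise ValidationError("mass_g must be positive where present")
    meta["mass_g"] = mass
    if "species_mass_g" in meta.columns:
        fallback = pd.to_numeric(meta["species_mass_g"], errors="coerce")
        meta["mass_g"] = meta["mass_g"].fillna(fallback)
    meta["species"] = meta["species"].map(normalize_species_name)
    return meta.set_index("sample_id", drop=False)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_distance_matrix(path_or_buffer) -> DistanceMatrix:
    """Read a square TSV distance matrix with an id header row and column."""
    df = pd.read_csv(path_or_buffer, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError("distance matrix row/column ids differ")
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


@dataclass
class ValidationReport:
    """Cross-reference report over the four pipeline inputs."""

    samples_without_metadata: list[str] = field(default_factory=list)
    metadata_without_samples: list[str] = field(default_factory=list)
    species_missing_from_host_tree: list[str] = field(default_factory=list)
    asvs_missing_from_asv_tree: list[str] = field(default_factory=list)

    def ok(self) -> bool:
        return not (
            self.samples_without_metadata
            or self.species_missing_from_host_tree
            or self.asvs_missing_from_asv_tree
        )

    def raise_if_invalid(self) -> None:
        problems = []
        for label, ids in (
            ("samples without metadata", self.samples_without_metadata),
            ("species missing from host tree", self.species_missing_from_host_tree),
            ("ASVs missing from ASV tree", self.asvs_missing_from_asv_tree),
        ):
            if ids:
                problems.append(f"{label}: {ids[:10]}")
        if problems:
            raise ValidationError("; ".join(problems))


def validate_inputs(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    host_tree: TreeNode,
    asv_tree: TreeNode,
    strict: bool = False,
) -> ValidationReport:
    """Check that sample, species and ASV identifiers agree across inputs.

    Species names join metadata to host-tree tips by exact string equality
    (after underscore canonicalisation in :func:`read_metadata`).
    """
    host_tips = {t.name for t in host_tree.tips()}
    asv_tips = {t.name for t in asv_tree.tips()}
    meta_samples = set(meta.index.astype(str))
    table_samples = set(table.index.astype(str))
    report = ValidationReport(
        samples_without_metadata=sorted(table_samples - meta_samples),
        metadata_without_samples=sorted(meta_samples - table_samples),
        species_missing_from_host_tree=sorted(set(meta["species"]) - host_tips),
        asvs_missing_from_asv_tree=sorted(set(table.columns) - asv_tips),
    )
    if strict:
        report.raise_if_invalid()
    return report
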