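"""Readers and writers for the on-disk formats the pipeline exchanges.

All tables are tab-separated UTF-8 with a header row.  Community count
tables are oriented samples x taxa (first column = sample id); a
``taxa_as_rows`` flag transposes on read.  Trees are newick, images are
8- or 16-bit grayscale TIFF/PNG, masks are PNG with nonzero = foreground.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from PIL import Image

from .errors import ParseError

__all__ = [
    "read_community_table",
    "write_community_table",
    "read_table",
    "write_table",
    "read_tree",
    "write_tree",
    "patristic_matrix",
    "read_gray_image",
    "write_gray_image",
    "read_mask",
    "write_mask",
    "read_calibration_series",
    "write_calibration_series",
    "file_sha256",
]


def read_community_table(path, taxa_as_rows: bool = False) -> pd.DataFrame:
    """Read a samples x taxa count table from TSV.

    The first column holds sample ids (taxon ids when ``taxa_as_rows``).
    Counts must be non-negative integers, ids unique, and every sample
    must contain at least one observation.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if taxa_as_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ParseError(f"duplicate sample ids: {dupes}")
    if df.columns.duplicated().any():
        raise ParseError("duplicate taxon ids")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"non-numeric entry in count table: {exc}") from exc
    if np.isnan(values).any():
        row = df.index[np.isnan(values).any(axis=1)][0]
        raise ParseError(f"missing/ragged value in row {row!r}")
    if (values < 0).any():
        row = df.index[(values < 0).any(axis=1)][0]
        raise ParseError(f"negative count in row {row!r}")
    if (values.sum(axis=1) == 0).any():
        row = df.index[values.sum(axis=1) == 0][0]
        raise ParseError(f"sample {row!r} has zero total count")
    return df


def write_community_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_table(path, index_col=0) -> pd.DataFrame:
    """Generic numeric TSV (samples x variables)."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path, index_label="sample_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_tree(path) -> dendropy.Tree:
    """Parse a newick tree; duplicate tips or malformed text raise ParseError."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"could not parse newick tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ParseError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ParseError("negative branch length in tree")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def patristic_matrix(tree: dendropy.Tree, labels=None) -> pd.DataFrame:
    """Tip-to-tip path-length (patristic) distance matrix.

    ``labels`` restricts and orders the output; all requested labels must
    be tips of the tree.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label is not None}
    tip_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if labels is None:
        labels = tip_labels
    missing = [lab for lab in labels if lab not in taxa]
    if missing:
        raise ParseError(f"taxa absent from tree: {missing}")
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=labels, columns=labels)


def read_gray_image(path) -> np.ndarray:
    """Load an 8/16-bit grayscale image, rescaled to the [0, 256] gray scale.

    8-bit white (255) and 16-bit white (65535) both map to 256.
    """
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:  # RGB(A) -> luminance
        arr = arr[..., :3].mean(axis=2)
    if arr.dtype == np.uint16:
        return arr.astype(float) * (256.0 / 65535.0)
    if arr.dtype == np.uint8:
        return arr.astype(float) * (256.0 / 255.0)
    return arr.astype(float)  # float rasters assumed already on [0, 256]


def write_gray_image(pixels: np.ndarray, path) -> None:
    """Write a [0, 256] gray raster as 16-bit TIFF/PNG."""
    scaled = np.clip(pixels, 0, 256) / 256.0 * 65535.0
    Image.fromarray(scaled.astype(np.uint16)).save(path)


def read_mask(path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=2)
    return (arr != 0).astype(np.uint8)


def write_mask(mask: np.ndarray, path) -> None:
    Image.fromarray((np.asarray(mask) != 0).astype(np.uint8) * 255).save(path)


def read_calibration_series(path) -> list[tuple[float, float]]:
    """Two-column TSV: concentration_mg_kg, mean_gray."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError("calibration series needs 2 columns (conc, gray)")
    return [(float(c), float(g)) for c, g in zip(df.iloc[:, 0], df.iloc[:, 1])]


def write_calibration_series(points, path) -> None:
    pd.DataFrame(points, columns=["concentration_mg_kg", "mean_gray"]).to_csv(
        path, sep="\t", index=False
    )


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
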