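"""Binary hierarchical clustering and two-color detection maps.

Presence/absence matrices cluster well under set-overlap distances; the
defaults here are Jaccard distance with average linkage, both
configurable.  Determinism matters because binary data produce many tied
distances: items are first sorted into canonical (lexicographic id) order
so equal-height merges resolve identically on every run and platform.

The reordered matrix plus the two Newick dendrograms are the contract of a
detection map; rendering to an image is an optional convenience and is
never a test surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from .model import DetectionCallMatrix, Dendrogram, DetectomeError

METRICS = ("jaccard", "hamming")
LINKAGES = ("average", "complete", "single")


def binary_distance(
    calls: DetectionCallMatrix, axis: str = "samples", metric: str = "jaccard"
) -> pd.DataFrame:
    """Pairwise distances between samples (columns) or miRNAs (rows).

    Jaccard distance between two all-absent profiles is defined as 0
    (identical emptiness); Hamming is the normalized mismatch fraction.
    """
    if metric not in METRICS:
        raise DetectomeError(f"unknown metric {metric!r} (expected {METRICS})")
    if axis == "samples":
        data = calls.calls.T
    elif axis == "mirnas":
        data = calls.calls
    else:
        raise DetectomeError(f"unknown axis {axis!r} (expected 'samples' or 'mirnas')")
    if data.shape[0] < 2:
        raise DetectomeError(f"need at least 2 items on axis {axis!r}")
    d = squareform(pdist(data.to_numpy(bool), metric=metric))
    return pd.DataFrame(d, index=data.index, columns=data.index)


def hcluster(distances: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a symmetric distance matrix.

    Leaves are put in canonical lexicographic order before merging, so the
    output tree is a pure function of the distance values, not of input
    order.  Merge heights are non-decreasing for the supported linkages.
    """
    if linkage not in LINKAGES:
        raise DetectomeError(f"unknown linkage {linkage!r} (expected {LINKAGES})")
    if list(distances.index) != list(distances.columns):
        raise DetectomeError("distance matrix rows and columns must match")
    vals = distances.to_numpy(float)
    if not np.allclose(vals, vals.T, atol=1e-12):
        raise DetectomeError("distance matrix must be symmetric")
    if not np.allclose(np.diag(vals), 0.0, atol=1e-12):
        raise DetectomeError("distance matrix diagonal must be zero")
    order = sorted(range(len(distances.index)), key=lambda i: str(distances.index[i]))
    labels = [str(distances.index[i]) for i in order]
    if len(labels) == 1:
        return Dendrogram(labels=labels, merges=np.empty((0, 4)), method=linkage)
    condensed = squareform(vals[np.ix_(order, order)], checks=False)
    Z = scipy_linkage(condensed, method=linkage)
    return Dendrogram(labels=labels, merges=Z, method=linkage)


@dataclass
class DetectionMap:
    """A call matrix reordered by dendrogram leaf orders — the data behind a
    two-color detection heatmap.  Reordering is a pure permutation."""

    matrix: pd.DataFrame
    row_order: list[str]
    col_order: list[str]
    row_dendrogram: Dendrogram | None
    col_dendrogram: Dendrogram | None


def detection_map(
    calls: DetectionCallMatrix,
    sample_dendrogram: Dendrogram | None = None,
    mirna_dendrogram: Dendrogram | None = None,
) -> DetectionMap:
    """Reorder the call matrix by the two dendrograms' leaf orders.

    A missing dendrogram leaves that axis in input order.  Leaf sets must
    match the matrix ids exactly.
    """
    rows = calls.mirna_ids
    cols = calls.sample_ids
    if mirna_dendrogram is not None:
        if set(mirna_dendrogram.labels) != set(rows):
            raise DetectomeError("miRNA dendrogram leaves do not match matrix rows")
        rows = mirna_dendrogram.leaf_order()
    if sample_dendrogram is not None:
        if set(sample_dendrogram.labels) != set(cols):
            raise DetectomeError("sample dendrogram leaves do not match matrix columns")
        cols = sample_dendrogram.leaf_order()
    return DetectionMap(
        matrix=calls.calls.loc[rows, cols].copy(),
        row_order=rows,
        col_order=cols,
        row_dendrogram=mirna_dendrogram,
        col_dendrogram=sample_dendrogram,
    )


def cluster_calls(
    calls: DetectionCallMatrix,
    metric: str = "jaccard",
    linkage: str = "average",
    cluster_rows: bool = True,
    cluster_cols: bool = True,
) -> DetectionMap:
    """Convenience: cluster both axes of a call matrix and build the map."""
    row_d = (
        hcluster(binary_distance(calls, "mirnas", metric), linkage)
        if cluster_rows and len(calls.mirna_ids) > 1
        else None
    )
    col_d = (
        hcluster(binary_distance(calls, "samples", metric), linkage)
        if cluster_cols and len(calls.sample_ids) > 1
        else None
    )
    return detection_map(calls, sample_dendrogram=col_d, mirna_dendrogram=row_d)


def plot_detection_map(
    dmap: DetectionMap,
    path,
    detected_color: str = "#2166ac",
    undetected_color: str = "black",
    title: str | None = None,
) -> None:
    """Render the two-color raster (detected vs undetected) to PNG/SVG.

    Colors are per-figure configurable (the canonical maps use blue/green/
    red/yellow/turquoise on black depending on the sample group shown).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    fig, ax = plt.subplots(figsize=(6, 8))
    ax.imshow(
        dmap.matrix.to_numpy(bool),
        aspect="auto",
        interpolation="none",
        cmap=ListedColormap([undetected_color, detected_color]),
        vmin=0,
        vmax=1,
    )
    ax.set_xticks(range(len(dmap.col_order)))
    ax.set_xticklabels(dmap.col_order, rotation=90, fontsize=5)
    ax.set_yticks([])
    ax.set_xlabel("samples")
    ax.set_ylabel(f"miRNAs ({len(dmap.row_order)})")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
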