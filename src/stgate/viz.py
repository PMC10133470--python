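"""Averaged-adjacency extraction and topographic edge export.

After training, the per-sample dynamic adjacencies are extracted in
evaluation mode, averaged elementwise over all samples and symmetrized.
The strongest connections are then selected *globally* (largest ten
upper-triangle values by default — deliberately distinct from the per-row
Top-K used inside the network) and exported as a scalp plot plus a
tab-separated edge table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DataError
from .features import ElectrodeMontage
from .model import STGATE

logger = logging.getLogger(__name__)


def average_adjacency(model: STGATE, X: np.ndarray, batch_size: int = 64,
                      post_topk: bool = False) -> np.ndarray:
    """Mean dynamic adjacency over all samples, symmetrized as (A + A^T)/2.

    By default the standardized pre-Top-K matrix is averaged (Top-K
    averaging would bias toward frequently selected but weak edges); set
    ``post_topk=True`` to average the sparsified matrices instead.
    """
    if not model.cfg.uses_spatial:
        raise ConfigurationError(
            f"variant {model.cfg.variant!r} has no spatial attention"
        )
    model.eval()
    total = None
    count = 0
    for start in range(0, len(X), batch_size):
        batch = model.dynamic_adjacency(X[start : start + batch_size],
                                        post_topk=post_topk)
        chunk = batch.sum(axis=0)
        total = chunk if total is None else total + chunk
        count += batch.shape[0]
    mean = total / count
    return (mean + mean.T) / 2.0


def top_edges_global(a_mean: np.ndarray, labels: list[str], n: int = 10):
    """The n globally largest upper-triangle entries as a ranked edge list.

    Returns ``(edges, exported)`` where ``edges`` is a list of
    ``(label_i, label_j, weight)`` sorted descending and ``exported`` is the
    matrix with all other entries zeroed.
    """
    a = np.asarray(a_mean, dtype=float)
    dim = a.shape[0]
    max_edges = dim * (dim - 1) // 2
    if n < 1 or n > max_edges:
        raise ConfigurationError(f"n must be in [1, {max_edges}], got {n}")
    iu, ju = np.triu_indices(dim, k=1)
    order = np.argsort(-a[iu, ju], kind="stable")[:n]
    exported = np.zeros_like(a)
    edges = []
    for idx in order:
        i, j = int(iu[idx]), int(ju[idx])
        exported[i, j] = exported[j, i] = a[i, j]
        edges.append((labels[i], labels[j], float(a[i, j])))
    return edges, exported


def export_topomap(edges, montage: ElectrodeMontage, path: str | Path):
    """Write a scalp-projection SVG and a tab-separated edge table.

    The table (``<path>.tsv``) is written first, so a plotting failure never
    corrupts it.  Returns ``(svg_path, table_path)``; ``svg_path`` is None if
    plotting failed.
    """
    path = Path(path)
    index = {lab: i for i, lab in enumerate(montage.labels)}
    for lab_i, lab_j, _ in edges:
        if lab_i not in index or lab_j not in index:
            raise DataError(f"edge ({lab_i}, {lab_j}) has labels outside the montage")
    table_path = path.with_suffix(".tsv")
    with open(table_path, "w") as fh:
        fh.write("channel_i\tchannel_j\tweight\n")
        for lab_i, lab_j, w in edges:
            fh.write(f"{lab_i}\t{lab_j}\t{w!r}\n")
    svg_path = path.with_suffix(".svg")
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        head = plt.Circle((0, 0), 1.05, fill=False, lw=1.5)
        ax.add_patch(head)
        coords = montage.coords2d
        max_w = max((abs(w) for _, _, w in edges), default=1.0) or 1.0
        for lab_i, lab_j, w in edges:
            pi, pj = coords[index[lab_i]], coords[index[lab_j]]
            ax.plot([pi[0], pj[0]], [pi[1], pj[1]], color="crimson",
                    lw=0.5 + 2.5 * abs(w) / max_w, alpha=0.8, zorder=1)
        ax.scatter(coords[:, 0], coords[:, 1], s=18, color="k", zorder=2)
        for lab, (x, y) in zip(montage.labels, coords):
            ax.annotate(lab, (x, y), fontsize=5, textcoords="offset points",
                        xytext=(2, 2))
        ax.set_xlim(-1.2, 1.2)
        ax.set_ylim(-1.2, 1.2)
        ax.set_aspect("equal")
        ax.axis("off")
        fig.savefig(svg_path, format="svg", bbox_inches="tight")
        plt.close(fig)
    except Exception:  # noqa: BLE001 - table must survive plot failures
        logger.exception("topomap plotting failed; edge table kept at %s", table_path)
        svg_path = None
    return svg_path, table_path


def read_edge_table(table_path: str | Path):
    """Inverse of the table written by :func:`export_topomap`."""
    edges = []
    with open(table_path) as fh:
        header = fh.readline()
        if not header.startswith("channel_i"):
            raise DataError(f"{table_path} is not an edge table")
        for line in fh:
            lab_i, lab_j, w = line.rstrip("\n").split("\t")
            edges.append((lab_i, lab_j, float(w)))
    return edges
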