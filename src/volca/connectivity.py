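"""Spearman correlation matrix and thresholded 3D functional connectivity.

Pairwise Spearman rank correlation between raw fluorescence traces is
insensitive to amplitude differences (illumination inhomogeneity, expression
level) but sensitive to common monotone changes, which makes it the
correlation measure of choice for functional coupling.  Neurons are ordered
by their distance from the constellation's center of mass (COM) so that
spatial structure is visible in the matrix; the graph keeps only the
strongest couplings (|R| above a strict threshold) with node degree encoding
hubness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .components import ComponentSet
from .errors import DegenerateInputError, ParameterError

__all__ = ["CorrelationMatrix", "order_by_com", "spearman_matrix", "build_graph"]


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman matrix with its COM-based ordering."""

    R: np.ndarray  # (n, n), values in [-1, 1], unit diagonal
    ordering: np.ndarray  # component ids, sorted by distance from COM
    com: np.ndarray  # (z, y, x) um

    def to_csv(self, path) -> None:
        pd.DataFrame(self.R, index=self.ordering, columns=self.ordering).to_csv(path)


def order_by_com(cset: ComponentSet, weighted: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Component ids sorted by Euclidean distance from the center of mass.

    The COM is the unweighted mean of component centroids by default;
    ``weighted=True`` weights each centroid by its footprint mass.  Ties are
    broken by id.
    """
    if len(cset) == 0:
        raise DegenerateInputError("cannot order an empty component set")
    cen = cset.centroids_um
    if weighted:
        w = np.array([fp.sum() for fp in cset.footprints], dtype=float)
        com = (cen * w[:, None]).sum(axis=0) / w.sum()
    else:
        com = cen.mean(axis=0)
    dist = np.linalg.norm(cen - com, axis=1)
    order = np.lexsort((cset.ids, dist))
    return cset.ids[order], com


def spearman_matrix(
    traces: np.ndarray, ordering: np.ndarray | None = None
) -> CorrelationMatrix:
    """Spearman rank correlation matrix of a set of traces.

    ``R_ij`` is the Pearson correlation of the rank-transformed traces
    (average ranks on ties).  A constant trace is rank-degenerate: its row
    and column are set to 0 (diagonal stays 1) with a warning.  ``ordering``
    gives the trace order (indices into ``traces``); identity if omitted.
    """
    traces = np.asarray(traces, dtype=np.float64)
    n, t = traces.shape
    if n < 2:
        raise ParameterError("need at least 2 traces")
    if t < 3:
        raise ParameterError("need traces of length >= 3")
    if ordering is None:
        ordering = np.arange(n)
    ordering = np.asarray(ordering)
    ordered = traces[ordering]

    ranks = np.apply_along_axis(rankdata, 1, ordered)
    sd = ranks.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant trace(s): Spearman row/column set to 0"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        R = np.corrcoef(ranks)
    R[degenerate, :] = 0.0
    R[:, degenerate] = 0.0
    np.fill_diagonal(R, 1.0)
    com = np.full(3, np.nan)
    return CorrelationMatrix(R=np.clip(R, -1.0, 1.0), ordering=ordering, com=com)


def build_graph(
    corr: CorrelationMatrix,
    threshold: float = 0.8,
    centroids_um: np.ndarray | None = None,
) -> nx.Graph:
    """Undirected functional-connectivity graph with |R| > threshold edges.

    The inequality is strict: a pair exactly at the threshold is not
    connected.  Edges carry the signed Spearman R; nodes carry their
    centroid (if given) and their recomputed degree, which visualization
    uses to scale node size.
    """
    R = corr.R
    n = len(R)
    g = nx.Graph(threshold=threshold)
    for k, comp_id in enumerate(corr.ordering):
        attrs = {}
        if centroids_um is not None:
            attrs["z_um"] = float(centroids_um[k][0])
            attrs["y_um"] = float(centroids_um[k][1])
            attrs["x_um"] = float(centroids_um[k][2])
        g.add_node(int(comp_id), **attrs)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(R[i, j]) > threshold:
                g.add_edge(int(corr.ordering[i]), int(corr.ordering[j]), R=float(R[i, j]))
    degrees = dict(g.degree())
    nx.set_node_attributes(g, degrees, "degree")
    return g
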