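"""Gaussian graphical model over binned genome tracks.

The edge weight between two tracks is their full partial correlation —
the correlation remaining after conditioning on every other track — read
off the inverse of the pairwise correlation matrix:

    w_ij = -J_ij / sqrt(J_ii * J_jj),   J = R^-1.

Bins are complete-case selected: any bin undefined in any track (or
masked) is dropped before computing R.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .tracks import MaskTrack, SignalTrack

COND_LIMIT = 1e8


@dataclass
class GGMGraph:
    nodes: list[str]
    R: np.ndarray  # correlation matrix
    J: np.ndarray  # precision (inverse correlation) matrix
    weights: np.ndarray  # full partial correlations, unit diagonal
    n_bins: int

    def edge_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.nodes)):
            for j in range(i + 1, len(self.nodes)):
                rows.append(
                    (self.nodes[i], self.nodes[j], self.weights[i, j], self.R[i, j])
                )
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "r_marginal"])


def fit_ggm(
    tracks: Mapping[str, SignalTrack], mask: MaskTrack | None = None
) -> GGMGraph:
    """Fit the graphical model on jointly defined, unmasked bins."""
    nodes = list(tracks)
    if len(nodes) < 2:
        raise ValueError("need >= 2 tracks")
    grid = tracks[nodes[0]].grid
    ok = np.ones(grid.n_bins, dtype=bool)
    for name in nodes:
        t = tracks[name]
        if t.grid != grid:
            raise ValueError(f"track {name!r} is on a different grid")
        ok &= t.defined
    if mask is not None:
        ok &= ~mask.values
    n = int(ok.sum())
    if n <= len(nodes) + 2:
        raise ValueError(f"insufficient bins: {n} for {len(nodes)} tracks")
    X = np.column_stack([tracks[name].values[ok] for name in nodes])
    sd = X.std(axis=0)
    flat = [nodes[i] for i in np.flatnonzero(sd == 0)]
    if flat:
        raise ValueError(f"zero-variance tracks: {flat}")
    R = np.corrcoef(X, rowvar=False)
    cond = np.linalg.cond(R)
    if cond > COND_LIMIT:
        # name the most collinear pair for the error message
        off = np.abs(R - np.eye(len(nodes)))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(
            f"correlation matrix near-singular (cond={cond:.2e}); most "
            f"collinear pair: {nodes[i]!r} ~ {nodes[j]!r} (r={R[i, j]:.6f})"
        )
    J = np.linalg.inv(R)
    d = np.sqrt(np.diag(J))
    W = -J / np.outer(d, d)
    np.fill_diagonal(W, 1.0)
    return GGMGraph(nodes, R, J, W, n)
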