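"""Signal alignment around anchor points and heat-map style summaries.

An alignment matrix holds a signal track (normalized by its genome-wide
mean) in fixed windows around anchor points (TSSs, peak centres, ...), one
row per anchor, ordered by an anchor score. For display the matrix is
pixelated to at most 200x200 by block averaging; for quantitative reading
the anchors are grouped into score quartiles and the per-quartile
column-wise median profile is taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import SignalTrack


@dataclass
class AlignmentMatrix:
    matrix: np.ndarray  # rows: anchors in score order; nan = undefined
    offsets_bp: np.ndarray
    scores: np.ndarray  # sorted ascending
    anchors: pd.DataFrame  # sorted rows: chrom, pos, strand, score
    norm_constant: float


def align_signal(
    anchors: pd.DataFrame, signal: SignalTrack, half_width: int
) -> AlignmentMatrix:
    """Signal around each anchor in a +/- ``half_width`` bp window.

    Columns sample the track at bin resolution at signed offsets from the
    anchor position; minus-strand anchors have their offsets reversed so
    that downstream is always to the right. Rows are sorted by score
    (ascending; ties broken by coordinate for determinism). Values are
    normalized by the genome-wide track mean; out-of-genome or undefined
    bins are nan.
    """
    if anchors.empty:
        raise ValueError("empty anchor set")
    grid = signal.grid
    W = grid.width
    norm = signal.mean()
    if not np.isfinite(norm) or norm <= 0:
        raise ValueError("signal mean must be positive for normalization")
    n_off = half_width // W
    offsets = np.arange(-n_off, n_off + 1)
    a = anchors.sort_values(
        ["score", "chrom", "pos"], kind="stable"
    ).reset_index(drop=True)
    mat = np.full((len(a), offsets.size), np.nan)
    chrom_idx = {c: i for i, c in enumerate(grid.chroms)}
    for row, (chrom, pos, strand) in enumerate(zip(a["chrom"], a["pos"], a.get("strand", pd.Series(["+"] * len(a))))):
        if chrom not in chrom_idx:
            continue
        ci = chrom_idx[chrom]
        nb = grid.n_bins_per_chrom[ci]
        center = int(pos) // W
        cols = center + offsets
        ok = (cols >= 0) & (cols < nb)
        vals = np.full(offsets.size, np.nan)
        vals[ok] = signal.values[grid.offsets[ci] + cols[ok]] / norm
        if strand == "-":
            vals = vals[::-1]
        mat[row] = vals
    return AlignmentMatrix(mat, offsets * W, a["score"].to_numpy(), a, norm)


def _block_mean(m: np.ndarray, n_blocks: int, axis: int) -> np.ndarray:
    size = m.shape[axis]
    n_blocks = min(n_blocks, size)
    splits = np.array_split(np.arange(size), n_blocks)
    parts = [np.nanmean(np.take(m, idx, axis=axis), axis=axis) for idx in splits]
    return np.stack(parts, axis=axis)


def pixelate(
    matrix: AlignmentMatrix, n_pixels: int = 200, return_counts: bool = False
):
    """Block-average rows (in score order) and columns to <= n_pixels each.

    Undefined cells are ignored within each block; blocks that are entirely
    undefined stay nan. No upsampling: fewer source rows than pixels give
    that many pixel rows. With ``return_counts`` the per-pixel defined-cell
    counts come back too; weighting pixels by them reproduces the global
    defined-cell mean of the source matrix exactly.
    """
    m = matrix.matrix
    if m.shape[0] < 1:
        raise ValueError("empty matrix")
    ok = np.isfinite(m)
    total = np.where(ok, m, 0.0)

    def block_sum(a, n_blocks, axis):
        size = a.shape[axis]
        splits = np.array_split(np.arange(size), min(n_blocks, size))
        parts = [np.take(a, idx, axis=axis).sum(axis=axis) for idx in splits]
        return np.stack(parts, axis=axis)

    sums = block_sum(block_sum(total, n_pixels, 0), n_pixels, 1)
    counts = block_sum(block_sum(ok.astype(float), n_pixels, 0), n_pixels, 1)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if return_counts:
        return out, counts
    return out


def quartile_median_profiles(matrix: AlignmentMatrix) -> np.ndarray:
    """Column-wise median profile per score quartile (4 x n_offsets).

    Rows are already in score order; they are split into four contiguous
    equal-count groups (remainders go to the lower quartiles). Undefined
    cells are ignored in the medians.
    """
    m = matrix.matrix
    if m.shape[0] < 4:
        raise ValueError("need >= 4 anchors for quartiles")
    groups = np.array_split(np.arange(m.shape[0]), 4)
    with np.errstate(invalid="ignore"):
        return np.stack([np.nanmedian(m[g], axis=0) for g in groups])
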