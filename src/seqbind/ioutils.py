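"""Readers and writers for the plain-text genomics formats used here.

bedGraph and BED are thin tab-separated tables handled through pandas;
FASTA reading goes through pyfaidx (any mapping of chromosome name to
sequence is accepted by the track functions), writing is plain 60-column
text. Undefined bins are omitted from bedGraph output and reappear as
``nan`` on read against a grid.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .tracks import BinGrid, MaskTrack, SignalTrack


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write defined bins as chrom/start/end/value lines."""
    grid = track.grid
    with open(path, "w") as fh:
        for chrom in grid.chroms:
            sl = grid.chrom_slice(chrom)
            vals = track.values[sl]
            starts = grid.bin_starts(chrom)
            for s, v in zip(starts, vals):
                if np.isfinite(v):
                    fh.write(f"{chrom}\t{s}\t{s + grid.width}\t{v:.6g}\n")


def read_bedgraph(path, grid: BinGrid) -> SignalTrack:
    """Project a bedGraph onto a grid; uncovered bins become undefined.

    Each bedGraph interval is assigned to the bins it overlaps, weighting
    by overlap length when intervals are coarser than the grid.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    num = np.zeros(grid.n_bins)
    den = np.zeros(grid.n_bins)
    W = grid.width
    for ci, chrom in enumerate(grid.chroms):
        sub = df[df["chrom"] == chrom]
        if sub.empty:
            continue
        nb = grid.n_bins_per_chrom[ci]
        off = grid.offsets[ci]
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            b_lo = max(0, int(s) // W)
            b_hi = min(nb, -(-int(e) // W))
            for b in range(b_lo, b_hi):
                ov = min(int(e), (b + 1) * W) - max(int(s), b * W)
                num[off + b] += ov * v
                den[off + b] += ov
    with np.errstate(invalid="ignore"):
        vals = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return SignalTrack(grid, vals)


def write_bed(intervals: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in intervals]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, names=("chrom", "start", "end")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    df.columns = list(names)[: df.shape[1]] + [
        f"col{i}" for i in range(len(names), df.shape[1])
    ]
    return df


def write_mask_bed(mask: MaskTrack, path) -> None:
    from .simulate import _bins_to_intervals  # local to avoid cycle

    write_bed(_bins_to_intervals(mask.grid, mask.values), path)
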