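"""Binned methylation level and methylation-density tracks.

Per-cytosine calls carry the counts ``n_m`` (reads supporting methylation)
and ``n_tot`` (covering reads) at a genomic position. The binned level is
the coverage-weighted average of per-site levels, i.e. sum(n_m)/sum(n_tot)
over the sites of a bin, which down-weights poorly covered sites. The
methylation density mCpG% of a bin is the product of its level and its CpG
density; mCpH% analogously for the pooled non-CpG (CH) contexts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import BinGrid, FeatureTable, SignalTrack

_CONTEXTS = ("CG", "CH")


@dataclass
class SiteCalls:
    """Per-cytosine methylation calls (0-based positions, CG/CH contexts)."""

    frame: pd.DataFrame  # columns: chrom, pos, strand, context, n_m, n_tot

    def __post_init__(self):
        df = self.frame
        required = {"chrom", "pos", "strand", "context", "n_m", "n_tot"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"site table missing columns {sorted(missing)}")
        bad = df.index[df["n_m"].to_numpy() > df["n_tot"].to_numpy()]
        if len(bad):
            r = df.loc[bad[0]]
            raise ValueError(
                f"n_m > n_tot at {r['chrom']}:{r['pos']} "
                f"({r['n_m']} > {r['n_tot']})"
            )
        unknown = set(df["context"].unique()) - set(_CONTEXTS)
        if unknown:
            raise ValueError(f"unknown contexts {sorted(unknown)}; expected CG/CH")

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, context: str) -> pd.DataFrame:
        return self.frame[self.frame["context"] == context]


def read_cytosine_report(path) -> SiteCalls:
    """Read a Bismark-style cytosine report.

    Tab-delimited columns: chromosome, 1-based position, strand, methylated
    count, unmethylated count, context (CG/CHG/CHH). Positions convert to
    0-based; CHG and CHH collapse to the pooled CH context.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "pos1", "strand", "count_m", "count_u", "context"],
        dtype={"chrom": str, "context": str},
    )
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos1"] - 1,
            "strand": df["strand"],
            "context": df["context"].map(lambda c: "CG" if c == "CG" else "CH"),
            "n_m": df["count_m"],
            "n_tot": df["count_m"] + df["count_u"],
        }
    )
    return SiteCalls(out)


def write_cytosine_report(sites: SiteCalls, path) -> None:
    df = sites.frame
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos1": df["pos"] + 1,
            "strand": df["strand"],
            "count_m": df["n_m"],
            "count_u": df["n_tot"] - df["n_m"],
            "context": df["context"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def bin_methylation_level(
    sites: SiteCalls, grid: BinGrid, context: str = "CG"
) -> SignalTrack:
    """Coverage-weighted methylation level per bin: sum(n_m)/sum(n_tot).

    Sites on either strand contribute to the bin containing their position;
    bins with no covered site of the requested context are undefined. Sites
    falling in a chromosome's dropped partial tail bin are ignored.
    """
    if context not in _CONTEXTS:
        raise ValueError(f"context must be one of {_CONTEXTS}")
    df = sites.subset(context)
    num = np.zeros(grid.n_bins)
    den = np.zeros(grid.n_bins)
    for ci, chrom in enumerate(grid.chroms):
        sub = df[df["chrom"] == chrom]
        if sub.empty:
            continue
        b = sub["pos"].to_numpy() // grid.width
        keep = b < grid.n_bins_per_chrom[ci]
        b = b[keep] + grid.offsets[ci]
        num += np.bincount(b, weights=sub["n_m"].to_numpy()[keep], minlength=grid.n_bins)
        den += np.bincount(b, weights=sub["n_tot"].to_numpy()[keep], minlength=grid.n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    return SignalTrack(grid, level)


def methylation_density(
    level: SignalTrack, features: FeatureTable, context: str = "CpG"
) -> SignalTrack:
    """Methylation density f_m(i) = l(i) * f_context(i).

    Bins with zero context density are defined to have zero methylation
    density even when the level is undefined there; bins with context
    present but no coverage stay undefined.
    """
    if context == "CpG":
        f_ctx = features.f_cpg
    elif context == "CpH":
        f_ctx = features.f_cph
    else:
        raise ValueError("context must be 'CpG' or 'CpH'")
    if level.grid != features.grid:
        raise ValueError("level and features must share a grid")
    out = level.values * f_ctx
    out[np.nan_to_num(f_ctx, nan=-1.0) == 0.0] = 0.0
    out[~features.defined] = np.nan
    return SignalTrack(level.grid, out)
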