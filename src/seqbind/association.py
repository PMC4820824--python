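"""Marginal/partial correlations and spatial statistics on binned tracks.

These are the tools used to dissect how a binding signal relates to base
composition once the strong genome-wide coupling between GC%, CpG% and
methylation density is taken into account: plain Pearson correlations,
partial correlations (formula and residual-regression paths), conditional
mean maps over the (GC%, CpG%) plane, peak-versus-flank contrasts, and
auto-/cross-correlation of tracks along the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import FeatureTable, MaskTrack, SignalTrack


def _joint_values(tracks: Sequence[SignalTrack], mask: MaskTrack | None):
    ok = np.ones(tracks[0].grid.n_bins, dtype=bool)
    for t in tracks:
        if t.grid != tracks[0].grid:
            raise ValueError("tracks must share a grid")
        ok &= t.defined
    if mask is not None:
        ok &= ~mask.values
    return [t.values[ok] for t in tracks], int(ok.sum())


def pearson_correlation(
    x: SignalTrack, y: SignalTrack, mask: MaskTrack | None = None
) -> tuple[float, int]:
    """Product-moment correlation over jointly defined, unmasked bins."""
    (xv, yv), n = _joint_values([x, y], mask)
    if n < 3:
        raise ValueError(f"need >= 3 jointly defined bins, have {n}")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(xv, yv)[0, 1])
    return r, n


def partial_correlation(
    x: SignalTrack,
    y: SignalTrack,
    controls: Sequence[SignalTrack] = (),
    mask: MaskTrack | None = None,
    method: str = "residual",
) -> tuple[float, int]:
    """Correlation of x and y after removing linear dependence on controls.

    With no controls this reduces to the Pearson correlation. With a single
    control the recursion formula
    ``r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))``
    and the residual-regression path agree; with several controls the
    correlation of least-squares residuals is used.
    """
    controls = list(controls)
    if not controls:
        return pearson_correlation(x, y, mask)
    vals, n = _joint_values([x, y, *controls], mask)
    if n < len(controls) + 3:
        raise ValueError(f"need >= {len(controls) + 3} jointly defined bins, have {n}")
    xv, yv, zs = vals[0], vals[1], vals[2:]
    if method == "formula":
        if len(controls) != 1:
            raise ValueError("formula path is defined for exactly one control")
        z = zs[0]
        r_xy = np.corrcoef(xv, yv)[0, 1]
        r_xz = np.corrcoef(xv, z)[0, 1]
        r_yz = np.corrcoef(yv, z)[0, 1]
        if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
            raise ValueError("degenerate control: perfectly correlated with x or y")
        r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        return float(r), n
    if method != "residual":
        raise ValueError("method must be 'residual' or 'formula'")
    Z = np.column_stack([np.ones(n)] + zs)
    for j, z in enumerate(zs):
        for v, name in ((xv, "x"), (yv, "y")):
            r = abs(np.corrcoef(v, z)[0, 1])
            if r >= 1.0 - 1e-12:
                raise ValueError(f"degenerate control #{j}: |r| = 1 with {name}")
    rx = xv - Z @ np.linalg.lstsq(Z, xv, rcond=None)[0]
    ry = yv - Z @ np.linalg.lstsq(Z, yv, rcond=None)[0]
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero residual variance after removing controls")
    return float(np.corrcoef(rx, ry)[0, 1]), n


@dataclass
class ConditionalMap:
    """Per-cell mean signal over a (f_GC, f_CpG) grid."""

    gc_edges: np.ndarray
    cpg_edges: np.ndarray
    mean: np.ndarray  # (n_gc, n_cpg), nan where masked
    count: np.ndarray
    density: np.ndarray
    masked: np.ndarray  # True where count < min_count

    def to_frame(self) -> pd.DataFrame:
        gc_mid = 0.5 * (self.gc_edges[:-1] + self.gc_edges[1:])
        cpg_mid = 0.5 * (self.cpg_edges[:-1] + self.cpg_edges[1:])
        gg, cc = np.meshgrid(gc_mid, cpg_mid, indexing="ij")
        return pd.DataFrame(
            {
                "f_gc": gg.ravel(),
                "f_cpg": cc.ravel(),
                "mean": self.mean.ravel(),
                "count": self.count.ravel(),
                "density": self.density.ravel(),
            }
        )


def conditional_enrichment_map(
    features: FeatureTable,
    signal: SignalTrack,
    gc_res: float = 0.02,
    cpg_res: float = 0.01,
    min_count: int = 50,
    mask: MaskTrack | None = None,
) -> ConditionalMap:
    """Average a (mean-normalized) signal within (f_GC, f_CpG) cells.

    Cells observed fewer than ``min_count`` times are masked; the density
    layer is the empirical measure of windows over the plane. A signal whose
    genome-wide mean is far from 1 triggers a warning through the returned
    object's provenance rather than an error (the contract asks for
    mean-normalized input).
    """
    vals, n = _joint_values([features.gc_track(), features.cpg_track(), signal], mask)
    if n == 0:
        raise ValueError("no jointly defined windows")
    gc, cpg, sig = vals
    gc_edges = np.arange(0.0, 1.0 + gc_res, gc_res)
    cpg_edges = np.arange(0.0, 0.5 + cpg_res, cpg_res)
    gi = np.clip(np.searchsorted(gc_edges, gc, side="right") - 1, 0, len(gc_edges) - 2)
    ci = np.clip(np.searchsorted(cpg_edges, cpg, side="right") - 1, 0, len(cpg_edges) - 2)
    shape = (len(gc_edges) - 1, len(cpg_edges) - 1)
    flat = gi * shape[1] + ci
    count = np.bincount(flat, minlength=shape[0] * shape[1]).reshape(shape)
    total = np.bincount(flat, weights=sig, minlength=shape[0] * shape[1]).reshape(shape)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    masked = count < min_count
    mean = np.where(masked, np.nan, mean)
    cm = ConditionalMap(gc_edges, cpg_edges, mean, count, count / n, masked)
    cm.signal_mean = float(np.mean(sig))  # ~1 expected for normalized input
    return cm


@dataclass
class ContrastResult:
    """Peak-versus-flank contrast of a signal."""

    per_peak: pd.DataFrame  # chrom, start, end, peak_mean, flank_mean
    fold: float  # mean(peak means) / mean(flank means)
    fraction_peak_higher: float
    p_value: float  # two-sided Wilcoxon rank-sum
    n_peaks: int
    n_dropped: int


def _merge_intervals(peaks: pd.DataFrame) -> pd.DataFrame:
    out = []
    for chrom, sub in peaks.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def peak_flank_contrast(
    peaks: pd.DataFrame,
    signal: SignalTrack,
    flank_width: int | None = None,
    mask: MaskTrack | None = None,
) -> ContrastResult:
    """Mean signal inside peaks versus their two flanks.

    Peaks are merged first. Each flank extends ``flank_width`` bp (default:
    the peak's own width) and is clipped at chromosome ends and at the
    neighbouring merged peaks. Per-peak means average the defined, unmasked
    bins whose midpoint lies in the interval; peaks with no usable bin are
    dropped (counted). The rank-sum test compares the per-peak and per-flank
    mean sets two-sidedly.
    """
    grid = signal.grid
    merged = _merge_intervals(peaks)
    vals = signal.values.copy()
    if mask is not None:
        vals = np.where(mask.values, np.nan, vals)
    rows = []
    n_dropped = 0
    for chrom, sub in merged.groupby("chrom", sort=False):
        if chrom not in grid.chroms:
            continue
        ci = grid.chroms.index(chrom)
        nb = grid.n_bins_per_chrom[ci]
        size = nb * grid.width
        sl = grid.chrom_slice(chrom)
        v = vals[sl]
        mids = grid.bin_starts(chrom) + grid.width / 2
        sub = sub.sort_values("start").reset_index(drop=True)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for j in range(len(sub)):
            s, e = int(starts[j]), int(ends[j])
            fw = int(flank_width) if flank_width is not None else (e - s)
            lf_lo = max(0, s - fw, ends[j - 1] if j > 0 else 0)
            rt_hi = min(size, e + fw, starts[j + 1] if j + 1 < len(sub) else size)
            in_peak = (mids >= s) & (mids < e)
            in_flank = ((mids >= lf_lo) & (mids < s)) | ((mids >= e) & (mids < rt_hi))
            pv = v[in_peak]
            fv = v[in_flank]
            pv = pv[np.isfinite(pv)]
            fv = fv[np.isfinite(fv)]
            if pv.size == 0 or fv.size == 0:
                n_dropped += 1
                continue
            rows.append((chrom, s, e, float(pv.mean()), float(fv.mean())))
    per_peak = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "peak_mean", "flank_mean"]
    )
    if per_peak.empty:
        raise ValueError("no peaks with defined signal")
    pk = per_peak["peak_mean"].to_numpy()
    fl = per_peak["flank_mean"].to_numpy()
    fold = float(pk.mean() / fl.mean()) if fl.mean() != 0 else np.inf
    frac = float((pk > fl).mean())
    p = float(stats.ranksums(pk, fl).pvalue)
    return ContrastResult(per_peak, fold, frac, p, len(per_peak), n_dropped)


@dataclass
class AcfResult:
    lags_bp: np.ndarray
    rho: np.ndarray
    hwhm_bp: float
    is_lower_bound: bool  # True when rho never crossed half maximum


def autocorrelation_hwhm(
    signal: SignalTrack, max_lag: int = 50, mask: MaskTrack | None = None
) -> AcfResult:
    """Half width at half maximum of the track autocorrelation, in bp.

    The autocovariance is pooled across chromosomes at each bin lag using
    all jointly defined pairs (masked bins excluded pairwise) around the
    global mean; the HWHM is the linearly interpolated lag at which the
    normalized autocorrelation first crosses 1/2.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1 bin")
    grid = signal.grid
    vals = signal.values.copy()
    if mask is not None:
        vals = np.where(mask.values, np.nan, vals)
    mu = np.nanmean(vals)
    cov = np.zeros(max_lag + 1)
    cnt = np.zeros(max_lag + 1)
    for chrom in grid.chroms:
        v = vals[grid.chrom_slice(chrom)] - mu
        ok = np.isfinite(v)
        v0 = np.where(ok, v, 0.0)
        for lag in range(0, max_lag + 1):
            if lag >= v.size:
                break
            a, b = v0[: v.size - lag], v0[lag:]
            pair = ok[: v.size - lag] & ok[lag:]
            cov[lag] += np.sum(a * b * pair)
            cnt[lag] += pair.sum()
    if cnt[0] == 0 or cov[0] <= 0:
        raise ValueError("undefined autocovariance at lag 0")
    rho = (cov / np.maximum(cnt, 1)) / (cov[0] / cnt[0])
    below = np.flatnonzero(rho < 0.5)
    W = grid.width
    lags_bp = np.arange(max_lag + 1) * W
    if below.size == 0:
        return AcfResult(lags_bp, rho, float(max_lag * W), True)
    k = int(below[0])
    # linear interpolation between lag k-1 and k
    r0, r1 = rho[k - 1], rho[k]
    frac = (r0 - 0.5) / (r0 - r1) if r0 != r1 else 0.0
    return AcfResult(lags_bp, rho, float((k - 1 + frac) * W), False)


@dataclass
class XcorrResult:
    offsets_bp: np.ndarray
    r: np.ndarray
    argmax_bp: int
    r_max: float


def cross_correlation(
    a: SignalTrack, b: SignalTrack, max_offset: int = 20, mask: MaskTrack | None = None
) -> XcorrResult:
    """Normalized cross-correlation of two tracks per signed bin offset."""
    if a.grid != b.grid:
        raise ValueError("tracks must share a grid")
    grid = a.grid
    av = a.values.copy()
    bv = b.values.copy()
    if mask is not None:
        av = np.where(mask.values, np.nan, av)
        bv = np.where(mask.values, np.nan, bv)
    offsets = np.arange(-max_offset, max_offset + 1)
    rs = np.zeros(offsets.size)
    for oi, off in enumerate(offsets):
        xs, ys = [], []
        for chrom in grid.chroms:
            x = av[grid.chrom_slice(chrom)]
            y = bv[grid.chrom_slice(chrom)]
            if off >= 0:
                x1, y1 = x[: x.size - off] if off else x, y[off:]
            else:
                x1, y1 = x[-off:], y[: y.size + off]
            ok = np.isfinite(x1) & np.isfinite(y1)
            xs.append(x1[ok])
            ys.append(y1[ok])
        xv = np.concatenate(xs)
        yv = np.concatenate(ys)
        if xv.size < 3 or np.std(xv) == 0 or np.std(yv) == 0:
            raise ValueError(f"degenerate data at offset {off}")
        rs[oi] = np.corrcoef(xv, yv)[0, 1]
    k = int(np.argmax(rs))
    return XcorrResult(offsets * grid.width, rs, int(offsets[k] * grid.width), float(rs[k]))
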