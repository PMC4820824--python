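"""Synthetic genomes, sequencing tracks, methylation calls and expression.

Every generator is a pure function of its configuration (and the seed
inside it); each output stream draws from its own RNG seeded as
``seed + fixed offset`` so files are independently reproducible.

The generative model, in outline:

* Genome — per-window GC targets follow a stationary AR(1) process on the
  logit scale with autocorrelation length ``gc_corr_length``, clamped to
  [0.2, 0.8]; bases are drawn independently per position at the local GC
  target, then extra CpG dinucleotides are implanted at a rate that grows
  with local GC (``cpg_coupling``), coupling CpG density to GC density
  beyond the pure product effect. ``cpg_coupling=0`` gives exactly
  independent base placement.
* ChIP/Input/MNase — ChIP and Input share a lognormal background rate
  ``lambda_i`` per bin; Input ~ Poisson(lambda_i), ChIP ~
  Poisson((lambda_i + e_i)/upsilon_true) with enrichment e_i > 0 only in
  peak bins and a linear function of the window's *realized* GC%, so that
  CpG% is conditionally independent of ChIP given GC% by construction.
  MNase is Poisson with rate exp(gamma * (GC% - mean)), normalized to its
  target depth. Peaks are either the top-GC runs of the genome
  (``peak_placement='gc'``, sequence-predictable, used by the
  Random-Forest experiment) or runs placed uniformly at random
  (``'random'``, used by the conditional-independence construction, which
  keeps E[ChIP | GC%] exactly linear).
* Methylation — every genomic cytosine in CpG context is emitted on both
  strands with Poisson coverage and Binomial methylated counts at a
  region-dependent level: ~70% background, hypomethylated
  promoter-proximal CpG islands, hypermethylated distal islands; CH
  context sites carry a low uniform level.
* Expression — per-gene log2(WT/KO) fold change is a linear function of
  promoter binding and log10 gene length plus noise whose variance depends
  on expression level; optional planted annotation terms receive an
  additional mean shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .methylation import SiteCalls
from .tracks import (
    C,
    G,
    BinGrid,
    FeatureTable,
    FragmentSet,
    SignalTrack,
    decode_sequence,
    make_bins,
)

# fixed per-stream seed offsets
_GENOME, _CHIP, _METH, _EXPR, _GENES, _MAPP = 11, 23, 37, 53, 71, 89


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic data generator.

    Defaults describe a small two-chromosome genome with mouse-like base
    composition (GC ~42%), a background-dominated ChIP experiment with the
    scaling factor 4.41 between Input and ChIP background rates, 70%
    background CpG methylation with hypo-/hyper-methylated proximal/distal
    CpG islands, and a null expression experiment (no planted effects).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_500_000
    bin_width: int = 150
    rf_window: int = 200
    # genome composition
    gc_mean: float = 0.42
    gc_sd: float = 0.07
    gc_corr_length: int = 1_000
    cpg_coupling: float = 4.0
    # ChIP experiment
    upsilon_true: float = 4.41
    enrich_fold: float = 8.0  # mean peak enrichment, multiples of depth_input
    enrich_beta: float = 8.0  # GC% slope of enrichment, same units per GC unit
    peak_fraction: float = 0.1
    peak_placement: str = "gc"  # 'gc' (top-GC runs) or 'random'
    peak_run_bins: int = 20
    depth_input: float = 10.0
    depth_mnase: float = 10.0
    background_sigma: float = 0.5  # lognormal sigma of shared background rate
    mnase_gamma: float = 3.0  # calibrated so r(MNase, GC%) ~ 0.6
    # methylation
    meth_background: float = 0.70
    meth_cgi_proximal: float = 0.10
    meth_cgi_distal: float = 0.90
    meth_ch: float = 0.02
    site_coverage_mean: float = 10.0
    cgi_fraction_of_genes: float = 0.5
    cgi_genome_fraction: float = 0.04  # cap on total island bp, both kinds
    # expression
    n_genes: int = 3_000
    n_go_terms: int = 50
    binding_effect: float = 0.0
    length_effect: float = 0.0
    planted_go_effect: float = 0.0
    planted_term_size: int = 50
    noise_sd_floor: float = 0.5  # fold-change noise sd at the typical expression

    def __post_init__(self):
        for name in (
            "gc_mean",
            "peak_fraction",
            "meth_background",
            "meth_cgi_proximal",
            "meth_cgi_distal",
            "meth_ch",
            "cgi_fraction_of_genes",
            "cgi_genome_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.upsilon_true <= 0:
            raise ValueError("upsilon_true must be > 0")
        if self.chrom_length < self.bin_width:
            raise ValueError("chrom_length smaller than bin_width")
        if self.chrom_length % self.bin_width != 0:
            raise ValueError("bin_width must divide chrom_length")
        if self.peak_placement not in ("gc", "random"):
            raise ValueError("peak_placement must be 'gc' or 'random'")
        if self.n_genes < 10 * self.n_go_terms:
            warnings.warn(
                f"n_genes={self.n_genes} < 10 * n_go_terms={self.n_go_terms}: "
                "annotation terms may be undersized",
                stacklevel=2,
            )

    @property
    def depth_chip(self) -> float:
        """Expected background ChIP fragments per bin (derived)."""
        return self.depth_input / self.upsilon_true

    @classmethod
    def ci_construction(cls, seed: int = 0, n_bins: int = 100_000) -> "SimConfig":
        """The conditional-independence construction.

        Enrichment covers the whole genome and is linear in realized window
        GC%, so that CpG% is independent of ChIP given GC% *and* the
        dependence removed by a partial correlation is exactly linear.
        """
        length = (n_bins // 2) * 150
        return cls(
            seed=seed,
            n_chroms=2,
            chrom_length=length,
            peak_fraction=1.0,
            peak_placement="random",
            enrich_fold=5.0,
            enrich_beta=10.0,
        )

    @classmethod
    def rf_construction(cls, seed: int = 0, n_windows: int = 40_000) -> "SimConfig":
        """GC-driven enrichment on the 200 bp prediction grid.

        Peaks are the top-GC runs of a smoothly varying genome, so binding
        is predictable from window base composition alone.
        """
        length = (n_windows // 2) * 200
        return cls(
            seed=seed,
            n_chroms=2,
            chrom_length=length,
            bin_width=200,
            gc_corr_length=2_000,
            gc_sd=0.08,
            peak_placement="gc",
            peak_fraction=0.1,
            depth_input=30.0,
        )


@dataclass
class SimGenome:
    """Simulated genome: coded sequences plus the per-bin GC target."""

    chroms: dict[str, np.ndarray]  # uint8 base codes
    grid: BinGrid
    gc_target: np.ndarray  # per bin, on `grid`

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chroms.items()}

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.chroms[chrom]

    def sequences(self) -> dict[str, str]:
        return {c: decode_sequence(s) for c, s in self.chroms.items()}


@dataclass
class SimTruth:
    """Planted ground truth of a simulated ChIP experiment."""

    upsilon_true: float
    lam: np.ndarray  # shared background rate per bin
    enrichment: np.ndarray  # e_i, > 0 only in peak bins
    peak_bins: np.ndarray  # bool per bin
    chip_rate: np.ndarray  # (lam + e) / upsilon
    mnase_rate: np.ndarray
    cpg_independent_given_gc: bool = True
    # filled by simulate_expression
    gene_log2fc: pd.Series | None = None
    planted_terms: list[str] = field(default_factory=list)


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    z = np.empty(n)
    z[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        z[i] = rho * z[i - 1] + innov[i - 1]
    return z


def simulate_genome(config: SimConfig) -> SimGenome:
    """Draw the genome sequence and per-bin GC targets."""
    rng = np.random.default_rng(config.seed + _GENOME)
    W = config.bin_width
    nb_per = config.chrom_length // W
    rho = float(np.exp(-W / config.gc_corr_length))
    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    grid = make_bins(sizes, W)
    chroms: dict[str, np.ndarray] = {}
    gc_target = np.empty(grid.n_bins)
    mu = logit(config.gc_mean)
    scale = config.gc_sd / (config.gc_mean * (1.0 - config.gc_mean))

    for ci, chrom in enumerate(grid.chroms):
        z = _ar1(rng, nb_per, rho)
        g = np.clip(expit(mu + scale * z), 0.2, 0.8)
        gc_target[grid.chrom_slice(chrom)] = g
        g_base = np.repeat(g, W)
        L = config.chrom_length
        # iid draw at local GC target: order A, C, G, T
        u = rng.random(L)
        half_at = (1.0 - g_base) / 2.0
        half_gc = g_base / 2.0
        codes = (
            (u >= half_at).astype(np.uint8)
            + (u >= half_at + half_gc)
            + (u >= half_at + 2 * half_gc)
        ).astype(np.uint8)
        # implant CpG dinucleotides at a GC-coupled rate
        if config.cpg_coupling != 0.0:
            boost = np.exp(config.cpg_coupling * (g_base[:-1] - config.gc_mean)) - 1.0
            rate = np.clip((g_base[:-1] / 2.0) ** 2 * boost, 0.0, 0.5)
            mask = rng.random(L - 1) < rate
            mask[1:] &= ~mask[:-1]  # no overlapping implants
            pos = np.flatnonzero(mask)
            codes[pos] = C
            codes[pos + 1] = G
        chroms[chrom] = codes
    return SimGenome(chroms, grid, gc_target)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")


def _peak_bins(
    config: SimConfig, features: FeatureTable, rng: np.random.Generator
) -> np.ndarray:
    grid = features.grid
    n = grid.n_bins
    pf = config.peak_fraction
    if pf == 0.0:
        return np.zeros(n, dtype=bool)
    if pf == 1.0:
        return np.ones(n, dtype=bool)
    if config.peak_placement == "gc":
        sm = np.empty(n)
        for chrom in grid.chroms:
            sl = grid.chrom_slice(chrom)
            g = np.nan_to_num(features.f_gc[sl], nan=config.gc_mean)
            sm[sl] = _smooth(g, config.peak_run_bins)
        thr = np.quantile(sm, 1.0 - pf)
        return sm > thr
    # random placement: non-overlapping runs, uniform starts
    run = config.peak_run_bins
    peaks = np.zeros(n, dtype=bool)
    target = int(round(pf * n))
    placed = 0
    attempts = 0
    while placed < target and attempts < 50 * (target // run + 1):
        attempts += 1
        chrom = grid.chroms[rng.integers(len(grid.chroms))]
        sl = grid.chrom_slice(chrom)
        nb = sl.stop - sl.start
        if nb <= run:
            continue
        s = int(rng.integers(0, nb - run))
        if peaks[sl.start + s : sl.start + s + run].any():
            continue
        peaks[sl.start + s : sl.start + s + run] = True
        placed += run
    return peaks


def _bins_to_intervals(grid: BinGrid, flags: np.ndarray) -> pd.DataFrame:
    rows = []
    W = grid.width
    for chrom in grid.chroms:
        sl = grid.chrom_slice(chrom)
        f = flags[sl]
        d = np.diff(np.concatenate([[0], f.astype(np.int8), [0]]))
        for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
            rows.append((chrom, int(s) * W, int(e) * W))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _counts_to_fragments(grid: BinGrid, counts: np.ndarray) -> FragmentSet:
    """Bin-aligned fragments, one full-bin interval per sampled fragment."""
    W = grid.width
    chroms, starts = [], []
    for chrom in grid.chroms:
        sl = grid.chrom_slice(chrom)
        c = counts[sl].astype(np.int64)
        bs = grid.bin_starts(chrom)
        starts.append(np.repeat(bs, c))
        chroms.append(np.repeat(np.array([chrom], dtype=object), int(c.sum())))
    start = np.concatenate(starts) if starts else np.array([], dtype=np.int64)
    chrom_arr = np.concatenate(chroms) if chroms else np.array([], dtype=object)
    return FragmentSet(chrom_arr, start, start + W)


@dataclass
class ChipSim:
    chip: SignalTrack
    input: SignalTrack
    mnase: SignalTrack
    fragments_chip: FragmentSet
    fragments_input: FragmentSet
    fragments_mnase: FragmentSet
    peaks: pd.DataFrame
    truth: SimTruth


def simulate_chip_experiment(config: SimConfig, features: FeatureTable) -> ChipSim:
    """Draw ChIP, Input and MNase channels over the feature grid."""
    if config.depth_input <= 0 or config.depth_mnase <= 0:
        raise ValueError("channel depths must be positive")
    rng = np.random.default_rng(config.seed + _CHIP)
    grid = features.grid
    n = grid.n_bins
    sig = config.background_sigma
    lam = config.depth_input * rng.lognormal(-0.5 * sig**2, sig, n)
    g = np.nan_to_num(features.f_gc, nan=config.gc_mean)
    peak_bins = _peak_bins(config, features, rng)
    e = np.zeros(n)
    e[peak_bins] = config.depth_input * np.maximum(
        0.0, config.enrich_fold + config.enrich_beta * (g[peak_bins] - config.gc_mean)
    )
    chip_rate = (lam + e) / config.upsilon_true
    mnase_shape = np.exp(config.mnase_gamma * (g - config.gc_mean))
    mnase_rate = config.depth_mnase * mnase_shape / mnase_shape.mean()

    input_counts = rng.poisson(lam).astype(float)
    chip_counts = rng.poisson(chip_rate).astype(float)
    mnase_counts = rng.poisson(mnase_rate).astype(float)

    truth = SimTruth(
        config.upsilon_true, lam, e, peak_bins, chip_rate, mnase_rate,
        cpg_independent_given_gc=True,
    )
    return ChipSim(
        SignalTrack(grid, chip_counts),
        SignalTrack(grid, input_counts),
        SignalTrack(grid, mnase_counts),
        _counts_to_fragments(grid, chip_counts),
        _counts_to_fragments(grid, input_counts),
        _counts_to_fragments(grid, mnase_counts),
        _bins_to_intervals(grid, peak_bins),
        truth,
    )


def expected_partial_r_gc(truth: SimTruth, features: FeatureTable) -> float:
    """Construction value of partial r(ChIP, GC% | CpG%).

    Conditional on the realized covariates, the only randomness left in the
    ChIP channel is Poisson, so the population moments are available in
    closed form: Cov(ChIP, X) = Cov(rate, X) and Var(ChIP) = Var(rate) +
    mean(rate) over the bins. The partial correlation then follows from the
    first-order recursion formula.
    """
    ok = features.defined
    g = features.f_gc[ok]
    c = features.f_cpg[ok]
    mu = truth.chip_rate[ok]
    var_chip = mu.var() + mu.mean()
    sd_chip = np.sqrt(var_chip)
    r_xg = np.cov(mu, g)[0, 1] / (sd_chip * g.std())
    r_xc = np.cov(mu, c)[0, 1] / (sd_chip * c.std())
    r_gc = np.corrcoef(g, c)[0, 1]
    return float((r_xg - r_xc * r_gc) / np.sqrt((1 - r_xc**2) * (1 - r_gc**2)))


def simulate_genes(config: SimConfig, grid: BinGrid | None = None) -> pd.DataFrame:
    """Gene anchors: TSS position, strand and transcript length."""
    rng = np.random.default_rng(config.seed + _GENES)
    chroms = (
        list(grid.chroms)
        if grid is not None
        else [f"chr{i + 1}" for i in range(config.n_chroms)]
    )
    margin = min(10_000, config.chrom_length // 10)
    chrom = rng.choice(len(chroms), size=config.n_genes)
    tss = rng.integers(margin, config.chrom_length - margin, size=config.n_genes)
    strand = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    length = np.round(10 ** rng.uniform(3.0, 5.0, size=config.n_genes)).astype(int)
    df = pd.DataFrame(
        {
            "gene": [f"gene{i:05d}" for i in range(config.n_genes)],
            "chrom": [chroms[i] for i in chrom],
            "tss": tss,
            "strand": strand,
            "length": length,
        }
    )
    return df.sort_values(["chrom", "tss"], kind="stable").reset_index(drop=True)


@dataclass
class MethSim:
    sites: SiteCalls
    cgis: pd.DataFrame  # chrom, start, end, kind in {proximal, distal}


def simulate_methylation(
    config: SimConfig, genome: SimGenome, genes: pd.DataFrame | None = None
) -> MethSim:
    """Per-cytosine CpG (both strands) and pooled CH calls.

    CpG sites inside promoter-proximal CpG-island intervals are
    hypomethylated, those inside distal islands hypermethylated, everything
    else sits at the background level. Coverage is Poisson per site, so a
    fraction of sites carries no read at all and exercises undefined-bin
    handling downstream.
    """
    rng = np.random.default_rng(config.seed + _METH)
    if genes is None:
        genes = simulate_genes(config, genome.grid)

    cgi_rows = []
    # islands stay a small genomic fraction even at high gene density
    total_bp = sum(genome.chrom_sizes.values())
    budget = int(config.cgi_genome_fraction * total_bp / (2 * 900))
    n_prox = min(int(len(genes) * config.cgi_fraction_of_genes), budget)
    chosen = genes.iloc[
        np.sort(rng.choice(len(genes), size=n_prox, replace=False))
    ]
    tss_by_chrom = {c: sub["tss"].to_numpy() for c, sub in genes.groupby("chrom")}
    for _, r in chosen.iterrows():
        half = int(rng.integers(150, 750))
        s = max(0, int(r["tss"]) - half)
        e = min(genome.chrom_sizes[r["chrom"]], int(r["tss"]) + half)
        cgi_rows.append((r["chrom"], s, e, "proximal"))
    n_dist = n_prox
    placed = 0
    while placed < n_dist:
        chrom = list(genome.chroms)[rng.integers(len(genome.chroms))]
        size = genome.chrom_sizes[chrom]
        half = int(rng.integers(150, 750))
        center = int(rng.integers(half, size - half))
        tss = tss_by_chrom.get(chrom, np.array([]))
        if tss.size and np.min(np.abs(tss - center)) < 2_000:
            continue  # keep distal islands away from promoters
        cgi_rows.append((chrom, center - half, center + half, "distal"))
        placed += 1
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end", "kind"])

    frames = []
    for chrom, codes in genome.chroms.items():
        is_cpg_start = (codes[:-1] == C) & (codes[1:] == G)
        pos_c = np.flatnonzero(is_cpg_start)  # plus-strand C
        pos_g = pos_c + 1  # minus-strand C (a G on plus)
        is_ch = (codes[:-1] == C) & ~is_cpg_start
        pos_ch_plus = np.flatnonzero(is_ch)
        prev_c = np.zeros(len(codes), dtype=bool)
        prev_c[1:] = codes[:-1] == C
        pos_ch_minus = np.flatnonzero((codes == G) & ~prev_c)

        level = np.full(len(codes), config.meth_background)
        for _, r in cgis[cgis["chrom"] == chrom].iterrows():
            level[int(r["start"]) : int(r["end"])] = (
                config.meth_cgi_proximal
                if r["kind"] == "proximal"
                else config.meth_cgi_distal
            )
        for pos, strand, ctx, pi in (
            (pos_c, "+", "CG", level[pos_c]),
            (pos_g, "-", "CG", level[pos_c]),  # both strands share the site level
            (pos_ch_plus, "+", "CH", np.full(pos_ch_plus.size, config.meth_ch)),
            (pos_ch_minus, "-", "CH", np.full(pos_ch_minus.size, config.meth_ch)),
        ):
            n_tot = rng.poisson(config.site_coverage_mean, pos.size)
            n_m = rng.binomial(n_tot, pi)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "strand": strand,
                        "context": ctx,
                        "n_m": n_m,
                        "n_tot": n_tot,
                    }
                )
            )
    sites = pd.concat(frames, ignore_index=True)
    sites = sites.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(
        drop=True
    )
    return MethSim(SiteCalls(sites), cgis)


@dataclass
class ExprSim:
    expression: pd.DataFrame
    annotation: pd.DataFrame  # gene, term
    truth: SimTruth


def promoter_mean_signal(
    genes: pd.DataFrame, signal: SignalTrack, window: int = 500
) -> np.ndarray:
    """Mean signal over the first ``window`` bp downstream of each TSS."""
    grid = signal.grid
    out = np.full(len(genes), np.nan)
    for i, (chrom, tss, strand) in enumerate(
        zip(genes["chrom"], genes["tss"], genes["strand"])
    ):
        if chrom not in grid.chroms:
            continue
        if strand == "-":
            lo, hi = int(tss) - window, int(tss)
        else:
            lo, hi = int(tss), int(tss) + window
        ci = grid.chroms.index(chrom)
        b_lo = max(0, lo // grid.width)
        b_hi = min(grid.n_bins_per_chrom[ci], -(-hi // grid.width))
        if b_hi <= b_lo:
            continue
        vals = signal.values[grid.offsets[ci] + b_lo : grid.offsets[ci] + b_hi]
        if np.isfinite(vals).any():
            out[i] = np.nanmean(vals)
    return out


def simulate_expression(
    config: SimConfig,
    binding: SignalTrack | None,
    genes: pd.DataFrame,
    truth: SimTruth | None = None,
) -> ExprSim:
    """Expression table, annotation, and the planted differential truth."""
    rng = np.random.default_rng(config.seed + _EXPR)
    ng = len(genes)
    x = rng.normal(3.0, 2.0, ng)  # log2 geometric-mean FPKM
    sigma2 = config.noise_sd_floor**2 * (1.0 + ((x - 3.0) / 4.0) ** 2)

    if binding is not None and config.binding_effect != 0.0:
        b = promoter_mean_signal(genes, binding)
        b = np.nan_to_num(b, nan=np.nanmean(b))
        bz = (b - b.mean()) / (b.std() if b.std() > 0 else 1.0)
    else:
        bz = np.zeros(ng)
    loglen = np.log10(genes["length"].to_numpy())
    lfc = (
        config.binding_effect * bz
        + config.length_effect * (loglen - loglen.mean())
        + rng.normal(0.0, np.sqrt(sigma2))
    )

    terms = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms)]
    ann_rows = []
    planted: list[str] = []
    gene_ids = genes["gene"].to_numpy()
    start_term = 0
    if config.planted_go_effect != 0.0 and config.n_go_terms >= 1:
        members = rng.choice(ng, size=min(config.planted_term_size, ng), replace=False)
        lfc[members] += config.planted_go_effect
        ann_rows.extend((gene_ids[m], terms[0]) for m in members)
        planted.append(terms[0])
        start_term = 1
    for t in range(start_term, config.n_go_terms):
        size = int(rng.integers(10, 61))
        members = rng.choice(ng, size=min(size, ng), replace=False)
        ann_rows.extend((gene_ids[m], terms[t]) for m in members)
    annotation = pd.DataFrame(ann_rows, columns=["gene", "term"])

    fpkm_wt = 2.0 ** (x + lfc / 2.0)
    fpkm_ko = 2.0 ** (x - lfc / 2.0)
    expr = pd.DataFrame(
        {
            "gene": gene_ids,
            "fpkm_wt": fpkm_wt,
            "fpkm_ko": fpkm_ko,
            "log2fc": lfc,
            "significant": np.abs(lfc) > 1.0,
            "length": genes["length"].to_numpy(),
        }
    )
    if truth is None:
        truth = SimTruth(
            config.upsilon_true,
            np.array([]),
            np.array([]),
            np.array([], dtype=bool),
            np.array([]),
            np.array([]),
        )
    truth.gene_log2fc = pd.Series(lfc, index=gene_ids)
    truth.planted_terms = planted
    return ExprSim(expr, annotation, truth)


def simulate_mappability(
    config: SimConfig, chrom_sizes: Mapping[str, int], width: int = 1_000
) -> SignalTrack:
    """Mappability on a coarse grid: mostly 1.0 with a few low-value runs."""
    rng = np.random.default_rng(config.seed + _MAPP)
    grid = make_bins(chrom_sizes, width)
    vals = np.ones(grid.n_bins)
    n_runs = max(1, grid.n_bins // 500)
    for _ in range(n_runs):
        chrom = grid.chroms[rng.integers(len(grid.chroms))]
        sl = grid.chrom_slice(chrom)
        nb = sl.stop - sl.start
        run = int(rng.integers(10, 20))
        if nb <= run:
            continue
        s = int(rng.integers(0, nb - run))
        vals[sl.start + s : sl.start + s + run] = rng.uniform(0.0, 0.3)
    return SignalTrack(grid, vals)


def with_options(config: SimConfig, **kwargs) -> SimConfig:
    """A copy of the configuration with fields replaced."""
    return replace(config, **kwargs)
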