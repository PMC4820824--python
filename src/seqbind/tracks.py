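"""Genome binning, sequence features, fragment coverage, and masking.

All coordinates are 0-based half-open internally. A genome is tiled with
non-overlapping windows of a fixed width; the final partial window of each
chromosome is dropped. Per-window quantities live in flat numpy arrays laid
out chromosome by chromosome, with ``numpy.nan`` marking undefined windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase

A, C, G, T = 0, 1, 2, 3
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(word: str) -> str:
    """Reverse complement of an ACGT word."""
    return "".join(_COMPLEMENT[b] for b in reversed(word.upper()))


@dataclass(frozen=True)
class BinGrid:
    """Tiling of a genome with fixed-width windows.

    Parameters
    ----------
    chrom_sizes : mapping of chromosome name to size in bp
    width : window width in bp; per chromosome ``floor(size / width)``
        windows are kept and the trailing partial window is dropped.
    """

    chrom_sizes: Mapping[str, int]
    width: int
    chroms: tuple = field(init=False)
    n_bins_per_chrom: tuple = field(init=False)
    offsets: tuple = field(init=False)

    def __post_init__(self):
        if self.width < 1:
            raise ValueError(f"bin width must be >= 1, got {self.width}")
        if not self.chrom_sizes:
            raise ValueError("empty chromosome set")
        chroms = tuple(self.chrom_sizes)
        nb = tuple(int(self.chrom_sizes[c]) // self.width for c in chroms)
        offs = tuple(np.concatenate([[0], np.cumsum(nb)]).tolist())
        object.__setattr__(self, "chroms", chroms)
        object.__setattr__(self, "n_bins_per_chrom", nb)
        object.__setattr__(self, "offsets", offs)

    @property
    def n_bins(self) -> int:
        return self.offsets[-1]

    def chrom_slice(self, chrom: str) -> slice:
        i = self.chroms.index(chrom)
        return slice(self.offsets[i], self.offsets[i + 1])

    def bin_index(self, chrom: str, pos: int) -> int:
        """Flat index of the bin containing ``pos``; -1 if in the dropped tail."""
        i = self.chroms.index(chrom)
        b = pos // self.width
        if b >= self.n_bins_per_chrom[i]:
            return -1
        return self.offsets[i] + b

    def bin_starts(self, chrom: str) -> np.ndarray:
        i = self.chroms.index(chrom)
        return np.arange(self.n_bins_per_chrom[i]) * self.width

    def intervals(self) -> pd.DataFrame:
        """All bins as a BED-like frame (chrom, start, end)."""
        rows = []
        for c in self.chroms:
            s = self.bin_starts(c)
            rows.append(pd.DataFrame({"chrom": c, "start": s, "end": s + self.width}))
        return pd.concat(rows, ignore_index=True)


def make_bins(chrom_sizes: Mapping[str, int], width: int) -> BinGrid:
    """Tile chromosomes with ``width``-bp windows, dropping partial tails."""
    return BinGrid(dict(chrom_sizes), int(width))


@dataclass
class SignalTrack:
    """Per-bin numeric genome track; ``nan`` marks undefined bins."""

    grid: BinGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError(
                f"values shape {self.values.shape} != grid bins ({self.grid.n_bins},)"
            )

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    def mean(self, mask: "MaskTrack | None" = None) -> float:
        """Genome-wide mean over defined (and unmasked) bins."""
        ok = self.defined
        if mask is not None:
            ok &= ~mask.values
        return float(np.mean(self.values[ok]))

    def normalized(self, mask: "MaskTrack | None" = None) -> "SignalTrack":
        """Track divided by its genome-wide mean."""
        m = self.mean(mask)
        if m == 0:
            raise ValueError("cannot normalize a track with zero mean")
        return SignalTrack(self.grid, self.values / m)


@dataclass
class MaskTrack:
    """Per-bin boolean mask (True = masked) on a grid."""

    grid: BinGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError("mask length does not match grid")

    @classmethod
    def empty(cls, grid: BinGrid) -> "MaskTrack":
        return cls(grid, np.zeros(grid.n_bins, dtype=bool))


def kmer_classes(k: int) -> list[tuple[str, tuple[str, ...]]]:
    """Reverse-complement equivalence classes of all ``4**k`` words.

    Returns an ordered list of ``(canonical, members)`` where the canonical
    representative is the lexicographically smaller of ``{w, revcomp(w)}``
    and classes are ordered by canonical word. For k=2 there are 10 classes
    (6 pairs plus the 4 palindromes AT, CG, GC, TA); for k=3, 32.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be in {{1, 2, 3}}, got {k}")
    bases = "ACGT"
    words = ["".join(w) for w in __import__("itertools").product(bases, repeat=k)]
    seen: dict[str, tuple[str, ...]] = {}
    for w in words:
        rc = revcomp(w)
        canon = min(w, rc)
        if canon not in seen:
            seen[canon] = (canon,) if rc == canon else (canon, rc)
    return sorted(seen.items())


def encode_sequence(seq) -> np.ndarray:
    """Map a sequence (str, bytes, or uint8 codes) to codes A,C,G,T=0..3; other=255."""
    if isinstance(seq, np.ndarray) and seq.dtype == np.uint8:
        return seq
    if not isinstance(seq, (bytes, bytearray)):
        seq = str(seq).encode("ascii")
    return _BASE_CODE[np.frombuffer(bytes(seq), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bytes(lut[codes]).decode("ascii")


@dataclass
class FeatureTable:
    """Per-bin sequence features on a grid.

    ``f_gc`` is the fraction of G/C bases, ``f_cpg`` (``f_cph``) the fraction
    of within-bin dinucleotide start positions holding CpG (CpH); k-mer class
    frequencies are stored per k as ``(n_bins, n_classes)`` arrays whose rows
    sum to 1 on defined bins. Bins containing any non-ACGT base are undefined.
    """

    grid: BinGrid
    f_gc: np.ndarray
    f_cpg: np.ndarray
    f_cph: np.ndarray
    kmer_freqs: dict[int, np.ndarray]
    kmer_names: dict[int, list[str]]
    defined: np.ndarray

    def gc_track(self) -> SignalTrack:
        v = np.where(self.defined, self.f_gc, np.nan)
        return SignalTrack(self.grid, v)

    def cpg_track(self) -> SignalTrack:
        v = np.where(self.defined, self.f_cpg, np.nan)
        return SignalTrack(self.grid, v)

    def cph_track(self) -> SignalTrack:
        v = np.where(self.defined, self.f_cph, np.nan)
        return SignalTrack(self.grid, v)

    def predictor_matrix(self, k_set: Sequence[int]) -> tuple[np.ndarray, list[str]]:
        """Feature matrix for binding prediction.

        Mononucleotides reduce to the single independent feature GC%
        (A+C+G+T frequencies sum to 1 and strand symmetry ties A to T and C
        to G); di-/tri-nucleotides enter as reverse-complement class
        frequencies. k_set={1,2} therefore yields exactly 11 columns.
        """
        cols, names = [], []
        for k in sorted(k_set):
            if k == 1:
                cols.append(self.f_gc[:, None])
                names.append("GC%")
            else:
                cols.append(self.kmer_freqs[k])
                names.extend(self.kmer_names[k])
        return np.hstack(cols), names


def _chrom_sequence(fasta, chrom: str) -> np.ndarray:
    """Fetch a chromosome from a dict/pyfaidx-like object as uint8 codes."""
    try:
        rec = fasta[chrom]
    except KeyError as e:
        raise KeyError(f"chromosome {chrom!r} missing from FASTA") from e
    if isinstance(rec, np.ndarray):
        return encode_sequence(rec)
    return encode_sequence(str(rec[:]) if hasattr(rec, "__getitem__") and not isinstance(rec, str) else rec)


def sequence_features(fasta, grid: BinGrid, k_set: Iterable[int] = (1, 2)) -> FeatureTable:
    """Per-bin GC%, CpG%, CpH% and k-mer class frequencies.

    Dinucleotide (and k-mer) counts use within-bin start positions only, so
    the CpG% denominator is ``W - 1``; dinucleotides spanning a bin boundary
    are ignored. Any non-ACGT base makes the whole bin undefined.
    """
    k_set = sorted(set(int(k) for k in k_set))
    for k in k_set:
        if k not in (1, 2, 3):
            raise ValueError("k_set entries must be in {1, 2, 3}")
    W = grid.width
    n = grid.n_bins
    f_gc = np.zeros(n)
    f_cpg = np.zeros(n)
    f_cph = np.zeros(n)
    defined = np.zeros(n, dtype=bool)
    classes = {k: kmer_classes(k) for k in k_set if k > 1}
    class_maps = {}
    for k, cls in classes.items():
        word_to_class = np.zeros(4 ** k, dtype=np.intp)
        for ci, (_, members) in enumerate(cls):
            for w in members:
                code = 0
                for b in w:
                    code = code * 4 + "ACGT".index(b)
                word_to_class[code] = ci
        class_maps[k] = word_to_class
    kmer_freqs = {k: np.zeros((n, len(classes[k]))) for k in classes}

    for ci_c, chrom in enumerate(grid.chroms):
        nb = grid.n_bins_per_chrom[ci_c]
        if nb == 0:
            continue
        codes = _chrom_sequence(fasta, chrom)[: nb * W].reshape(nb, W)
        sl = grid.chrom_slice(chrom)
        ok = ~(codes == 255).any(axis=1)
        defined[sl] = ok
        f_gc[sl] = ((codes == C) | (codes == G)).mean(axis=1)
        left, right = codes[:, :-1], codes[:, 1:]
        f_cpg[sl] = ((left == C) & (right == G)).mean(axis=1)
        f_cph[sl] = ((left == C) & (right != G) & (right != 255)).mean(axis=1)
        for k in classes:
            # word code per within-bin start position, then per-bin histogram
            wc = np.zeros((nb, W - k + 1), dtype=np.intp)
            for j in range(k):
                wc = wc * 4 + np.where(codes[:, j : W - k + 1 + j] == 255, 0, codes[:, j : W - k + 1 + j])
            cc = class_maps[k][wc]
            flat = (np.arange(nb)[:, None] * len(classes[k]) + cc).ravel()
            counts = np.bincount(flat, minlength=nb * len(classes[k])).reshape(
                nb, len(classes[k])
            )
            kmer_freqs[k][sl] = counts / (W - k + 1)

    for arr in (f_gc, f_cpg, f_cph):
        arr[~defined] = np.nan
    for k in kmer_freqs:
        kmer_freqs[k][~defined] = np.nan
    names = {k: [canon for canon, _ in classes[k]] for k in classes}
    return FeatureTable(grid, f_gc, f_cpg, f_cph, kmer_freqs, names, defined)


@dataclass
class FragmentSet:
    """Aligned fragments or read starts as parallel arrays, 0-based half-open."""

    chrom: np.ndarray  # object/str array
    start: np.ndarray
    end: np.ndarray | None = None  # None => read starts needing 3' extension
    strand: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.start)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FragmentSet":
        end = df["end"].to_numpy() if "end" in df else None
        strand = df["strand"].to_numpy() if "strand" in df else None
        return cls(df["chrom"].to_numpy(), df["start"].to_numpy(), end, strand)

    def to_frame(self) -> pd.DataFrame:
        d = {"chrom": self.chrom, "start": self.start}
        if self.end is not None:
            d["end"] = self.end
        if self.strand is not None:
            d["strand"] = self.strand
        return pd.DataFrame(d)


def fragment_coverage(
    fragments: FragmentSet,
    grid: BinGrid,
    extension: int = 0,
    stat: str = "mean",
) -> SignalTrack:
    """Mean per-base fragment coverage per bin.

    When the fragment set carries only read starts (no ``end``), each record
    is extended 3' by ``extension`` bp (minus-strand reads extend leftwards
    from their mapped coordinate). Full intervals are used as-is. Fragments
    running past a chromosome end are clipped. ``stat='center'`` samples the
    per-base coverage at the bin centre instead of averaging it.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    if stat not in ("mean", "center"):
        raise ValueError("stat must be 'mean' or 'center'")
    values = np.zeros(grid.n_bins)
    n_clipped = 0
    chrom_arr = np.asarray(fragments.chrom)
    for ci, chrom in enumerate(grid.chroms):
        size = int(grid.chrom_sizes[chrom])
        nb = grid.n_bins_per_chrom[ci]
        sel = chrom_arr == chrom
        if not sel.any() or nb == 0:
            continue
        starts = np.asarray(fragments.start)[sel].astype(np.int64)
        if fragments.end is not None:
            ends = np.asarray(fragments.end)[sel].astype(np.int64)
        else:
            # read start -> fragment of length `extension` in the 3' direction
            if fragments.strand is not None:
                minus = np.asarray(fragments.strand)[sel] == "-"
            else:
                minus = np.zeros(len(starts), dtype=bool)
            ends = np.where(minus, starts + 1, starts + extension)
            starts = np.where(minus, starts + 1 - extension, starts)
        n_clipped += int((starts < 0).sum() + (ends > size).sum())
        starts = np.clip(starts, 0, size)
        ends = np.clip(ends, 0, size)
        keep = ends > starts
        starts, ends = starts[keep], ends[keep]
        cover_len = nb * grid.width
        depth_diff = np.bincount(
            np.clip(starts, 0, cover_len), minlength=cover_len + 1
        ) - np.bincount(np.clip(ends, 0, cover_len), minlength=cover_len + 1)
        depth = np.cumsum(depth_diff[:cover_len])
        sl = grid.chrom_slice(chrom)
        per_bin = depth.reshape(nb, grid.width)
        if stat == "mean":
            values[sl] = per_bin.mean(axis=1)
        else:
            values[sl] = per_bin[:, grid.width // 2]
    track = SignalTrack(grid, values)
    track.n_clipped = n_clipped  # diagnostic, not part of the statistics
    return track


def smooth_track(track: SignalTrack, n_bins: int) -> SignalTrack:
    """Per-chromosome rolling mean over ``n_bins`` bins (nan-propagating).

    Used e.g. to turn a per-bin enrichment track into the window-averaged
    fold-enrichment target a peak caller would report.
    """
    if n_bins <= 1:
        return SignalTrack(track.grid, track.values.copy())
    kernel = np.ones(n_bins) / n_bins
    out = np.empty_like(track.values)
    for chrom in track.grid.chroms:
        sl = track.grid.chrom_slice(chrom)
        out[sl] = np.convolve(track.values[sl], kernel, mode="same")
    return SignalTrack(track.grid, out)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs of True in a boolean vector."""
    if not mask.any():
        return []
    d = np.diff(np.concatenate([[0], mask.astype(np.int8), [0]]))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def build_mask(
    occupancy: SignalTrack,
    mappability: SignalTrack | None = None,
    occ_threshold: float = 100.0,
    map_level: float = 0.5,
    map_run: int = 10,
    pad: int = 10_000,
) -> MaskTrack:
    """Mask anomalous regions on the occupancy grid.

    Two rules, united: (a) bins whose occupancy exceeds ``occ_threshold``,
    padded by ``pad`` bp on both sides; (b) runs of at least ``map_run``
    consecutive mappability bins (typically a coarser 1 kb grid) with mean
    mappability below ``map_level``, likewise padded. The mappability rule is
    projected onto the occupancy grid: an analysis bin is masked when it
    overlaps a masked interval.
    """
    grid = occupancy.grid
    masked = np.zeros(grid.n_bins, dtype=bool)
    intervals: dict[str, list[tuple[int, int]]] = {c: [] for c in grid.chroms}

    for ci, chrom in enumerate(grid.chroms):
        sl = grid.chrom_slice(chrom)
        occ = occupancy.values[sl]
        W = grid.width
        for s, e in _runs(np.nan_to_num(occ, nan=0.0) > occ_threshold):
            intervals[chrom].append((s * W - pad, e * W + pad))

    if mappability is not None:
        mg = mappability.grid
        if set(mg.chroms) - set(grid.chroms):
            raise ValueError("mappability grid chromosomes do not match occupancy grid")
        for chrom in mg.chroms:
            sl = mg.chrom_slice(chrom)
            low = np.nan_to_num(mappability.values[sl], nan=0.0) < map_level
            for s, e in _runs(low):
                if e - s >= map_run:
                    intervals[chrom].append((s * mg.width - pad, e * mg.width + pad))

    for ci, chrom in enumerate(grid.chroms):
        sl = grid.chrom_slice(chrom)
        nb = grid.n_bins_per_chrom[ci]
        W = grid.width
        sub = np.zeros(nb, dtype=bool)
        for s, e in intervals[chrom]:
            lo = max(0, s // W)
            hi = min(nb, -(-e // W))
            sub[lo:hi] = True
        masked[sl] = sub
    return MaskTrack(grid, masked)
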