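"""Binning, sequence features, fragment coverage and masking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seqbind as sb
from seqbind.tracks import encode_sequence, smooth_track

from conftest import as_track, flat_grid


class TestMakeBins:
    @pytest.mark.parametrize(
        "size,width,n_expected,last",
        [
            (1000, 150, 6, (750, 900)),
            (149, 150, 0, None),
            (300, 150, 2, (150, 300)),
        ],
    )
    def test_partial_tail_dropped(self, size, width, n_expected, last):
        grid = sb.make_bins({"chr1": size}, width)
        assert grid.n_bins == n_expected
        if last is not None:
            starts = grid.bin_starts("chr1")
            assert (starts[-1], starts[-1] + width) == last

    def test_empty_chromosome_set_rejected(self):
        with pytest.raises(ValueError):
            sb.make_bins({}, 150)

    def test_bin_index_roundtrip(self):
        grid = sb.make_bins({"a": 450, "b": 600}, 150)
        assert grid.bin_index("b", 0) == 3
        assert grid.bin_index("a", 449) == 2
        assert grid.bin_index("b", 599) == 6


class TestKmerClasses:
    def test_dinucleotide_classes_match_enumeration(self):
        got = sb.kmer_classes(2)
        expected = {
            "AA": {"AA", "TT"}, "AC": {"AC", "GT"}, "AG": {"AG", "CT"},
            "AT": {"AT"}, "CA": {"CA", "TG"}, "CC": {"CC", "GG"},
            "CG": {"CG"}, "GA": {"GA", "TC"}, "GC": {"GC"}, "TA": {"TA"},
        }
        assert {c: set(m) for c, m in got} == expected
        assert [c for c, _ in got] == sorted(expected)

    @pytest.mark.parametrize("k,n_classes", [(1, 2), (2, 10), (3, 32)])
    def test_class_count_and_cover(self, k, n_classes):
        classes = sb.kmer_classes(k)
        assert len(classes) == n_classes
        # exhaustive oracle: classes are disjoint and cover all 4^k words
        all_words = {"".join(w) for w in itertools.product("ACGT", repeat=k)}
        members = [w for _, ms in classes for w in ms]
        assert len(members) == len(set(members))
        assert set(members) == all_words
        for canon, ms in classes:
            assert canon == min(ms)
            assert set(ms) == {canon, sb.revcomp(canon)}

    def test_invalid_k_rejected(self):
        for k in (0, 4, -1):
            with pytest.raises(ValueError):
                sb.kmer_classes(k)


def naive_features(seq: str, k: int):
    """Independent per-position counting oracle for one bin."""
    counts = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        canon = min(w, sb.revcomp(w))
        counts[canon] = counts.get(canon, 0) + 1
    total = len(seq) - k + 1
    return {c: n / total for c, n in counts.items()}


class TestSequenceFeatures:
    def test_acgt_bin(self):
        grid = sb.make_bins({"c": 4}, 4)
        ft = sb.sequence_features({"c": "ACGT"}, grid)
        assert ft.f_gc[0] == pytest.approx(0.5)
        assert ft.f_cpg[0] == pytest.approx(1 / 3)

    def test_cgcg_bin(self):
        grid = sb.make_bins({"c": 4}, 4)
        ft = sb.sequence_features({"c": "CGCG"}, grid)
        assert ft.f_gc[0] == pytest.approx(1.0)
        assert ft.f_cpg[0] == pytest.approx(2 / 3)

    def test_random_bins_match_naive_oracle(self, rng):
        W = 150
        seq = "".join(rng.choice(list("ACGT"), size=10 * W))
        grid = sb.make_bins({"c": len(seq)}, W)
        ft = sb.sequence_features({"c": seq}, grid, k_set=(1, 2, 3))
        for b in range(grid.n_bins):
            sub = seq[b * W : (b + 1) * W]
            gc = (sub.count("G") + sub.count("C")) / W
            assert ft.f_gc[b] == pytest.approx(gc, abs=1e-12)
            assert ft.f_cpg[b] == pytest.approx(sub.count("CG") / (W - 1), abs=1e-12)
            for k in (2, 3):
                oracle = naive_features(sub, k)
                for ci, name in enumerate(ft.kmer_names[k]):
                    assert ft.kmer_freqs[k][b, ci] == pytest.approx(
                        oracle.get(name, 0.0), abs=1e-12
                    )
        # class frequencies sum to 1 per k on defined bins
        for k in (2, 3):
            np.testing.assert_allclose(ft.kmer_freqs[k].sum(axis=1), 1.0)

    def test_ambiguous_base_undefines_bin(self):
        grid = sb.make_bins({"c": 8}, 4)
        ft = sb.sequence_features({"c": "ACGTACNT"}, grid)
        assert ft.defined[0] and not ft.defined[1]
        assert np.isnan(ft.f_gc[1])

    def test_missing_chromosome_raises(self):
        grid = sb.make_bins({"c": 8}, 4)
        with pytest.raises(KeyError):
            sb.sequence_features({"other": "ACGTACGT"}, grid)

    @settings(max_examples=25, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=12, max_size=40))
    def test_cpg_frequency_property(self, seq):
        W = len(seq) // 2
        grid = sb.make_bins({"c": len(seq)}, W)
        ft = sb.sequence_features({"c": seq}, grid, k_set=(1, 2))
        assert np.all(ft.f_cpg[ft.defined] <= 0.5 + 1e-12)
        cg_idx = ft.kmer_names[2].index("CG")
        np.testing.assert_allclose(
            ft.f_cpg[ft.defined], ft.kmer_freqs[2][ft.defined, cg_idx]
        )


def coverage_oracle(frags, grid, extension):
    """Per-base accumulation array oracle."""
    out = np.zeros(grid.n_bins)
    for ci, chrom in enumerate(grid.chroms):
        size = grid.chrom_sizes[chrom]
        depth = np.zeros(size)
        for c, s, e, strand in frags:
            if c != chrom:
                continue
            if e is None:
                s, e = (s + 1 - extension, s + 1) if strand == "-" else (s, s + extension)
            for p in range(max(0, s), min(size, e)):
                depth[p] += 1
        sl = grid.chrom_slice(chrom)
        nb = grid.n_bins_per_chrom[ci]
        out[sl] = depth[: nb * grid.width].reshape(nb, grid.width).mean(axis=1)
    return out


class TestFragmentCoverage:
    def test_single_extended_read_fills_its_bin(self):
        grid = sb.make_bins({"c": 600}, 200)
        fr = sb.FragmentSet(np.array(["c"]), np.array([200]), None, np.array(["+"]))
        track = sb.fragment_coverage(fr, grid, extension=200)
        np.testing.assert_allclose(track.values, [0, 1.0, 0])

    def test_additivity(self, rng):
        grid = sb.make_bins({"c": 3000}, 150)
        starts = rng.integers(0, 2800, 5)
        fr1 = sb.FragmentSet(np.repeat("c", 5).astype(object), starts, starts + 180)
        fr2 = sb.FragmentSet(
            np.repeat("c", 10).astype(object),
            np.concatenate([starts, starts]),
            np.concatenate([starts, starts]) + 180,
        )
        t1 = sb.fragment_coverage(fr1, grid)
        t2 = sb.fragment_coverage(fr2, grid)
        np.testing.assert_allclose(t2.values, 2 * t1.values)

    def test_random_fragments_match_per_base_oracle(self, rng):
        grid = sb.make_bins({"a": 3000, "b": 1500}, 150)
        recs = []
        for _ in range(100):
            chrom = "a" if rng.random() < 0.7 else "b"
            size = 3000 if chrom == "a" else 1500
            s = int(rng.integers(0, size - 10))
            strand = "+" if rng.random() < 0.5 else "-"
            recs.append((chrom, s, None, strand))
        fr = sb.FragmentSet(
            np.array([r[0] for r in recs], dtype=object),
            np.array([r[1] for r in recs]),
            None,
            np.array([r[3] for r in recs]),
        )
        track = sb.fragment_coverage(fr, grid, extension=200)
        np.testing.assert_allclose(track.values, coverage_oracle(recs, grid, 200))

    def test_coverage_conservation(self, rng):
        # sum(bin value * W) equals total fragment bases minus clipped bases
        grid = sb.make_bins({"a": 3000}, 150)
        starts = rng.integers(0, 3000, 50)
        ends = np.minimum(starts + 120, 3000)
        fr = sb.FragmentSet(np.repeat("a", 50).astype(object), starts, ends)
        track = sb.fragment_coverage(fr, grid)
        assert track.values @ np.full(grid.n_bins, 150) == pytest.approx(
            (ends - starts).sum()
        )


class TestBuildMask:
    def grid(self):
        return sb.make_bins({"c": 100_000}, 1000)

    def test_high_occupancy_padded(self):
        grid = self.grid()
        occ = np.zeros(grid.n_bins)
        occ[50] = 101
        mask = sb.build_mask(sb.SignalTrack(grid, occ), None)
        idx = np.flatnonzero(mask.values)
        np.testing.assert_array_equal(idx, np.arange(40, 61))

    def test_mappability_run_length_boundary(self):
        grid = self.grid()
        occ = sb.SignalTrack(grid, np.zeros(grid.n_bins))
        for n_low, expect_any in [(9, False), (10, True)]:
            mp = np.ones(grid.n_bins)
            mp[20 : 20 + n_low] = 0.2
            mask = sb.build_mask(occ, sb.SignalTrack(grid, mp))
            assert mask.values.any() == expect_any
        mp = np.ones(grid.n_bins)
        mp[20:30] = 0.2
        mask = sb.build_mask(occ, sb.SignalTrack(grid, mp))
        np.testing.assert_array_equal(
            np.flatnonzero(mask.values), np.arange(10, 40)
        )

    def test_clean_genome_unmasked(self):
        grid = self.grid()
        occ = sb.SignalTrack(grid, np.full(grid.n_bins, 50.0))
        mp = sb.SignalTrack(grid, np.ones(grid.n_bins))
        assert not sb.build_mask(occ, mp).values.any()

    def test_monotone_in_occupancy_threshold(self, rng):
        grid = self.grid()
        occ = sb.SignalTrack(grid, rng.exponential(60, grid.n_bins))
        prev = None
        for thr in (50, 100, 200, 400):
            m = sb.build_mask(occ, None, occ_threshold=thr).values
            if prev is not None:
                assert not (m & ~prev).any()  # raising threshold never adds bins
            prev = m


def test_smooth_track_preserves_interior_mean():
    t = as_track(np.arange(100, dtype=float))
    s = smooth_track(t, 5)
    np.testing.assert_allclose(s.values[2:-2], t.values[2:-2])


def test_encode_decode_roundtrip():
    from seqbind.tracks import decode_sequence

    seq = "ACGTTGCA"
    assert decode_sequence(encode_sequence(seq)) == seq
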