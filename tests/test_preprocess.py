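"""Promoter binning, fractional bin counting, linear normalization, tensors."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import epitriclust as et
from epitriclust.intervals import GenomicInterval, SignalTrack


def iv(start, end, name="", strand="."):
    return GenomicInterval("chr1", start, end, name=name, strand=strand)


class TestBinInterval:
    def test_equal_quarters_plus_strand(self):
        bins = et.bin_interval(iv(1000, 2000, strand="+"), 4)
        assert [(b.start, b.end) for b in bins] == [
            (1000, 1250), (1250, 1500), (1500, 1750), (1750, 2000),
        ]

    def test_minus_strand_reverses_bin_order(self):
        plus = et.bin_interval(iv(1000, 2000, strand="+"), 4)
        minus = et.bin_interval(iv(1000, 2000, strand="-"), 4)
        assert [(b.start, b.end) for b in minus] == [
            (b.start, b.end) for b in reversed(plus)
        ]

    def test_remainder_goes_to_earliest_bins(self):
        bins = et.bin_interval(iv(0, 10), 3)
        lengths = [len(b) for b in bins]
        assert lengths == [4, 3, 3]
        assert sum(lengths) == 10

    def test_region_shorter_than_bin_count_rejected(self):
        with pytest.raises(ValueError, match="length 2 < n_bins=3"):
            et.bin_interval(iv(0, 2), 3)

    @given(
        start=st.integers(0, 10_000),
        length=st.integers(1, 500),
        n_bins=st.integers(1, 20),
        strand=st.sampled_from("+-."),
    )
    def test_bins_tile_region_exactly(self, start, length, n_bins, strand):
        if length < n_bins:
            return
        region = iv(start, start + length, strand=strand)
        bins = et.bin_interval(region, n_bins)
        assert len(bins) == n_bins
        spans = sorted((b.start, b.end) for b in bins)
        assert spans[0][0] == start and spans[-1][1] == start + length
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            assert e1 == s2  # contiguous, non-overlapping
        assert max(len(b) for b in bins) - min(len(b) for b in bins) <= 1


class TestCountInBins:
    def test_record_matching_one_bin_exactly(self):
        bins = et.bin_interval(iv(0, 400), 4)
        track = SignalTrack("A", "m", [(iv(0, 100), 8.0)])
        assert et.count_in_bins(track, bins).tolist() == [8.0, 0.0, 0.0, 0.0]

    def test_empty_track_all_zero(self):
        bins = et.bin_interval(iv(0, 400), 4)
        assert et.count_in_bins(SignalTrack("A", "m", []), bins).tolist() == [0] * 4

    def test_record_split_proportionally_and_mass_conserved(self):
        # value 6 spanning bins 1-3 of [0,300)/3 equally -> (2,2,2)
        bins = et.bin_interval(iv(0, 300), 3)
        track = SignalTrack("A", "m", [(iv(0, 300), 6.0)])
        counts = et.count_in_bins(track, bins)
        assert counts.tolist() == [2.0, 2.0, 2.0]
        assert counts.sum() == pytest.approx(6.0)

    def test_mass_conservation_random_tracks(self, rng):
        """Records fully inside the region contribute exactly their value."""
        region = iv(0, 997)
        bins = et.bin_interval(region, 10)
        pos, records = 0, []
        while pos < 900:
            start = pos + int(rng.integers(0, 5))
            end = start + int(rng.integers(1, 60))
            if end > 997:
                break
            records.append((iv(start, end), float(rng.gamma(2.0, 3.0))))
            pos = end
        track = SignalTrack("A", "m", records)
        counts = et.count_in_bins(track, bins)
        assert counts.sum() == pytest.approx(sum(v for _, v in records))

    def test_other_chromosome_ignored(self):
        bins = et.bin_interval(iv(0, 100), 2)
        track = SignalTrack(
            "A", "m", [(GenomicInterval("chr2", 0, 100), 5.0)]
        )
        assert et.count_in_bins(track, bins).tolist() == [0.0, 0.0]


class TestNormalizeLinear:
    def test_scalar_multiply(self):
        out = et.normalize_linear(np.array([[2.0, 4.0, 6.0]]), 1e6, 1e7)
        assert out.tolist() == [[20.0, 40.0, 60.0]]

    def test_identity_when_totals_match(self):
        x = np.arange(6.0).reshape(2, 3)
        assert np.array_equal(et.normalize_linear(x, 5.0, 5.0), x)

    def test_nonpositive_library_rejected(self):
        with pytest.raises(ValueError, match="library_total"):
            et.normalize_linear(np.ones((2, 2)), 0.0, 1.0)

    def test_grand_totals_equal_target_when_library_is_slice_sum(self, rng):
        for _ in range(5):
            x = rng.gamma(1.0, 2.0, size=(6, 8))
            out = et.normalize_linear(x, x.sum(), 1e6)
            assert out.sum() == pytest.approx(1e6)

    def test_linearity_in_input(self, rng):
        x = rng.gamma(1.0, 2.0, size=(3, 4))
        a = 3.7
        assert np.allclose(
            et.normalize_linear(a * x, 10.0, 2.0),
            a * et.normalize_linear(x, 10.0, 2.0),
        )


class TestBuildMarkTensor:
    @staticmethod
    def make_world(n_groups=2, signal=True):
        promoters = [iv(i * 1000, i * 1000 + 400, name=f"g{i}") for i in range(3)]
        tracks = []
        for gi in range(n_groups):
            records = []
            if signal:
                records = [
                    (iv(i * 1000 + 50 * gi, i * 1000 + 200 + 50 * gi),
                     float(10 + gi + i))
                    for i in range(3)
                ]
            tracks.append(SignalTrack(f"G{gi}", "m", records))
        return tracks, promoters

    def test_shape_groups_genes_bins(self):
        tracks, promoters = self.make_world()
        t = et.build_mark_tensor(tracks, promoters, n_bins=4, target_total=1e6)
        assert t.values.shape == (2, 3, 4)
        assert t.genes == ["g0", "g1", "g2"]  # promoter file order

    def test_seven_groups_gives_first_axis_seven(self):
        tracks, promoters = self.make_world(n_groups=7)
        t = et.build_mark_tensor(tracks, promoters, n_bins=4)
        assert t.values.shape[0] == 7

    def test_empty_track_yields_zero_slice(self):
        tracks, promoters = self.make_world()
        tracks[1] = SignalTrack("G1", "m", [])
        t = et.build_mark_tensor(tracks, promoters, n_bins=4)
        assert np.all(t.values[1] == 0)
        assert t.values[0].sum() > 0

    def test_duplicate_group_labels_rejected(self):
        tracks, promoters = self.make_world()
        tracks[1].group = "G0"
        with pytest.raises(ValueError, match="duplicate group"):
            et.build_mark_tensor(tracks, promoters, n_bins=4)

    def test_too_short_promoter_error_names_gene(self):
        tracks, promoters = self.make_world()
        promoters[1] = iv(1000, 1003, name="g1")
        with pytest.raises(ValueError, match="g1"):
            et.build_mark_tensor(tracks, promoters, n_bins=4)

    def test_permutation_equivariance_on_gene_axis(self):
        tracks, promoters = self.make_world()
        t1 = et.build_mark_tensor(tracks, promoters, n_bins=4)
        perm = [2, 0, 1]
        t2 = et.build_mark_tensor(tracks, [promoters[i] for i in perm], n_bins=4)
        assert t2.genes == [t1.genes[i] for i in perm]
        assert np.array_equal(t2.values, t1.values[:, perm, :])

    def test_each_group_slice_normalized_to_target_over_library(self):
        tracks, promoters = self.make_world()
        t = et.build_mark_tensor(
            tracks, promoters, n_bins=4, target_total=1e6,
            library_from_promoters=True,
        )
        # promoter-restricted library: every group's grand total hits target
        assert t.values[0].sum() == pytest.approx(1e6)
        assert t.values[1].sum() == pytest.approx(1e6)
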