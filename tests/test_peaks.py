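"""Significant-window detection, gap merging, read attachment, gap scan."""

import numpy as np
import pytest

from waveseq import (
    GenomeDef,
    MCConfig,
    MotherWavelet,
    PeakCallConfig,
    ScaleGrid,
    WindowTrack,
    attach_read_counts,
    cwt,
    draw_segments,
    estimate_thresholds,
    gap_saturation,
    merge_windows,
    shift_reads,
    significant_windows,
)
from waveseq.peaks import PutativePeak, call_putative_peaks
from waveseq.thresholds import ScaleThresholds

from conftest import make_reads


def manual_thresholds(values, grid, wavelet):
    return ScaleThresholds(thresholds=np.asarray(values, dtype=float),
                           grid=grid, wavelet=wavelet,
                           config=MCConfig(n_samples=100, sample_length=128,
                                           p_thres=0.2))


class TestSignificantWindows:
    def test_zero_power_gives_empty_mask(self):
        grid = ScaleGrid(s0=2, dj=0.5, J=3)
        wavelet = MotherWavelet("morlet")
        result = cwt(np.zeros(64) + 1.0, grid, wavelet)
        thr = manual_thresholds([0.5, 0.5, 0.5], grid, wavelet)
        config = PeakCallConfig(min_scales=1)
        assert not significant_windows(result, thr, config).any()

    def test_single_scale_single_column(self):
        """With a one-scale band and one column above threshold, exactly
        that window is flagged (min_scales caps at the band size)."""
        grid = ScaleGrid(s0=2, dj=0.5, J=1)
        wavelet = MotherWavelet("mexican_hat")
        x = np.zeros(64)
        x[32] = 50.0
        result = cwt(x, grid, wavelet)
        cut = result.power[0].max() * 0.999
        thr = manual_thresholds([cut], grid, wavelet)
        mask = significant_windows(result, thr,
                                   PeakCallConfig(require_positive=False))
        assert mask.sum() == 1 and mask[32]

    def test_troughs_rejected_when_positive_required(self):
        """A depletion trough has high power but negative coefficient."""
        grid = ScaleGrid(s0=2, dj=0.25, J=5)
        wavelet = MotherWavelet("mexican_hat")
        x = np.full(128, 10.0)
        x[60:68] = 0.0  # a hole, not a peak
        result = cwt(x, grid, wavelet)
        thr = manual_thresholds(np.full(5, 1.0), grid, wavelet)
        with_sign = significant_windows(
            result, thr, PeakCallConfig(require_positive=True, min_scales=1))
        without = significant_windows(
            result, thr, PeakCallConfig(require_positive=False, min_scales=1))
        assert without[60:68].any()
        assert not with_sign[62:66].any()

    def test_grid_mismatch_is_error(self):
        wavelet = MotherWavelet("morlet")
        result = cwt(np.ones(64), ScaleGrid(s0=2, dj=0.5, J=3), wavelet)
        thr = manual_thresholds([1, 1], ScaleGrid(s0=2, dj=0.5, J=2), wavelet)
        with pytest.raises(ValueError):
            significant_windows(result, thr, PeakCallConfig())

    def test_empty_scale_band_is_error(self):
        grid = ScaleGrid(s0=2, dj=0.5, J=3)
        wavelet = MotherWavelet("morlet")
        result = cwt(np.ones(64), grid, wavelet)
        thr = manual_thresholds([1, 1, 1], grid, wavelet)
        with pytest.raises(ValueError, match="band"):
            significant_windows(result, thr,
                                PeakCallConfig(scale_band=(100.0, 200.0)))


class TestMergeWindows:
    def mask(self, significant, n=16):
        m = np.zeros(n, dtype=bool)
        m[list(significant)] = True
        return m

    def test_gap_of_two_bridged_when_g_two(self):
        peaks = merge_windows(self.mask({3, 4, 7}), 2, 200, "chr1")
        assert [(p.start, p.end) for p in peaks] == [(600, 1600)]
        assert peaks[0].n_windows == 5

    def test_gap_of_four_splits_when_g_two(self):
        peaks = merge_windows(self.mask({3, 4, 9}), 2, 200, "chr1")
        assert [(p.start, p.end) for p in peaks] == [(600, 1000), (1800, 2000)]

    def test_adjacent_windows_merge_at_g_zero(self):
        peaks = merge_windows(self.mask({1, 2}), 0, 200, "chr1")
        assert [(p.start, p.end) for p in peaks] == [(200, 600)]

    def test_peaks_end_on_significant_windows(self):
        """Bridged gaps are interior; peak edges never extend into
        non-significant territory."""
        peaks = merge_windows(self.mask({3, 6}), 5, 200, "chr1")
        assert [(p.start, p.end) for p in peaks] == [(600, 1400)]

    def test_empty_mask_gives_no_peaks(self):
        assert merge_windows(self.mask(set()), 3, 200, "chr1") == []

    def test_chromosome_end_truncation(self):
        peaks = merge_windows(self.mask({14, 15}), 0, 200, "chr1",
                              chrom_length=3100)
        assert peaks[0].end == 3100


class TestAttachReadCounts:
    def test_half_open_counting(self, small_genome):
        reads = make_reads([("chrA", p, p + 36, "+") for p in (0, 399, 400)])
        readset = shift_reads(reads, 0, small_genome)
        peaks = [PutativePeak("chrA", 0, 400, 2)]
        attach_read_counts(peaks, readset)
        assert peaks[0].read_count == 2

    def test_empty_readset(self, small_genome):
        readset = shift_reads([], 0, small_genome)
        peaks = [PutativePeak("chrA", 0, 400, 2)]
        attach_read_counts(peaks, readset)
        assert peaks[0].read_count == 0

    def test_disjoint_peaks_conserve_reads(self, small_genome, rng):
        starts = rng.integers(0, 99_000, size=500)
        readset = shift_reads(
            make_reads([("chrA", int(s), int(s) + 36, "+") for s in starts]),
            0, small_genome)
        peaks = [PutativePeak("chrA", i * 10_000, (i + 1) * 10_000, 50)
                 for i in range(10)]
        attach_read_counts(peaks, readset)
        assert sum(p.read_count for p in peaks) <= readset.library_size


def _toy_calling_setup(rng, n_windows=2048, rate=1.0, block=(900, 950, 20.0)):
    genome = GenomeDef.from_dict({"chr1": n_windows * 200})
    counts = rng.poisson(rate, n_windows).astype(np.int64)
    lo, hi, fold = block
    counts[lo:hi] += rng.poisson(rate * (fold - 1), hi - lo)
    positions = np.sort(np.concatenate([
        np.repeat(np.arange(n_windows) * 200 + 100, counts)]))
    from waveseq.preprocess import ReadSet

    readset = ReadSet(positions={"chr1": positions},
                      library_size=int(counts.sum()))
    track = WindowTrack(200, {"chr1": counts}, readset.library_size)
    config = MCConfig(n_samples=300, sample_length=512, p_thres=0.2)
    grid = ScaleGrid.for_signal(512)
    segments = draw_segments(track, config, rng)
    thresholds = estimate_thresholds(segments, grid, MotherWavelet("morlet"),
                                     0.2, keep_samples=False)
    return genome, track, readset, thresholds


class TestGapBehaviour:
    def test_peak_count_and_bp_monotone_in_g(self, rng):
        genome, track, readset, thresholds = _toy_calling_setup(rng)
        counts, bps = [], []
        for g in (0, 1, 2, 5, 10, 20):
            peaks = call_putative_peaks(
                track, thresholds, PeakCallConfig.punctate(gap=g), genome,
                readset)
            counts.append(len(peaks))
            bps.append(sum(p.length for p in peaks))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert all(a <= b for a, b in zip(bps, bps[1:]))

    def test_peaks_disjoint_sorted_and_cover_mask(self, rng):
        genome, track, readset, thresholds = _toy_calling_setup(rng)
        peaks = call_putative_peaks(track, thresholds,
                                    PeakCallConfig.punctate(gap=2), genome)
        for a, b in zip(peaks, peaks[1:]):
            assert a.end <= b.start

    def test_gap_saturation_nondecreasing(self, rng):
        genome, track, readset, thresholds = _toy_calling_setup(rng)
        rows = gap_saturation(track, readset, thresholds, genome,
                              [0, 1, 2, 5, 10], top_n=20,
                              base_config=PeakCallConfig.punctate())
        fracs = [f for _, f in rows]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))
        assert all(0 <= f <= 1 for f in fracs)

    def test_gap_saturation_all_peaks_equals_total_fraction(self, rng):
        genome, track, readset, thresholds = _toy_calling_setup(rng)
        peaks = call_putative_peaks(track, thresholds,
                                    PeakCallConfig.punctate(gap=0), genome,
                                    readset)
        total_frac = sum(p.read_count for p in peaks) / readset.library_size
        rows = gap_saturation(track, readset, thresholds, genome, [0],
                              top_n=10 ** 6,
                              base_config=PeakCallConfig.punctate())
        assert rows[0][1] == pytest.approx(total_frac)


def test_calling_invariant_under_global_rescaling(rng):
    """Doubling every count co-scales powers and thresholds, leaving
    the significant-window set unchanged."""
    genome, track, readset, _ = _toy_calling_setup(rng)
    config = MCConfig(n_samples=300, sample_length=512, p_thres=0.2)
    grid = ScaleGrid.for_signal(512)
    wavelet = MotherWavelet("morlet")
    seg = draw_segments(track, config, np.random.default_rng(3))
    thr = estimate_thresholds(seg, grid, wavelet, 0.2)
    scaled_track = WindowTrack(200, {"chr1": track.counts["chr1"] * 2},
                               track.library_size * 2)
    seg2 = draw_segments(scaled_track, config, np.random.default_rng(3))
    thr2 = estimate_thresholds(seg2, grid, wavelet, 0.2)
    pc = PeakCallConfig.punctate()
    peaks1 = call_putative_peaks(track, thr, pc, genome)
    peaks2 = call_putative_peaks(scaled_track, thr2, pc, genome)
    assert [(p.start, p.end) for p in peaks1] == \
        [(p.start, p.end) for p in peaks2]
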