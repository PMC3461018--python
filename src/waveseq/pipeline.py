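"""End-to-end one-sample and two-sample peak-calling workflows.

``call_peaks`` runs the single-sample analysis: preprocess reads,
learn Monte Carlo power thresholds, aggregate significant windows into
putative peaks, score them against the randomized empirical null, and
BH-correct. ``call_differential`` runs the matched test/control
analysis with the exact binomial test and a control-swap pass so that
regions significant in either direction enter a single non-redundant
differential list.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cwt import MotherWavelet, ScaleGrid
from .peaks import PeakCallConfig, PutativePeak, call_putative_peaks
from .preprocess import (
    DEFAULT_SHIFT,
    DEFAULT_WINDOW,
    GenomeDef,
    Read,
    ReadSet,
    WindowTrack,
    bin_counts,
    deduplicate,
    shift_reads,
)
from .significance import (
    bh_fdr,
    binomial_two_sample,
    build_randomized_null,
    one_sample_pvalue,
)
from .significance import swap_merge as _swap_merge
from .thresholds import MCConfig, draw_segments, estimate_thresholds

logger = logging.getLogger(__name__)

PEAK_COLUMNS = ["chrom", "start", "end", "n_windows", "read_count",
                "max_power", "boundary", "p_value", "q_value"]
DMR_COLUMNS = ["chrom", "start", "end", "t_norm", "c_norm", "fold",
               "direction", "p_value", "q_value"]


def prepare_sample(reads: list[Read], genome: GenomeDef,
                   shift: int = DEFAULT_SHIFT,
                   window_size: int = DEFAULT_WINDOW,
                   ) -> tuple[ReadSet, WindowTrack]:
    """Deduplicate, shift and bin one sample's reads."""
    unique = deduplicate(reads)
    readset = shift_reads(unique, shift, genome)
    track = bin_counts(readset, window_size, genome)
    return readset, track


def learn_thresholds(track: WindowTrack, wavelet: MotherWavelet,
                     mc: MCConfig, rng: np.random.Generator,
                     per_chromosome: bool = False):
    """Monte Carlo thresholds for one track (pooled across chromosomes
    by default; ``per_chromosome`` learns a separate set per chromosome
    with enough windows)."""
    grid = ScaleGrid.for_signal(mc.sample_length)
    if not per_chromosome:
        segments = draw_segments(track, mc, rng)
        return estimate_thresholds(segments, grid, wavelet, mc.p_thres,
                                   keep_samples=False)
    out = {}
    for chrom, counts in track.counts.items():
        if len(counts) < mc.sample_length:
            continue
        sub = WindowTrack(track.window_size, {chrom: counts},
                          track.library_size, track.normalized)
        segments = draw_segments(sub, mc, rng)
        out[chrom] = estimate_thresholds(segments, grid, wavelet, mc.p_thres,
                                         keep_samples=False)
    return out


def _peaks_frame(peaks: list[PutativePeak]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [p.chrom for p in peaks],
        "start": [p.start for p in peaks],
        "end": [p.end for p in peaks],
        "n_windows": [p.n_windows for p in peaks],
        "read_count": [p.read_count for p in peaks],
        "max_power": [p.max_power for p in peaks],
        "boundary": [p.boundary_flag for p in peaks],
    })


def call_peaks(reads: list[Read], genome: GenomeDef, *,
               wavelet: str = "morlet",
               shift: int = DEFAULT_SHIFT,
               window_size: int = DEFAULT_WINDOW,
               p_thres: float = 0.2,
               gap: int = 0,
               n_samples: int = 5000,
               sample_length: int = 4096,
               n_null: int = 1_000_000,
               seed: int = 0,
               per_chromosome_thresholds: bool = False,
               peak_config: PeakCallConfig | None = None) -> pd.DataFrame:
    """One-sample workflow: putative peaks with empirical p and BH q.

    Returns a DataFrame (one row per putative peak, sorted by position)
    with read counts, the randomized-null p-value and the q-value.
    """
    rng = np.random.default_rng(seed)
    mother = MotherWavelet(wavelet)
    readset, track = prepare_sample(reads, genome, shift, window_size)
    if readset.library_size == 0:
        logger.warning("no reads after preprocessing; returning empty call set")
        return pd.DataFrame(columns=PEAK_COLUMNS)
    mc = MCConfig(n_samples=n_samples, sample_length=sample_length,
                  p_thres=p_thres)
    thresholds = learn_thresholds(track, mother, mc, rng,
                                  per_chromosome=per_chromosome_thresholds)
    config = peak_config or PeakCallConfig.for_wavelet(wavelet, gap=gap)
    peaks = call_putative_peaks(track, thresholds, config, genome, readset)
    if not peaks:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    null = build_randomized_null(peaks, readset, genome, n_null, rng)
    frame = _peaks_frame(peaks)
    frame["p_value"] = one_sample_pvalue(frame["read_count"].to_numpy(), null)
    frame["q_value"] = bh_fdr(frame["p_value"].to_numpy())
    return frame


def _binomial_pass(peak_sample: tuple[ReadSet, WindowTrack],
                   other_sample: tuple[ReadSet, WindowTrack],
                   genome: GenomeDef, mother: MotherWavelet, mc: MCConfig,
                   config: PeakCallConfig, rng: np.random.Generator,
                   peaks_are_test: bool, one_sided: bool,
                   normalized: bool) -> pd.DataFrame:
    """Call putative peaks on one sample and binomial-test each against
    the other. Direction labels are always relative to the test sample:
    'gain' where the test sample has more normalized reads."""
    peak_rs, peak_track = peak_sample
    other_rs, _ = other_sample
    thresholds = learn_thresholds(peak_track, mother, mc, rng)
    peaks = call_putative_peaks(peak_track, thresholds, config, genome, peak_rs)
    rows = []
    for pk in peaks:
        own = pk.read_count
        other = other_rs.count_in(pk.chrom, pk.start, pk.end)
        if peaks_are_test:
            t_raw, c_raw = own, other
            lib_t, lib_c = peak_rs.library_size, other_rs.library_size
        else:
            t_raw, c_raw = other, own
            lib_t, lib_c = other_rs.library_size, peak_rs.library_size
        p, t_norm, c_norm = binomial_two_sample(t_raw, c_raw, lib_t, lib_c,
                                                one_sided=one_sided,
                                                normalized=normalized)
        fold = (t_norm + 1) / (c_norm + 1)
        rows.append((pk.chrom, pk.start, pk.end, t_norm, c_norm, fold,
                     "gain" if t_norm > c_norm else "loss", p))
    if not rows:
        return pd.DataFrame(columns=DMR_COLUMNS)
    frame = pd.DataFrame(rows, columns=DMR_COLUMNS[:-1])
    frame["q_value"] = bh_fdr(frame["p_value"].to_numpy())
    return frame


def call_differential(test_reads: list[Read], control_reads: list[Read],
                      genome: GenomeDef, *,
                      wavelet: str = "morlet",
                      shift: int = DEFAULT_SHIFT,
                      window_size: int = DEFAULT_WINDOW,
                      p_thres: float = 0.2,
                      gap: int = 0,
                      n_samples: int = 5000,
                      sample_length: int = 4096,
                      alpha: float = 0.05,
                      one_sided: bool = False,
                      normalized: bool = True,
                      seed: int = 0,
                      peak_config: PeakCallConfig | None = None,
                      ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Two-sample workflow with control swap.

    Putative peaks are called on the test sample and binomial-tested
    against the control; the samples are then swapped (peaks on the
    control) to capture regions enriched in the control, and regions
    significant at ``alpha`` from either pass are merged into one
    non-redundant differential list. ``normalized=False`` switches the
    binomial test to raw counts with a library-ratio null, exact at any
    sequencing depth. Returns (merged DMRs, per-pass
    score tables under keys 'forward' and 'swapped').
    """
    mother = MotherWavelet(wavelet)
    test = prepare_sample(test_reads, genome, shift, window_size)
    control = prepare_sample(control_reads, genome, shift, window_size)
    if test[0].library_size == 0 or control[0].library_size == 0:
        empty = pd.DataFrame(columns=["chrom", "start", "end",
                                      "directions", "min_q"])
        return empty, {"forward": pd.DataFrame(columns=DMR_COLUMNS),
                       "swapped": pd.DataFrame(columns=DMR_COLUMNS)}
    mc = MCConfig(n_samples=n_samples, sample_length=sample_length,
                  p_thres=p_thres)
    config = peak_config or PeakCallConfig.for_wavelet(wavelet, gap=gap)
    # each pass gets an identically seeded generator so that the peaks
    # called on a given sample do not depend on which input slot it
    # occupies — swapping test and control then mirrors the output
    forward = _binomial_pass(test, control, genome, mother, mc, config,
                             np.random.default_rng(seed),
                             peaks_are_test=True, one_sided=one_sided,
                             normalized=normalized)
    swapped = _binomial_pass(control, test, genome, mother, mc, config,
                             np.random.default_rng(seed),
                             peaks_are_test=False, one_sided=one_sided,
                             normalized=normalized)
    merged = _swap_merge(forward, swapped, alpha=alpha)
    return merged, {"forward": forward, "swapped": swapped}


def write_peaks_bed(frame: pd.DataFrame, path: str | Path) -> None:
    """Peaks as BED6+ : name, score = -log10 q, strand '.', then read
    count, p, q and max power columns."""
    with open(path, "w") as fh:
        for i, row in enumerate(frame.itertuples(index=False)):
            score = -np.log10(max(row.q_value, 1e-300))
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tpeak{i}\t"
                     f"{score:.4g}\t.\t{row.read_count}\t{row.p_value:.4g}\t"
                     f"{row.q_value:.4g}\t{row.max_power:.6g}\n")


def write_dmrs_bed(frame: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(frame.itertuples(index=False)):
            score = -np.log10(max(row.min_q, 1e-300))
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tdmr{i}\t"
                     f"{score:.4g}\t.\t{row.directions}\t{row.min_q:.4g}\n")
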