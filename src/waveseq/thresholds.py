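"""Monte Carlo per-scale wavelet-power significance thresholds.

Rather than assuming a background distribution, power cutoffs are
learned from the data: N contiguous segments of L windows are drawn
from the count track (chromosomes weighted by their number of eligible
segment starts), the wavelet power of each segment is evaluated at the
segment midpoint — the point farthest from the padding — and the upper
``p_thres`` empirical quantile of those midpoint powers, per scale,
becomes the calling threshold.

Because the thresholds are learned from the same track they are applied
to, the whole calling pipeline is invariant to a global rescaling of
the counts: power and thresholds both scale by the square of the
factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil, pi

import numpy as np

from .cwt import MotherWavelet, ScaleGrid, pad_length, wavelet_fourier_basis
from .preprocess import WindowTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo sampling parameters.

    ``n_samples`` random segments of ``sample_length`` windows each;
    ``p_thres`` is the upper-tail probability defining the per-scale
    power cutoff (0.2 suits punctate marks, 0.4 broad ones).
    """

    n_samples: int = 5000
    sample_length: int = 4096  # 2**12 windows
    p_thres: float = 0.2

    def __post_init__(self) -> None:
        if self.n_samples < 100:
            raise ValueError("need at least 100 Monte Carlo samples")
        L = self.sample_length
        if L < 2 or (L & (L - 1)):
            raise ValueError("sample_length must be a power of two")
        if not 0 < self.p_thres < 1:
            raise ValueError("p_thres must lie in (0, 1)")


@dataclass
class ScaleThresholds:
    """Per-scale power cutoffs plus the sampled powers that produced them."""

    thresholds: np.ndarray  # length J
    grid: ScaleGrid
    wavelet: MotherWavelet
    config: MCConfig
    midpoint_powers: np.ndarray | None = None  # N x J, diagnostics

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("scale_windows\tpower_threshold\n")
            for s, t in zip(self.grid.scales, self.thresholds):
                fh.write(f"{s:.6g}\t{t:.10g}\n")


def draw_segments(track: WindowTrack, config: MCConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw N random contiguous L-window segments from the track.

    Each segment lies entirely within one chromosome. The chromosome is
    chosen with probability proportional to its number of valid segment
    starts; chromosomes shorter than L windows are excluded. Sampling is
    with replacement. Returns an (N, L) array.
    """
    L = config.sample_length
    eligible = {c: len(v) - L + 1 for c, v in track.counts.items() if len(v) >= L}
    excluded = [c for c in track.counts if c not in eligible]
    if excluded:
        logger.info("MC sampling: %d chromosomes shorter than L=%d excluded",
                    len(excluded), L)
    if not eligible:
        raise ValueError(
            f"no chromosome has >= {L} windows; reduce sample_length")
    chroms = sorted(eligible)
    weights = np.array([eligible[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(chroms), size=config.n_samples, p=weights)
    segments = np.empty((config.n_samples, L),
                        dtype=np.asarray(next(iter(track.counts.values()))).dtype)
    for i, ci in enumerate(picks):
        chrom = chroms[ci]
        start = int(rng.integers(0, eligible[chrom]))
        segments[i] = track.counts[chrom][start:start + L]
    return segments


def midpoint_powers(segments: np.ndarray, grid: ScaleGrid,
                    wavelet: MotherWavelet, chunk: int = 512) -> np.ndarray:
    """Wavelet power at the midpoint column of each segment.

    Equivalent to running the full FFT transform on every segment and
    slicing column L/2, but computed as one matrix product per chunk:
    only a single output position of the inverse FFT is needed.
    """
    n_seg, L = segments.shape
    mid = L // 2
    npad = pad_length(L)
    w = 2 * pi * np.fft.fftfreq(npad)
    # column j: conj(wavelet spectrum at scale_j) * inverse-FFT phase at mid
    phase = np.exp(2j * pi * np.arange(npad) * mid / npad) / npad
    basis = np.column_stack([
        np.conj(wavelet_fourier_basis(wavelet, s, w)) * phase
        for s in grid.scales
    ])
    out = np.empty((n_seg, grid.J))
    for lo in range(0, n_seg, chunk):
        block = np.fft.fft(segments[lo:lo + chunk].astype(float), npad, axis=1)
        wmid = block @ basis
        if wavelet.is_complex:
            out[lo:lo + chunk] = np.abs(wmid) ** 2
        else:
            out[lo:lo + chunk] = wmid.real**2
    return out


def quantile_threshold(samples: np.ndarray, p_thres: float) -> float:
    """Upper p_thres empirical quantile: the ceil((1-p)*N)-th order
    statistic (1-based, ascending)."""
    n = len(samples)
    # ceil((1-p)*n) computed as n - floor(p*n), immune to float error
    # in (1 - p_thres) for p_thres values like 0.99
    k = n - int(np.floor(p_thres * n + 1e-9))
    k = max(k, 1)
    return float(np.partition(samples, k - 1)[k - 1])


def estimate_thresholds(segments: np.ndarray, grid: ScaleGrid,
                        wavelet: MotherWavelet, p_thres: float,
                        keep_samples: bool = True) -> ScaleThresholds:
    """Per-scale power thresholds from Monte Carlo segment samples."""
    if len(segments) < 100:
        raise ValueError("need at least 100 segments")
    powers = midpoint_powers(segments, grid, wavelet)
    cutoffs = np.array([quantile_threshold(powers[:, j], p_thres)
                        for j in range(grid.J)])
    config = MCConfig(n_samples=len(segments),
                      sample_length=segments.shape[1], p_thres=p_thres)
    return ScaleThresholds(thresholds=cutoffs, grid=grid, wavelet=wavelet,
                           config=config,
                           midpoint_powers=powers if keep_samples else None)
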