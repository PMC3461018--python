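"""Synthetic ChIP-Seq data with known enrichment ground truth.

Fragment centers are drawn from a Poisson process over each chromosome
at ``background_rate`` expected reads per window, multiplied by a fold
factor inside spiked intervals. Three archetypes of real histone-mark
and TF data are emulated by spike geometry alone: punctate (~1 kb, high
fold, H3K4me3/TFBS-like), intermediate (2-10 kb, H3K36me3-like) and
diffuse (10-100 kb, low fold, H3K27me3-like). Each center becomes a
single-end read whose 5' end sits half a fragment length upstream on a
uniformly random strand, so that shifting reads by fragment_length/2
recovers the center exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .preprocess import GenomeDef

DEFAULT_FRAGMENT = 190  # mononucleosome + linker, bp
DEFAULT_READ_LENGTH = 36
DEFAULT_BACKGROUND = 0.5  # expected reads per 200 bp window


@dataclass(frozen=True)
class Spike:
    """A ground-truth enrichment interval."""

    chrom: str
    start: int
    end: int
    fold: float
    shape: str = "block"  # "block" | "gaussian"

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("spike fold must exceed 1")
        if self.start >= self.end:
            raise ValueError("empty spike interval")
        if self.shape not in ("block", "gaussian"):
            raise ValueError(f"unknown spike shape {self.shape!r}")


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated sample."""

    genome: GenomeDef
    background_rate: float = DEFAULT_BACKGROUND  # reads per window
    spikes: tuple[Spike, ...] = ()
    fragment_length: int = DEFAULT_FRAGMENT
    read_length: int = DEFAULT_READ_LENGTH
    window_size: int = 200  # bp per rate unit

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Spike]] = {}
        for sp in self.spikes:
            if sp.chrom not in self.genome.lengths:
                raise ValueError(f"spike on unknown chromosome {sp.chrom}")
            if sp.end > self.genome.lengths[sp.chrom] or sp.start < 0:
                raise ValueError("spike outside chromosome bounds")
            by_chrom.setdefault(sp.chrom, []).append(sp)
        for chrom, sps in by_chrom.items():
            sps = sorted(sps, key=lambda s: s.start)
            for a, b in zip(sps, sps[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping spikes on {chrom}")


def punctate_spec(genome: GenomeDef | None = None,
                  spikes_per_chrom: int = 50,
                  fold: float = 20.0,
                  spike_length: int = 1000) -> SimSpec:
    """Punctate benchmark: window-aligned 1 kb fold-20 spikes at
    H3K4me3-like density (~10 per Mb) on a 2 x 5 Mb genome over
    Poisson background of 0.5 reads per 200 bp window."""
    if genome is None:
        genome = GenomeDef.from_dict({"chr1": 5_000_000, "chr2": 5_000_000})
    spikes = []
    for chrom in genome.names:
        clen = genome.lengths[chrom]
        for s in np.linspace(0.02 * clen, 0.96 * clen, spikes_per_chrom):
            start = int(round(s / 200) * 200)
            spikes.append(Spike(chrom, start, start + spike_length, fold))
    return SimSpec(genome=genome, spikes=tuple(spikes))


def broad_spec(rng: np.random.Generator,
               genome: GenomeDef | None = None,
               blocks_per_chrom: int = 5,
               fold: float = 3.0) -> SimSpec:
    """Diffuse-domain benchmark: 20-50 kb fold-3 blocks (widths drawn
    from ``rng``) on a 2 x 10 Mb genome, ~1.8% of it enriched —
    H3K27me3-like low signal-to-noise conditions."""
    if genome is None:
        genome = GenomeDef.from_dict({"chr1": 10_000_000, "chr2": 10_000_000})
    spikes = []
    for chrom in genome.names:
        clen = genome.lengths[chrom]
        starts = np.linspace(0.05 * clen, 0.90 * clen,
                             blocks_per_chrom).astype(int)
        widths = rng.integers(100, 251, size=blocks_per_chrom) * 200
        for s, w in zip(starts, widths):
            spikes.append(Spike(chrom, int(s), int(s + w), fold))
    return SimSpec(genome=genome, spikes=tuple(spikes))


def _spike_centers(spike: Spike, base_rate_per_bp: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Extra fragment centers contributed by one spike (on top of the
    homogeneous background that already covers its interval)."""
    length = spike.end - spike.start
    extra_fold = spike.fold - 1.0
    if spike.shape == "block":
        n = rng.poisson(base_rate_per_bp * extra_fold * length)
        return spike.start + rng.integers(0, length, size=n)
    # gaussian: fold tapers from the interval midpoint, sigma = length/4
    sigma = length / 4.0
    mid = (spike.start + spike.end) / 2.0
    mass = base_rate_per_bp * extra_fold * sigma * np.sqrt(2 * np.pi)
    n = rng.poisson(mass)
    pts = rng.normal(mid, sigma, size=2 * n + 16)
    pts = pts[(pts >= spike.start) & (pts < spike.end)][:n]
    while len(pts) < n:  # top up the truncated tail draws
        more = rng.normal(mid, sigma, size=n)
        more = more[(more >= spike.start) & (more < spike.end)]
        pts = np.concatenate([pts, more])[:n]
    return pts.astype(np.int64)


def simulate_reads(spec: SimSpec, rng: np.random.Generator,
                   ) -> tuple[list[tuple[str, int, int, str]], list[Spike]]:
    """Generate BED read tuples (chrom, start, end, strand) plus truth.

    Deterministic for a fixed generator state; reads are sorted by
    (chrom order, start) so output files are byte-stable.
    """
    if spec.genome.total_bp() == 0:
        raise ValueError("zero-length genome")
    rate_per_bp = spec.background_rate / spec.window_size
    half = spec.fragment_length // 2
    reads: list[tuple[str, int, int, str]] = []
    spikes_by_chrom: dict[str, list[Spike]] = {}
    for sp in spec.spikes:
        spikes_by_chrom.setdefault(sp.chrom, []).append(sp)
    for chrom in spec.genome.names:
        clen = spec.genome.lengths[chrom]
        n_bg = rng.poisson(rate_per_bp * clen)
        centers = [rng.integers(0, clen, size=n_bg)]
        for sp in spikes_by_chrom.get(chrom, []):
            centers.append(_spike_centers(sp, rate_per_bp, rng))
        centers = np.concatenate(centers) if centers else np.empty(0, np.int64)
        strands = rng.integers(0, 2, size=len(centers))  # 0 = +, 1 = -
        starts = np.where(strands == 0, centers - half,
                          centers + half + 1 - spec.read_length)
        starts = np.clip(starts, 0, max(clen - spec.read_length, 0))
        ends = np.minimum(starts + spec.read_length, clen)
        order = np.argsort(starts, kind="stable")
        for i in order:
            reads.append((chrom, int(starts[i]), int(ends[i]),
                          "+" if strands[i] == 0 else "-"))
    truth = sorted(spec.spikes, key=lambda s: (spec.genome.names.index(s.chrom), s.start))
    return reads, truth


def simulate_pair(spec: SimSpec, dmr_spikes: tuple[Spike, ...],
                  rng: np.random.Generator):
    """Matched test/control pair: shared spikes in both samples,
    ``dmr_spikes`` enriched only in the test sample, independent noise
    otherwise. Returns (test reads, control reads, DMR truth)."""
    shared = set((s.chrom, s.start, s.end) for s in spec.spikes)
    for d in dmr_spikes:
        for (c, a, b) in shared:
            if d.chrom == c and d.start < b and a < d.end:
                raise ValueError("DMR spike overlaps a shared spike")
    test_spec = replace(spec, spikes=tuple(spec.spikes) + tuple(dmr_spikes))
    test_reads, _ = simulate_reads(test_spec, rng)
    control_reads, _ = simulate_reads(spec, rng)
    truth = sorted(dmr_spikes,
                   key=lambda s: (spec.genome.names.index(s.chrom), s.start))
    return test_reads, control_reads, truth


def write_bed(reads, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (chrom, start, end, strand) in enumerate(reads):
            fh.write(f"{chrom}\t{start}\t{end}\tr{i}\t0\t{strand}\n")


def write_truth(truth: list[Spike], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, sp in enumerate(truth):
            fh.write(f"{sp.chrom}\t{sp.start}\t{sp.end}\tspike{i}\t"
                     f"{sp.fold:g}\t.\t{sp.shape}\n")


def write_chrom_sizes(genome: GenomeDef, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in genome.names:
            fh.write(f"{name}\t{genome.lengths[name]}\n")


def score_against_truth(called, truth) -> tuple[float, float]:
    """Recall and precision by >= 1 bp overlap.

    ``called`` and ``truth`` are iterables of (chrom, start, end) or
    objects with those attributes. A truth interval counts as recovered
    if any call overlaps it; a call counts as true if it overlaps any
    truth interval. With zero calls precision is reported as 1.0.
    """

    def _norm(items):
        out = []
        for it in items:
            if hasattr(it, "chrom"):
                out.append((it.chrom, it.start, it.end))
            else:
                out.append((it[0], int(it[1]), int(it[2])))
        return out

    calls = _norm(called)
    truths = _norm(truth)
    if not truths:
        recall = 1.0
    else:
        hit = 0
        for tc, ts, te in truths:
            if any(c == tc and s < te and ts < e for c, s, e in calls):
                hit += 1
        recall = hit / len(truths)
    if not calls:
        return recall, 1.0
    true_calls = sum(
        1 for c, s, e in calls
        if any(tc == c and s < te and ts < e for tc, ts, te in truths)
    )
    return recall, true_calls / len(calls)
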