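"""Read ingestion and window-count track construction.

Reads arrive as 6-column BED intervals. They are deduplicated, shifted
towards the fragment center (95 bp by default, half of a ~190 bp
mononucleosome fragment), and binned into fixed non-overlapping windows
(200 bp by default) per chromosome. All coordinates are 0-based,
half-open, in the BED dialect.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_SHIFT = 95
DEFAULT_WINDOW = 200


@dataclass(frozen=True)
class Read:
    """A single aligned read: 0-based half-open interval plus strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid read interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class GenomeDef:
    """Ordered chromosome names and lengths in bp."""

    names: tuple[str, ...]
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        for name in self.names:
            if self.lengths[name] <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeDef":
        return cls(names=tuple(lengths), lengths=dict(lengths))

    def n_windows(self, chrom: str, window_size: int) -> int:
        return -(-self.lengths[chrom] // window_size)  # ceil division

    def total_bp(self) -> int:
        return sum(self.lengths.values())


@dataclass
class ReadSet:
    """Per-chromosome sorted arrays of shifted fragment-center positions."""

    positions: dict[str, np.ndarray]
    library_size: int

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of centers in [start, end) on ``chrom``."""
        pos = self.positions.get(chrom)
        if pos is None:
            return 0
        return int(np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left"))


@dataclass
class WindowTrack:
    """Per-chromosome read counts over fixed non-overlapping windows."""

    window_size: int
    counts: dict[str, np.ndarray]
    library_size: int
    normalized: bool = False

    def total(self) -> float:
        return float(sum(c.sum() for c in self.counts.values()))


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_chrom_sizes(path: str | Path) -> GenomeDef:
    """Parse a two-column chromosome-sizes table (name, length in bp)."""
    lengths: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            lengths[fields[0]] = int(fields[1])
    return GenomeDef.from_dict(lengths)


def read_bed(path: str | Path, genome: GenomeDef) -> list[Read]:
    """Parse a 6-column BED file of aligned reads.

    Columns 4-5 (name, score) are ignored. Reads on chromosomes absent
    from ``genome`` are skipped with a warning; malformed lines are a
    hard error naming the line number.
    """
    reads: list[Read] = []
    skipped = 0
    known = set(genome.names)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith(("#", "track", "browser")):
                continue
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, start_s, end_s, _name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            if chrom not in known:
                skipped += 1
                continue
            reads.append(Read(chrom, start, end, strand))
    if skipped:
        logger.warning("skipped %d reads on chromosomes absent from the genome", skipped)
    return reads


def deduplicate(reads: Iterable[Read]) -> list[Read]:
    """Drop exact duplicates, keeping the first occurrence.

    The duplicate key is (chrom, start, end, strand) — the conservative
    PCR-duplicate definition for fixed-length single-end reads.
    """
    seen: set[tuple[str, int, int, str]] = set()
    kept: list[Read] = []
    for read in reads:
        key = (read.chrom, read.start, read.end, read.strand)
        if key not in seen:
            seen.add(key)
            kept.append(read)
    logger.info("deduplicate: retained %d reads", len(kept))
    return kept


def shift_reads(reads: Iterable[Read], shift_bp: int, genome: GenomeDef) -> ReadSet:
    """Shift each read from its 5' end towards the fragment center.

    Plus-strand reads map to ``start + shift_bp``; minus-strand reads to
    ``(end - 1) - shift_bp``. Positions are clamped to the chromosome so
    no read is lost, and sorted per chromosome.
    """
    if shift_bp < 0:
        raise ValueError("shift_bp must be >= 0")
    per_chrom: dict[str, list[int]] = {name: [] for name in genome.names}
    total = 0
    for read in reads:
        if read.strand == "+":
            pos = read.start + shift_bp
        else:
            pos = (read.end - 1) - shift_bp
        limit = genome.lengths[read.chrom] - 1
        pos = min(max(pos, 0), limit)
        per_chrom[read.chrom].append(pos)
        total += 1
    positions = {
        chrom: np.sort(np.asarray(plist, dtype=np.int64))
        for chrom, plist in per_chrom.items()
    }
    return ReadSet(positions=positions, library_size=total)


def bin_counts(readset: ReadSet, window_size: int, genome: GenomeDef) -> WindowTrack:
    """Count shifted centers in non-overlapping windows of ``window_size`` bp.

    Window ``i`` covers ``[i*w, (i+1)*w)``; the last window of each
    chromosome may be short.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    counts: dict[str, np.ndarray] = {}
    for chrom in genome.names:
        n_win = genome.n_windows(chrom, window_size)
        pos = readset.positions.get(chrom)
        if pos is None or len(pos) == 0:
            counts[chrom] = np.zeros(n_win, dtype=np.int64)
            continue
        counts[chrom] = np.bincount(pos // window_size, minlength=n_win).astype(np.int64)
    return WindowTrack(
        window_size=window_size,
        counts=counts,
        library_size=readset.library_size,
        normalized=False,
    )


def normalize_per_million(track: WindowTrack) -> WindowTrack:
    """Scale all counts to reads-per-million mapped reads."""
    if track.normalized:
        raise ValueError("track is already normalized")
    if track.library_size <= 0:
        raise ValueError("cannot normalize a track with zero library size")
    factor = 1e6 / track.library_size
    counts = {chrom: c.astype(np.float64) * factor for chrom, c in track.counts.items()}
    return WindowTrack(
        window_size=track.window_size,
        counts=counts,
        library_size=track.library_size,
        normalized=True,
    )


def write_bedgraph(track: WindowTrack, genome: GenomeDef, path: str | Path) -> None:
    """Write a window-count track as bedGraph (zero windows skipped)."""
    with open(path, "w") as fh:
        for chrom in genome.names:
            counts = track.counts[chrom]
            chrom_len = genome.lengths[chrom]
            w = track.window_size
            for i in np.nonzero(counts)[0]:
                start = int(i) * w
                end = min(start + w, chrom_len)
                value = counts[i]
                text = f"{value:.6g}" if track.normalized else f"{int(value)}"
                fh.write(f"{chrom}\t{start}\t{end}\t{text}\n")


def read_bedgraph(path: str | Path, genome: GenomeDef, window_size: int,
                  library_size: int = 0, normalized: bool = False) -> WindowTrack:
    """Reconstruct a WindowTrack from a window-aligned bedGraph file."""
    dtype = np.float64 if normalized else np.int64
    counts = {
        chrom: np.zeros(genome.n_windows(chrom, window_size), dtype=dtype)
        for chrom in genome.names
    }
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith(("#", "track")):
                continue
            chrom, start, _end, value = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if chrom not in counts:
                continue
            if start % window_size:
                raise ValueError(f"{path}:{lineno}: interval not window-aligned")
            counts[chrom][start // window_size] = float(value) if normalized else int(value)
    return WindowTrack(window_size=window_size, counts=counts,
                       library_size=library_size, normalized=normalized)
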