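"""Distribution-free significance for putative peaks.

One-sample mode builds a randomized empirical null: peak lengths are
resampled with replacement from the putative-peak length distribution,
dropped uniformly onto the genome, and the read counts they capture
form the null frequency table F(R). A peak with r reads gets the
permutation p-value (1 + #{null >= r}) / (P + 1) — the +1 pseudocount
keeps p strictly positive, differing from the plain tail fraction by at
most 1/P.

Two-sample mode treats each putative peak as a Bernoulli experiment on
the per-million-normalized test and control read counts, with an exact
binomial test of H0: success probability 1/2. The default is two-sided
(minimum-likelihood method); the one-sided upper tail P(X >= T) is
available.

Benjamini-Hochberg step-up correction is applied genome-wide, and a
control-swap merge produces a non-redundant differential-region list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import GenomeDef, ReadSet
from .peaks import PutativePeak


@dataclass
class RandomizedNull:
    """Empirical null distribution of read counts in randomized peaks.

    ``sorted_counts`` holds the P null read counts in ascending order;
    the frequency table F(R) and its survival function are derived
    views of it.
    """

    sorted_counts: np.ndarray
    n_draws: int

    def frequency_table(self) -> pd.Series:
        """F(R): number of randomized peaks with read count R."""
        values, counts = np.unique(self.sorted_counts, return_counts=True)
        return pd.Series(counts, index=values, name="F")

    def survival(self, r: int | np.ndarray) -> np.ndarray:
        """#{randomized peaks with count >= r}."""
        idx = np.searchsorted(self.sorted_counts, r, side="left")
        return self.n_draws - idx


def build_randomized_null(peaks: list[PutativePeak], readset: ReadSet,
                          genome: GenomeDef, n_draws: int,
                          rng: np.random.Generator) -> RandomizedNull:
    """Randomize length-matched intervals over the genome and count reads.

    Each of ``n_draws`` intervals takes a length drawn with replacement
    from the putative-peak length multiset and a uniform position: the
    chromosome is chosen proportional to its number of valid start
    positions for that length, so placement is uniform over all genomic
    positions where the interval fits entirely.
    """
    if not peaks:
        raise ValueError("need at least one putative peak to build the null")
    if n_draws < 1:
        raise ValueError("n_draws must be positive")
    lengths = np.array([p.length for p in peaks], dtype=np.int64)
    max_chrom = max(genome.lengths.values())
    if lengths.max() > max_chrom:
        raise ValueError("a putative peak is longer than every chromosome")
    drawn = rng.choice(lengths, size=n_draws, replace=True)
    chrom_names = list(genome.names)
    chrom_lens = np.array([genome.lengths[c] for c in chrom_names], dtype=np.int64)
    all_counts = np.empty(n_draws, dtype=np.int64)
    out_pos = 0
    for ell in np.unique(drawn):
        n_ell = int((drawn == ell).sum())
        valid = np.maximum(chrom_lens - ell + 1, 0)
        weights = valid / valid.sum()
        picks = rng.choice(len(chrom_names), size=n_ell, p=weights)
        counts_ell = np.empty(n_ell, dtype=np.int64)
        for ci in np.unique(picks):
            sel = picks == ci
            n_c = int(sel.sum())
            starts = rng.integers(0, valid[ci], size=n_c)
            pos = readset.positions.get(chrom_names[ci])
            if pos is None or len(pos) == 0:
                counts_ell[sel] = 0
            else:
                lo = np.searchsorted(pos, starts, side="left")
                hi = np.searchsorted(pos, starts + ell, side="left")
                counts_ell[sel] = hi - lo
        all_counts[out_pos:out_pos + n_ell] = counts_ell
        out_pos += n_ell
    return RandomizedNull(sorted_counts=np.sort(all_counts), n_draws=n_draws)


def one_sample_pvalue(r: int | np.ndarray, null: RandomizedNull) -> np.ndarray | float:
    """Permutation p-value: (1 + #{null >= r}) / (P + 1)."""
    p = (1 + null.survival(r)) / (null.n_draws + 1)
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(p)
    return p


def binomial_two_sample(t_raw: int, c_raw: int, lib_t: int, lib_c: int,
                        one_sided: bool = False,
                        normalized: bool = True) -> tuple[float, int, int]:
    """Exact binomial test comparing test vs control read counts.

    In the default normalized mode, counts are scaled to per-million and
    rounded to the nearest integer; with t = T_norm + C_norm trials the
    test counts T_norm successes under H0: p = 1/2. Two-sided (default)
    uses the minimum-likelihood rule, which at p0 = 1/2 reduces to
    doubling the smaller tail; one-sided reports P(X >= T_norm).

    With ``normalized=False`` the raw counts are tested directly with
    null success probability lib_T / (lib_T + lib_C). This is exact at
    any sequencing depth, whereas per-million rounding distorts the
    Bernoulli variance when library sizes are far from 10^6.

    Returns (p, T_norm, C_norm) — the per-million counts are reported
    in either mode.
    """
    if t_raw < 0 or c_raw < 0:
        raise ValueError("read counts must be non-negative")
    if lib_t <= 0 or lib_c <= 0:
        raise ValueError("library sizes must be positive")
    t_norm = int(round(t_raw * 1e6 / lib_t))
    c_norm = int(round(c_raw * 1e6 / lib_c))
    if normalized:
        successes, trials, p0 = t_norm, t_norm + c_norm, 0.5
    else:
        successes, trials, p0 = t_raw, t_raw + c_raw, lib_t / (lib_t + lib_c)
    if trials == 0:
        return 1.0, t_norm, c_norm
    if one_sided:
        p = float(stats.binom.sf(successes - 1, trials, p0))
    elif normalized:
        # symmetric null: min-likelihood outcomes are the two mirror tails
        low = min(successes, trials - successes)
        p = float(min(1.0, 2.0 * stats.binom.cdf(low, trials, 0.5)))
    else:
        p = float(stats.binomtest(successes, trials, p0).pvalue)
    # deep tails can underflow to exactly 0, which BH cannot accept
    p = max(min(p, 1.0), 1e-300)
    return p, t_norm, c_norm


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def swap_merge(dmrs_forward: pd.DataFrame, dmrs_reverse: pd.DataFrame,
               alpha: float = 0.05) -> pd.DataFrame:
    """Merge significant regions from the forward and swapped passes.

    Keeps rows with q < alpha from each pass, unions intervals that
    overlap by at least 1 bp, and annotates each merged region with the
    contributing direction labels and the minimum q among its parts.
    """
    frames = []
    for df in (dmrs_forward, dmrs_reverse):
        if len(df):
            frames.append(df.loc[df["q_value"] < alpha,
                                 ["chrom", "start", "end", "direction", "q_value"]])
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "directions", "min_q"])
    pooled = pd.concat(frames, ignore_index=True)
    if pooled.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "directions", "min_q"])
    pooled = pooled.sort_values(["chrom", "start", "end"], kind="stable")
    rows = []
    cur = None
    for rec in pooled.itertuples(index=False):
        if cur is not None and rec.chrom == cur["chrom"] and rec.start < cur["end"]:
            cur["end"] = max(cur["end"], rec.end)
            cur["dirs"].add(rec.direction)
            cur["min_q"] = min(cur["min_q"], rec.q_value)
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"chrom": rec.chrom, "start": rec.start, "end": rec.end,
                   "dirs": {rec.direction}, "min_q": rec.q_value}
    if cur is not None:
        rows.append(cur)
    return pd.DataFrame({
        "chrom": [r["chrom"] for r in rows],
        "start": [r["start"] for r in rows],
        "end": [r["end"] for r in rows],
        "directions": [",".join(sorted(r["dirs"])) for r in rows],
        "min_q": [r["min_q"] for r in rows],
    })
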