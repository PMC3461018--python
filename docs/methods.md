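# Methods

## Model and rationale

ChIP-Seq enrichment comes in very different shapes: transcription-factor
binding and H3K4me3 give sharp ~1 kb pile-ups, H3K36me3 marks gene
bodies over 2–10 kb, and H3K27me3 spreads over tens of kilobases at low
signal-to-noise. Local read-count statistics tuned for one regime fail
in another. The approach here scores enrichment through the continuous
wavelet power spectrum of the window-count track: the power |W(s, t)|²
responds to a bump of width ~s windows at position t, so a single
decomposition covers all feature widths at once, and the detection
scale is chosen per mark class rather than per window.

Nothing parametric is assumed about the background. Both the
window-level detection threshold and the peak-level significance are
learned from the data itself: an empirical per-scale power distribution
(Monte Carlo segments), and an empirical read-count null
(length-matched randomized intervals) or an exact binomial comparison
against a matched control.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| window_size | 200 bp | binning resolution of the count track |
| shift | 95 bp | 5'-to-fragment-center shift (≈ half of a 190 bp mononucleosome fragment); override for TF libraries with a different fragment size |
| wavelet | morlet (ω₀ = 6) | Mexican hat for > 10 kb domains |
| s₀, dj | 2 windows, 0.25 | dyadic scale grid s_j = s₀·2^(j·dj), capped at min(1024, L/4) |
| N, L | 5000, 2¹² windows | Monte Carlo segment count and length |
| p_thres | 0.2 / 0.4 | upper-tail probability of the per-scale power threshold; looser for broad marks |
| g | 0 / 2 / 5 / 10 | max bridged non-significant windows (TF / H3K4me3 / H3K36me3 / H3K27me3) |
| P | 10⁶ | randomized-null draws (one-sample) |
| α | 0.05 | BH-FDR cutoff for reporting / swap merge |

### Scale bands and the persistence rule

The mother wavelet determines the response shape, but which scales
*trigger* a call is a free design choice. Three presets are provided:

* punctate — Morlet, scales 4–12 windows (equivalent Fourier periods
  ≈ 0.8–2.5 kb at 200 bp windows);
* intermediate — Morlet, scales 4–48 (≈ 0.8–10 kb);
* broad — Mexican hat, scales 8–64 (equivalent periods ≈ 6–50 kb;
  the Mexican hat's Fourier period is ≈ 3.97·s).

Restricting the band matters. At large scales a p_thres-level
exceedance covers runs of hundreds of windows, so an unrestricted band
floods the putative-peak list with long background segments; those long
lengths then enter the randomized null's length distribution and fatten
its read-count tail, destroying the contrast between real peaks and the
null. Matching the band to the expected feature width keeps background
runs short and the null sharp.

A window is called significant only when its power exceeds the
threshold at `min_scales = 3` scales within the band (a ~1.4× scale
range at dj = 0.25). Noise exceedances are mostly isolated in scale
while genuine enrichment persists across neighbouring scales; the
persistence requirement cuts the spurious-window rate several-fold at
no cost in read capture. Setting `min_scales = 1` recovers plain
any-scale thresholding. Both wavelets also require a positive
coefficient at the scale of largest excess: power is sign-blind, and
for the real-valued Mexican hat in particular a depletion trough
carries as much power as an enrichment bump.

### Thresholding details

Thresholds are learned from N random contiguous L-window segments
(chromosomes weighted by eligible starts, sampling with replacement;
chromosomes shorter than L are excluded from sampling but still
called). The power is evaluated at each segment's midpoint — the point
farthest from the zero padding — and the per-scale threshold is the
⌈(1−p_thres)·N⌉-th order statistic of those N powers. By construction
the fraction of sampled powers above the threshold is p_thres ± 1/N.
Thresholds are pooled across chromosomes by default (per-chromosome
mode available), and raw counts are used rather than per-million
values: thresholds learned from the same track make every calling
decision invariant to a global rescaling of the counts, since power
and thresholds both scale by the square of the factor.

## Numerical choices

* FFT convolution uses the analytic Fourier form of each wavelet with
  unit-energy normalization √(2πs) and zero padding to the next power
  of two ≥ 4·T. The generous padding keeps the circular convolution
  equal to the linear one to ~1e-12 even at the largest grid scale;
  with minimal padding the wrap-around error at scale T/4 reaches
  ~1e-3 relative.
* Positions within the e-folding distance √2·s of either signal end
  are inside the cone of influence; peaks touching it are flagged
  (`boundary`) but never dropped, so telomeric enrichment is retained.
* Morlet scales below ~4 windows under-sample the oscillation (the
  spectrum at the Nyquist frequency is no longer negligible), which is
  one reason the punctate band starts at scale 4.
* The empirical p-value carries a +1 pseudocount,
  p = (1 + #{null ≥ r}) / (P + 1), so p is never 0 (a raw tail
  fraction of 0 breaks both BH and log-scored output); it differs from
  the plain fraction by at most 1/P.
* The two-sided exact binomial test at H₀: p = ½ uses the
  minimum-likelihood rule, which for a symmetric null equals the
  doubled smaller tail; p-values are floored at 1e-300 against
  underflow. Normalized counts are rounded to the nearest integer
  before testing.
* The BH step-up is the standard sorted cumulative-minimum
  implementation, applied genome-wide per analysis pass.
* Both passes of the two-sample workflow use identically seeded
  generators, so the peaks called on a given sample do not depend on
  which input slot it occupies; swapping test and control exactly
  mirrors the output (directions flip, intervals unchanged).

## Two-sample normalization caveat

Per-million scaling treats the rounded normalized counts as Bernoulli
trials. That is well calibrated when library sizes are near 10⁶ (the
regime of real ChIP libraries, where the factor is ≤ 1) but inflates
variance when small libraries are scaled *up*, making the test
anticonservative on toy data. The `normalized=False` mode
(`--raw-counts`) instead tests the raw counts with null success
probability lib_T/(lib_T + lib_C), which is exact at any depth; the
calibration tests use it, and it is the statistically cleaner choice
whenever exactness matters more than matching the classical recipe.

## Synthetic data

The generator draws fragment centers from a per-chromosome Poisson
process (default 0.5 expected reads per 200 bp window, the density of
a ~10 M-read mammalian library) and multiplies the rate by a fold
factor inside spiked intervals (block profile, or Gaussian with
σ = length/4). Each center becomes a fixed-length read on a uniform
random strand with its 5' end half a fragment upstream, so the standard
shift recovers the center exactly. Two canonical benchmarks are frozen
as constructors:

* `punctate_spec()` — 2 × 5 Mb genome, 100 window-aligned 1 kb spikes
  at fold 20 (≈ H3K4me3 peak density of ~10 per Mb);
* `broad_spec(rng)` — 2 × 10 Mb genome, 10 blocks of 20–50 kb at
  fold 3 (≈ 1.8% of the genome enriched, H3K27me3-like SNR).

What the generator does **not** model: mappability and GC structure,
PCR duplicates, fragment-length dispersion, copy-number variation, and
the pervasive low-grade enrichment of real chromatin. Passing the
spike-in benchmarks therefore demonstrates the machinery's
correctness and its behaviour under idealized Poisson noise, not
performance on real libraries, where background autocorrelation makes
all peak callers less precise.

Self-contamination of the randomized null is real and intended: null
intervals landing on true enrichment inflate the null tail in
proportion to the enriched genome fraction, exactly as in real
low-SNR marks, which is why the broad benchmark keeps its blocks at a
realistic ~2% of the genome.

## Problem sizes used in the shipped checks

The acceptance script and end-to-end tests run the punctate benchmark
at full method defaults (N = 5000, P = 10⁶), the broad benchmark the
same, and the spike-free calibration at N = 1000, P = 10⁵ over 20
replicates of a 10 Mb genome — sizes at which every Monte Carlo
estimate is stable to the tolerances asserted while the whole suite
stays interactive on a single CPU.

## Known limitations

* The randomized null conditions only on peak length and total read
  count; within-peak shape is never scored, so a diffuse and a sharp
  interval with equal counts are equally significant.
* p-values are granular at 1/(P+1); with very many putative peaks the
  BH correction near the floor is conservative.
* Window-level resolution is 200 bp; no sub-window summit estimation.
* The per-million binomial mode's calibration depends on library size
  (see above).
* Thresholds assume the track is wide-sense stationary at the sampled
  segment scale; strong chromosome-wide trends (e.g. copy-number
  amplifications) will raise thresholds globally rather than locally.
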