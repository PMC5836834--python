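# Methods

## Problem setting and model

The pipeline targets diurnal expression time courses sampled at a fixed
interval Δ (hours) over `c` complete cycles of a fixed period `P = 24 h`:
sample times `t_i = iΔ`, `i = 0 … cP/Δ − 1`. Because the sampling is
sparse (6–8 points per cycle), no attempt is made to estimate a continuous
acrophase; instead each gene is assigned to one of `n = P/Δ` discrete
phases whose peaks coincide with the sample-collection times. With Δ = 3 h
there are 8 phases with 6-h confidence intervals; with Δ = 4 h, 6 phases
with 8-h intervals. Phase `p` has peak `pΔ` and wrapped confidence
interval `[pΔ − Δ, pΔ + Δ] mod P` — phase 0 under 3-h sampling spans
ZT21–ZT3, phase 1 ZT0–ZT6, and so on; adjacent intervals deliberately
overlap by one sampling interval.

The implicit signal model is a single cosine at the circadian frequency
plus i.i.d. noise,

    x(t_i) = b + A·cos(2π(t_i − φ)/P) + ε_i ,

which is also exactly what the synthetic generator draws. The classifier
only uses the Pearson correlation between a z-scored profile and the
template bank, so it is invariant to `b` and `A > 0` and depends on the
noise only through the profile's shape.

## Normalization

Samples are forced onto a common distribution with quantile normalization
`x_norm = F₂⁻¹(G(x))`. The reference `F₂⁻¹` is the mean of the samples'
order statistics, optionally smoothed with a seven-point Savitzky–Golay
filter of polynomial order 2 (order 2 reproduces linear trends exactly and
is the canonical smoothing choice; the window is a parameter but 7 is the
default). The smoothed reference is re-sorted ascending because a quantile
function must be non-decreasing and the filter can introduce tiny local
inversions. Ties within a sample get average ranks and hence averaged
(linearly interpolated) reference values, keeping the map monotone and
deterministic. Each gene profile is then z-scored with the sample
(n−1) standard deviation; constant profiles carry no phase information and
are dropped with a logged count.

Two exact fixed-point properties hold and are tested: after
transformation every sample's sorted values equal the reference
(tie-free case), and re-quantile-normalizing the output (reference
recomputed, no re-smoothing) is the identity. Note the full stage
sequence quantile → z-score is *not* idempotent as a whole: z-scoring is
row-wise and destroys the common column distribution, so a complete
second pass changes values at the 0.1-level. The stages are idempotent
individually, not jointly.

## Periodicity gate (permutation test at one frequency)

The gate statistic is the periodogram power at the single circadian
frequency, the DFT bin completing `c` oscillations over the record:
`S = |Σ_k x_k e^{−2πi c k/n}|² / n`. The null distribution is generated by
uniformly shuffling the time order of the profile (values and hence total
power preserved; temporal arrangement destroyed), giving

    p = (1 + #{shuffles with S* ≥ S}) / (B + 1),   B = 999 by default.

Genes with `p < α` (default 0.05) are kept. No multiplicity correction is
applied, deliberately: peripheral-tissue oscillators are synchronized to a
single circadian factor, so the per-gene tests probe one shared hypothesis
rather than a family of independent ones, and an FDR step would only
shrink the gene list. The exact permutation scheme of the historical
signal-to-noise gate this mirrors is not published in detail; this module
is a documented reconstruction (single-frequency power + time
permutation), not a verbatim reimplementation.

A design with a single cycle and fewer than 4 samples cannot resolve the
circadian bin and is rejected. At n = 6 the tie structure of the statistic
is fully enumerable: only rotations/reflections of a cosine arrangement
tie its power, which the tests verify exhaustively.

## Phase assignment and confidence

Templates are discrete cosines evaluated at the sample times, one per
phase. Assignment is the argmax of Pearson correlation over the bank;
exact ties (a peak equidistant between two collection times) break toward
the smaller phase index, with a 1e-12 tolerance so the rule is stable
against floating-point jitter. Negating a profile moves its call by
exactly half the bank (antiphase); scaling and shifting do not move it.

Confidence in a call uses the maximum entropy bootstrap for short
non-stationary series. For a profile of length n the replicate
construction is: order statistics; interval midpoints
`z_k = (x_(k)+x_(k+1))/2`; tails `z_0 = x_(1) − m`, `z_n = x_(n) + m` with
`m` the 10%-trimmed mean of absolute successive differences of the
time-ordered series; desired interval means
`(0.75, 0.25) / (0.25, 0.5, 0.25) / (0.25, 0.75)` convex combinations of
neighboring order statistics; n i.i.d. uniforms mapped through the
piecewise-linear quantile function over intervals of mass 1/n with a
constant within-interval shift to hit the desired means (interior
midpoints already equal the desired means, so only the two edge intervals
shift, by ±m/2, and draws never leave `[z_0, z_n]`); finally the sorted
draws are reordered to the source's rank sequence. The desired means sum
to `Σx`, so the ensemble is mean-preserving. Replicate dispersion
expansion steps found in some implementations of the algorithm are *not*
applied: they would break the support bound and the clean rank/mean
invariants that the construction above guarantees and the tests pin down.

Each of B replicates (default 999; 199 in tests) is re-classified against
the bank, and

    confidence_p = (1 + #{replicates with peak outside [peak* − Δ, peak* + Δ]}) / (B + 1).

The window criterion (endpoints inclusive, so an adjacent phase still
counts as inside) is the default, matching the overlapping per-phase
confidence intervals; a strict variant ("any other phase counts as
outside") is available via `criterion="strict"`. Confident groups use
`confidence_p < α` with α = 0.05 by default (α = 0.10, i.e. 90%
confidence, is the documented alternative).

**What this p-value is and is not.** Because replicates preserve the rank
order of the source exactly, they are strongly correlated with it
(Pearson ≈ 0.95 for n = 12), and the re-assigned phase rarely leaves the
±Δ window even for pure-noise profiles. The confidence p-value therefore
measures *stability of the peak location under mean-preserving,
shape-preserving resampling* — a signal-strength-independent sharpness
measure — and must not be read as a frequentist error rate against an
independent-noise null: on its own it passes a large fraction of i.i.d.
noise profiles (measured ≈ 0.88 at α = 0.05 under the window criterion,
≈ 0.22 under the strict one). In the pipeline it is always applied *after*
the periodicity gate, so the end-to-end pass rate for pure noise is the
product ≈ 0.05 × 0.88 ≈ 4%. This behavior is intrinsic to rank-preserving
bootstrap schemes and is surfaced honestly by the calibration test suite
rather than patched by inflating replicate dispersion.

Reproducibility: one seed per run; per-gene bootstrap and permutation
streams are spawned from it by row index (`numpy.random.SeedSequence`), so
results are independent of gene processing order and bit-identical across
re-runs.

## Enrichment

For each (term, phase-group) cell: `p = P(X ≥ k)` with
`X ~ Hypergeometric(N, K, n)` — `N` universe genes (the whole array is the
background), `K` term carriers, `n` group size, `k` observed carriers.
Computed via the survival function with stable tail summation and clipped
into `(0, 1]`. A Benjamini–Hochberg column across the 6–8 phases within
each term row is reported for reference only; the default highlighting
(`p ≤ 0.05`) uses the raw p-values, consistent with the dependence
argument above. The wide view appends a per-phase "Number of genes" row.
The unit of analysis is the gene identifier; any probe→gene collapsing is
assumed done at ingestion. The discrete hypergeometric tail is
super-uniform under the null, so the realized false-positive fraction at
0.05 depends on the (K, n, N) geometry; the calibration test uses
K = 100, n = 300, N = 1000, whose exact null rate is 0.044.

## Synthetic data

`generate_expression` draws: a fixed fraction of oscillating genes
(default 0.5 — historical analyses of comparable tissue panels put the
oscillating share anywhere between ~20% and >90%, so the generator sits in
the middle); amplitudes log-uniform on [0.5, 4.0] against noise sd 0.5,
spanning SNR 1–8 so both easy and marginal genes exist; baselines uniform
on [6, 12] (a log2-intensity-like scale); peak times on the sampling grid
by default (for exact recovery scoring) or uniform in [0, 24); Gaussian
i.i.d. noise. The default design is 4-h sampling over two cycles
(12 samples, 6 phases) — two cycles are the minimum for a well-resolved
single-frequency permutation test. `generate_annotation` plants terms by
drawing a Binomial(genes_per_term, excess_fraction) share of each planted
term's genes from the target phase's true oscillators and the rest
uniformly; unplanted terms sample uniformly from the universe.

What the generator does **not** emulate: probe-level artifacts,
cross-hybridization, batch effects, heteroskedastic or autocorrelated
noise, non-sinusoidal waveforms, and probe→gene redundancy. Passing
recovery tests therefore demonstrates correctness of the machinery under
the stated model, not performance on raw array data.

## Numerical choices and edge cases

- Zeitgeber headers `ZT<number>` (case-insensitive) or bare numbers are
  parsed and columns reordered to design time order; anything else
  requires `assume_design_order=True`. Missing values are rejected at
  ingestion — every downstream statistic assumes complete profiles.
- Times are real hours wrapped into `[0, P)` (half-open).
- Permutation/bootstrap p-values are bounded below by `1/(B+1)`; B ≥ 99
  is enforced everywhere.
- Constant profiles: excluded at z-scoring (normalization), power 0 /
  p = 1 at the gate, and rejected by the bootstrap (zero variance).
- Reference smoothing falls back to the identity (with a warning) when
  the matrix has fewer genes than the window.
- Problem sizes used by the behavioral test suite: 1000 genes for phase
  recovery at SNR 4 (B = 199), 2000 genes for gate calibration (B = 999),
  500 genes for confidence calibration, 100 repeats for planted-enrichment
  recovery, 10,000 replicates for the bootstrap mean check — sizes chosen
  so Monte-Carlo error is well inside the asserted bands.

## Known limitations

- The phase-confidence statistic is a stability measure, not a
  noise-calibrated test (see above); it must be used downstream of the
  periodicity gate.
- Period is fixed (24 h); no period estimation, multi-frequency testing,
  harmonic regression, or continuous acrophase CIs.
- The permutation gate's historical counterpart is reconstructed, not
  reproduced; published gene counts from proprietary array data are out of
  reach and the pipeline reproduces the *shape* of such analyses on
  synthetic data instead.
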