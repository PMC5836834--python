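# circaphase

Phase assignment for circadian gene-expression time courses.

Bulk transcriptome time courses sampled every 3–4 h over one or two 24-h
cycles are too sparse to estimate a continuous peak time per gene, yet many
questions — *which cellular functions are active at which time of day?* —
only need genes grouped by *when* they peak. `circaphase` implements a
discrete-phase pipeline for exactly this setting:

1. **Normalization** — quantile normalization of every sample to a common
   reference distribution `x_norm = F₂⁻¹(G(x))`, where `G` is the sample's
   empirical distribution function and `F₂` the reference (the average of
   the samples' order statistics, smoothed with a seven-point
   Savitzky–Golay filter), followed by per-gene z-scoring.
2. **Periodicity gate** — a permutation test on periodogram power at the
   single circadian frequency: `p = (1 + #{shuffles with power ≥ observed})
   / (B + 1)`, uncorrected for multiplicity (all genes are probed for one
   shared circadian factor, not independent hypotheses).
3. **Phase assignment** — each profile is classified to the nearest of
   `n_phases = period / interval` discrete cosine templates
   `cos(2π(t − p·Δ)/24)` anchored at the sample-collection times (8 phases
   for 3-h sampling, 6 for 4-h), by maximum Pearson correlation.
4. **Phase confidence** — the profile is resampled with the maximum
   entropy bootstrap (rank-preserving replicates from a maximum-entropy
   density over the observed order statistics); the confidence p-value is
   the fraction of replicates whose re-assigned peak leaves the called
   phase's confidence interval `[peak − Δ, peak + Δ]` (wrapped mod 24; the
   ZT0 phase under 3-h sampling spans ZT21–ZT3).
5. **Enrichment** — each confident phase group is tested for annotation-term
   over-representation against the whole-array background with the
   hypergeometric upper tail `P(X ≥ k)`, plus a per-term Benjamini–Hochberg
   column for reference.

A synthetic-data generator with full ground truth (which genes oscillate,
at which phase and amplitude, which annotation terms are planted into which
phase group) backs every stage, so the whole pipeline is testable end to
end without proprietary array data.

## Worked example

```yaml
# demo.yaml
seed: 42
n_genes: 1000          # 500 oscillating + 500 flat
frac_oscillating: 0.5
noise_sd: 0.5          # amplitudes 0.5-4.0 => SNR 1-8
n_terms: 30
genes_per_term: 25
planted:               # two terms tilted into phase groups 0 (ZT0) and 3 (ZT12)
  - [0, 0.8]
  - [3, 0.8]
filter_permutations: 999
phase_boot: 199
```

```sh
circaphase -v run-all --config demo.yaml --out demo
```

The run writes the simulated matrix plus truth tables, then
`normalized.tsv`, `periodicity.tsv`, `kept.txt`, `assignments.tsv`,
`enrichment.tsv` (+ wide and abundance views) and a `manifest.json` that
replays the run bit-identically. With this configuration the periodicity
gate keeps 475 of 1000 genes (442 truly oscillating, 33 noise genes — the
gate runs at uncorrected α = 0.05 by design), and 91% of the confident
phase calls hit the true simulated peak time. `assignments.tsv` holds one
call per kept gene:

```
gene_id  phase_index  peak_zt  correlation     confidence_p
g0000    4            16       0.96979218299   0.005
g0001    4            16       0.917909150982  0.005
g0002    5            20       0.976825280447  0.005
```

`enrichment_wide.tsv` mirrors a published-style term × phase p-value
matrix; the two planted terms surface exactly where they were planted
(phase 0 and phase 3 columns):

```
term_id  0          1       2       3          4       5
T00      1.291e-17  1       0.8945  0.8074     1       1
T01      1          0.9029  1       6.806e-18  0.9306  1
T02      0.0732     0.9029  0.6429  0.8074     0.7326  0.5644
```

Each stage is also available separately (`circaphase simulate | normalize |
filter | phase | enrich`) and as plain library calls; see the module
docstrings and `docs/methods.md`.

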