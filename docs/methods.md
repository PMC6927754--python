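# Methods

## Read counting

Reads are assigned by exact substring search: every window of the read (at
each spacer length present in the library) is looked up in a hash map of
spacers. With a no-mismatch requirement this is equivalent to exact
alignment for any read that fully covers the spacer, and it needs no
knowledge of where the spacer sits inside the amplicon. Only the forward
orientation is searched by default — amplicon sequencing fixes the vector
orientation — with an opt-in reverse-complement scan. A read matching
spacers of two distinct guides, or a spacer shared by two guides, is
"ambiguous" and assigned to none; assigned + ambiguous + unassigned always
equals the number of reads. No trimming, quality filtering or fuzzy
matching is performed.

## Normalization and per-guide scores

Size factors use the median-of-ratios estimator: with counts c_ij for
guide i in sample j, and the per-guide geometric mean g_i across samples
computed over the guides detected (count > 0) in every sample,
sf_j = median_i (c_ij / g_i). Factors are reported as computed, without
rescaling to unit product. A consequence worth stating precisely: scaling
one of m samples by a constant c multiplies that sample's factor by
c^((m−1)/m) and every other factor by c^(−1/m). The factor *ratios*
therefore absorb exactly the depth change, and the normalized matrix is
reproduced up to a global factor c^(1/m), which cancels out of any
between-sample comparison. Only the full negative-binomial machinery of
differential-abundance tools is deliberately omitted: the downstream
statistic consumes nothing but a per-guide fold change, so dispersion
estimation and shrinkage would add parameters without changing the
hit-calling logic (a design choice, recorded here).

The per-guide statistic is lfc_i = log2((c_iT/sf_T + p)/(c_iC/sf_C + p))
with pseudocount p = 1 on normalized counts (config-exposed), then

    z_i = (lfc_i − median(lfc)) / s

across the entire library. The default scale is s = 1.4826 × MAD (median
absolute deviation), the conventional robust z; because "mean absolute
deviation" is also a defensible reading of that phrase in screen-analysis
write-ups, `mad_mode="mean_abs_dev"` switches to the literal unscaled mean
absolute deviation. A zero-spread fold-change distribution is an error at
the estimator level; the pipeline catches the one legitimate case
(a contrast of a sample against itself) and scores it as all-zero z.
A pre-treatment baseline sample is read and QC'd but does not enter the
contrast, which is treatment vs vehicle.

## RSA gene statistic

Guides are ranked by z twice — ascending for the depletion ("down")
direction, descending for enrichment ("up") — with ties broken by
guide_id for reproducibility. For a gene with n guides at ranks
r_1 < … < r_n among N, the score is

    RSA = log10 min_{i=1..n} P(X ≥ i),  X ~ Hypergeometric(N, n, r_i),

the smallest upper-tail probability over the prefixes of the gene's rank
list: "at least i of the gene's n guides in the top r_i". The min is the
canonical construction and is not corrected for the n cutoffs tried, so
the score is anti-conservative as a per-gene P value (the permutation
null utility quantifies this; at default thresholds a 2000-gene null
screen yields ~1.5 stringent calls). Hit calling uses the fixed gates
rather than corrected P values, mirroring standard screen practice;
Benjamini–Hochberg FDR columns are emitted for reference but never gate
calls.

Tails are computed in log space from gammaln with at most n summed terms
per cutoff, vectorized across the whole library; correctness is pinned by
two independent routes in the tests (exact rational enumeration of all
C(N, n) placements for every N ≤ 12, n ≤ 4, and scipy's hypergeometric
survival function at random larger sizes). `permutation_null_hits`
re-uses a precomputed cutoff × rank tail table so thousands of
guide-to-gene label permutations run in seconds at genome scale.

Gene quartiles Q1/Q3 use linear interpolation between order statistics
(quantile q at position 1 + (m−1)q); with 5 guides Q1 is therefore the
second-lowest z. One convention had to be fixed for reproducibility; this
is numpy's default and the most common one.

Hit gates (all inclusive, config-overridable): sensitizer stringent
RSA-down ≤ −4 and Q1 z ≤ −1; lenient RSA-down ≤ −3 with the same z gate;
resistance mirrors with RSA-up and Q3 z ≥ +1. The stringent set is a
subset of the lenient set by construction. A gene passing both directions
(possible only with pathological z patterns) is flagged and assigned the
direction with the smaller log10 P. Single-guide genes are scored but
flagged `low_confidence`.

## Synthetic screens

The generator reproduces the count-level structure of a genome-scale
modifier screen; defaults are the screen's design conditions where those
are known, and field-typical values elsewhere:

| parameter | default | meaning |
|---|---|---|
| n_genes × guides_per_gene | 2000 × 5 (18,360 at genome scale) | library layout |
| reads_per_guide | 1000 | sequencing depth target per arm |
| baseline_sigma | 0.5 | lognormal spread of plasmid pool, log2 units |
| bottleneck_cells_per_guide | 1000 | multinomial cell-sampling depth |
| nb_dispersion α | 0.05 | var = μ + αμ², 0 degrades to Poisson |
| n_sensitizers / n_resistance | 40 / 40 | planted modifier genes |
| effect_mu_sens / effect_mu_res | −3 / +3 | mean per-guide log2FC shift |
| effect_sigma | 0.5 | between-guide effect spread |
| p_active_guide | 0.8 | probability a guide is effective |
| neutral_sigma | 0.15 | residual log2FC noise, log2 units |

Depth, library layout and cell coverage follow the reference screen
design this package targets; the noise and effect-size parameters are not
estimates of any particular dataset — screens of this kind rarely report
quantitative noise parameters — but are chosen to be realistic for the
assay class and are config-exposed. Infection at low MOI is abstracted into a single
multinomial bottleneck over cells, because the analysis consumes counts
and the bottleneck captures the representation-noise consequence of
finite coverage; there are no clonal dynamics, no time-resolved growth
(effects are expressed directly as log2FC shifts, not fitness rates), no
persister-state kinetics and no sequencing-error simulation. Passing
recovery tests on these simulations therefore demonstrates that the
statistics behave correctly under the assumed noise model — not that any
particular biological dataset would yield the same precision/recall.

Guide inactivity (p_active) is the feature that makes the simulator a
meaningful testbed for RSA: with only ~80% of guides active, a gene's z
vector routinely contains neutral entries, which defeats mean-based
aggregation but not the rank-prefix minimum.

Determinism: all draws derive from `SeedSequence([seed, stream])` so a
configuration is bit-reproducible across runs and platforms;
`simulate_library` and `simulate_screen` use separate streams, keeping
the library identical whether or not counts are generated.

## Numerical and degenerate-input choices

- Hypergeometric tails: log-space gammaln sums (exact to ~1e-15 relative),
  clipped at log 1 = 0; no underflow down to P ≈ 1e-300.
- `robust_z` raises on zero spread; `size_factors` raises when no guide is
  detected in all samples (advising pseudocount normalization) and with
  fewer than two samples.
- Missing guides in a counts file become explicit zeros (a dropout screen
  must distinguish absence from zero); unknown guides are dropped; both
  are logged with counts.
- Representation band is the closed multiplicative interval
  [median/k, k·median]; zero-count guides fall outside it whenever the
  median is positive, and an all-zero sample yields an explicit
  undefined flag rather than a number.
- QC is advisory: no guide is ever filtered from the analysis on count
  grounds.

## Benchmarks computed by the tests and acceptance script

At the design conditions (20 seeds), stringent calling recovers planted
sensitizer and resistance genes with mean recall ≈ 0.94 and precision
≈ 0.99; the null configuration produces stringent calls at a rate
statistically indistinguishable from the guide-permutation null (exact
binomial test); and the genome-scale configuration (91,800 guides) runs
end to end through the file interfaces in seconds. Test-suite problem
sizes (2000-gene screens, 200-seed null sweeps) were chosen so the entire
suite completes in well under a minute of compute while keeping
Monte-Carlo error on the reported averages below a percentage point.

## Known limitations

- One contrast, one sample per arm: no replicate-aware variance modeling,
  no Wald/likelihood-ratio tests, no batch correction.
- RSA P values are scores, not calibrated per-gene P values (see above);
  comparisons across libraries of very different size should use the
  permutation null.
- Exact-match counting discards reads with any sequencing error in the
  spacer (~depth loss, not bias, at typical error rates) and reads that
  do not fully cover the spacer.
- Copy-number or essentiality confounders of dropout signals are not
  modeled or corrected.
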