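# Methods

This note documents the models and procedures `replicore` implements, the
parameters that matter, the numerical choices, what the synthetic data
generator does and does not emulate, and known limitations.

## The replication signal and the tent model

Bidirectional replication from a single origin means a replicating cell
holds, on average, more copies of origin-proximal than terminus-proximal
loci; in a metagenome this appears as a coverage gradient along the
chromosome of each abundant clade. `replicore` works at the granularity of
single-copy core genes (SCCGs): per gene, coverage is summed read length
divided by gene length, and each gene is placed at its midpoint
`floor((start+end)/2)` on the circular reference genome (coordinates are
0-based half-open internally; GFF3 is converted at the boundary).

With the terminus fixed at position `t`, the expected coverage of gene `g`
is modeled as linear in the circular distance
`d_g = min(|m_g − t|, L − |m_g − t|) ∈ [0, L/2]`:

    cov_g = c + b · d_g

Fitting forward and reverse arms simultaneously under an equal-slope
constraint is, with `t` fixed, exactly ordinary least squares of `cov_g`
on `d_g` (identical normal equations), so plain OLS is used; genes are
equally weighted regardless of length. The slope is standardized as
`R = b · L / 2` — the fitted coverage excess at the origin relative to the
terminus, a dimensionless quantity comparable across samples *at a common
sequencing depth*.

The linear (tent) form is a first-order description; the copy-number
profile of a population with age-distributed replication forks is
exponential. The generator offers `coverage_shape="exponential"`
(`c · 2^(R·2d/L)`) to probe how the linear fit degrades under that
mismatch.

## Rarefaction

Coverage slope in absolute units scales with library depth, so unequal
depths masquerade as unequal replication. All samples of an ecotype are
therefore subsampled to one shared depth

    depth = ceil(target_coverage × Σ gene lengths / read_length)

with `target_coverage = 5.0` by default — the floor below which the slope
is not reliably recoverable — and `read_length = 150` bp (an assumed,
configurable value; using one value rather than per-sample empirical means
keeps the depth genuinely shared). Subsampling is uniform **without
replacement**, `n_replicates = 30` independent replicates per sample;
samples with fewer reads than the depth are excluded with a QC flag
(`below_min_coverage`), never upsampled. The replicate stream for
`(seed, sample, r)` is spawned from a stable blake2b hash of the sample id,
so adding or reordering samples never perturbs another sample's draws.

The final estimate `R_obs` is the mean standardized slope over replicates;
its standard error is the replicate standard deviation over √n. A negative
mean is flagged (`negative_slope_removed`) and written as missing — the
tent model has no interpretation for an inverted profile — but the row is
retained so downstream consumers decide.

Note that rarefying to depth `D` rescales the whole profile: the slope
recoverable at that depth is the generating slope times
(depth coverage / model mean coverage). Validation therefore compares
fitted values against `expected_r_at_depth`, not against the shape
parameter directly.

## Terminus identification

One terminus is fixed per ecotype: per sample, a candidate minimum is
found on the mean coverage profile over replicates; the batch terminus is
the **circular median** of the per-sample minima (the observed position
minimizing the summed circular distance to all of them, ties to the
smallest coordinate).

Two per-sample locators are provided:

- `best_fit_terminus` (default): scans every gene midpoint as a candidate
  terminus and keeps the one whose tent fit has the lowest residual sum of
  squares, penalizing negative-slope fits so a flat profile does not lock
  onto an inverted tent. This matched-filter reading uses all genes.
- `circular_minimum_position`: the midpoint of the gene minimizing a
  circular moving median (default window 21 genes, odd, wrapping).

The smoothed argmin is kept because it is the historically standard
reading, but it is not the default: the tent is *shallowest* exactly at
its minimum, so a locator that only looks at the few genes near the dip
has an intrinsically large error (at 5–10× coverage, median localization
error ≈ 7% of the circumference, versus ≈ 1% for the RSS scan). Both
break ties toward the smallest coordinate and warn on flat profiles.

## The hierarchical diel model

For taxa whose DNA replication is synchronized to the light-dark cycle,
observations are pooled per noon-to-noon day bin (an observation at time
`t` on day `D` joins bin `D` if `t ≥ 12:00`, else bin `D−1`; the boundary
is inclusive-left). The model is

    R_obs_i ~ Normal(μ(t_i, d_i), σ_obs)
    μ(t, d) = c0 + (R24_d − c0) · exp(−Δ(t, t1)² / (2 tw²))
    R24_d   ~ Normal(μ_R, τ)

with `Δ(t, t1) = min(|t − t1|, 24 − |t − t1|)` the wrapped hour difference
(no artifacts at midnight). Parameters: `t1` peak time (h), `tw` width of
the replication period (h), `c0` background slope, `R24_d` the daily
maximum for bin `d`, and a population level `(μ_R, τ)` that shrinks poorly
sampled days toward the ecotype mean. A tent-shaped mean
(`max(0, 1 − Δ/tw)` weight) is available via `mean_shape="tent"`; the
Gaussian bump is the default because it is the form the estimator's
forward model states.

Default weakly informative priors: `t1 ~ Normal(20, 3)` h (evening
S-phase peak, broad), `tw ~ HalfNormal(3)`, `c0 ~ Normal(0, 1)`,
`μ_R ~ Normal(0.5, 1)`, `τ ~ HalfNormal(0.5)`,
`σ_obs ~ HalfNormal(0.5)`. All overridable.

Sampling uses an affine-invariant ensemble (emcee) with
differential-evolution moves (80% DE, 20% DE-snooker) — the stretch move
mixes poorly on the correlated `(t1, tw, R24)` posterior — at 40 walkers ×
4000 steps, the first half discarded as warm-up. Walkers are treated as
chains for arviz's split R-hat; the fit is flagged non-converged (with a
warning, not an exception) if any R-hat exceeds 1.05. `t1` is summarized
circularly (circular mean; quantiles of deviations wrapped to ±12 h).

Identifiability caveat: with ~2 observations per day falling inside the
bump, each `R24_d` posterior has sd ≈ 0.04–0.05 at σ_obs = 0.05, so
individual posterior means can sit 10–15% from truth in any one
realization even when the sampler is perfect; the population mean `μ_R`
and the peak time `t1` are much better determined. The model-free
cross-check `interpolated_daily_max` (max of the piecewise-linear
interpolant through a bin's points, i.e. the bin's largest observation)
tracks the posterior maxima closely on recovery simulations.

`detect_diel_rhythm` is a permutation test: statistic = range of 2-h
hour-of-day bin means; null = R_obs values permuted over observation
times; `p = (1 + #{null ≥ obs}) / (1 + n_permutations)`.

## Reference-genome selection

Candidates are scored by (1) mean DCJ distance to the other genomes of the
ecotype — computed on the intersection of gene sets (removed genes are
reported), duplicates rejected — via the adjacency-graph formula
`d = N − (C + I/2)` with `C` cycles and `I` odd paths (for two single
circular chromosomes, `d = N − C`); linear chromosomes are supported
through telomeres, and odd paths are identified as components with an odd
number of extremities. (2) The number of large gaps in pooled SCCG
coverage: maximal circular runs of ≥ `min_run` genes (default 10) at
coverage ≤ 0, a wrap-around run counted once. (3) Percent read
recruitment. The shortlist is the `top_k = 6` lowest mean-DCJ candidates;
within it the ranking is lexicographic (gaps ascending, recruitment
descending, mean DCJ ascending, then genome id) — an explicit,
reproducible stand-in for what is otherwise expert judgment; all three
columns are reported so a user can override.

## Ω nutrient-stress indices

Per stress gene: coverage normalized to the sample's summed SCCG coverage
(samples with zero SCCG coverage are excluded with a warning), Z-scored
across the full sample set (sample sd, ddof 1), summed per category.
Genes whose normalized coverage has spread at or below float-rounding
level (sd ≤ 1e−12 of the column maximum) contribute 0 rather than
amplifying representation noise. By construction each category's Ω sums
to 0 across samples; Ω is invariant to rescaling any one sample's
coverages and its SCCG total together. Gene-to-category curation is user
input, not hard-coded. Whether Z-scores should be scoped per transect or
pooled is a judgment call; the implementation pools by default and leaves
grouping to the caller.

## The synthetic generator

`simulate_read_table` draws per-gene read counts around
`λ_g · gene_length / read_length`, scaled to a total read budget
(`total_reads=None` takes the budget the coverage model itself implies),
with Poisson or negative-binomial noise and a fixed read length (150 bp).
The depth-dependent origin bias multiplies `λ_g` by
`1 + s · log10(total_reads/1e5) · (1 − 2 d_g/L)`, truncated at 0. This
knob emulates a *mapping/extraction-depth* artifact: its strength is a
property of the depth at which reads were extracted, which is why
`remap_at_depth` (re-extraction with the bias re-evaluated at the new
depth) — and not a plain subsample, which preserves read composition — is
the correct emulation of re-processing a sample at a reduced depth. It
exists to verify that depth equalization removes the depth–slope
correlation, not to model library chemistry.

Not emulated: sequencing error, quality scores, read-length variation,
within-gene read positions, GC bias, multi-ecotype mixtures, and
multi-fork (exponential) copy-number profiles except as the optional shape
switch. Passing tests therefore demonstrate correctness of the estimators
under the stated sampling models, not robustness to every artifact of real
libraries.

## Validation problem sizes

The validation experiments (`replicore.validation`, shared by the test
suite and `scripts/acceptance.py`) use: 700 genes of 800 bp on a 1.6 Mbp
genome; slope recovery on 10 batches × 10 samples with parent libraries at
500× rarefied to a common 10× depth (parents deep enough that replicate
subsampling, not parent shot noise, dominates the error budget); depth-bias
on 50 samples spanning 10⁵–10⁷ reads re-extracted at 1.25× the common 5×
depth; DCJ against a breadth-first-search oracle on ≤ 5-gene circular
genomes; the standard diel scenario (5 days × 8 samples/day, t1 = 20:00,
tw = 2 h, σ_obs = 0.05) for recovery and a scaled-down scenario
(3 days × 6 samples/day, 24 walkers × 1200 steps) for 50-replication
interval calibration; 200 + 200 simulations at 199 permutations for the
rhythmicity error rates.

## Known limitations

- R_obs is an index of replication at a standardized depth, not a growth
  rate; calibrating it to doublings per day is out of scope.
- A single fixed terminus per ecotype assumes the reference genome's
  structure represents in situ populations; strong rearrangements between
  reference and population produce gap-rich, attenuated profiles (which
  the reference-selection module is designed to catch).
- The Pearson correlation used in the depth-bias check has null sd
  ≈ 1/√(n−1) ≈ 0.14 at n = 50, so its post-rarefaction value fluctuates at
  that scale even when no real correlation remains.
- Per-day `R24_d` point estimates are noisy at realistic per-day sampling
  (see the identifiability caveat above); inferences should lean on `μ_R`,
  `t1`, and interval summaries rather than single-day point values.
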