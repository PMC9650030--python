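# Methods

This note records the models behind each stage, the defaults and why
they were chosen, what the synthetic data does and does not emulate,
and the numerical decisions a maintainer would want to know about.

## Coverage-correlation damage detection

**Model.** A transcript's per-base read-depth profile has a shape set
by positional biases that are stable across samples; endonucleolytic
cleavage removes or depletes coverage on one side of the break and so
changes the shape. For gene *g* with count vectors *x*, *y* (one per
sample, window-1 counts), the statistic is the Pearson correlation of
*x* and *y*. Intact genes score near 1; cleaved genes drop. The
statistic is computed on raw counts: it is invariant to multiplying
either vector by a positive constant, so sequencing-depth differences
cannot move it.

**Undefined values.** A constant vector has zero variance and no
defined correlation; such genes (typically all-zero, or below the
coverage floor) are excluded from the ranking and reported separately
rather than being assigned a pseudo-value.

**Defaults.** `min_mean_cov = 10` (below ~10× mean coverage the
correlation is dominated by sampling noise); `pcc_threshold = 0.5` for
the binary damage call. Both are exposed because no principled
universal cutoff exists. The *ranking* is the robust readout: on
planted full-truncation damage with noise-free counts, every damaged
gene scores strictly below every intact gene (intact pairs are
identical vectors, PCC = 1). The binary threshold is a convenience: a
fully truncated transcript typically scores ≈ 0.2–0.4, but when the
intact profile's structure happens to align with the cleavage point the
damaged PCC can exceed any fixed threshold (values up to ≈ 0.66
observed across 20 planted transcripts), so threshold calls should be
read together with the ranking.

**Enrichment.** Class over-representation among damaged genes is the
hypergeometric upper tail P(X ≥ k) with population = universe size,
successes = class size, draws = number selected; BH adjustment across
the six RNA classes, with raw p also reported. The overlap test for two
gene sets uses the same tail with draws = |B|. Both are exact
(scipy.stats), verified in the tests against direct enumeration on
populations ≤ 12 at 1e-12.

## Ligation-junction mapping

**Adapter search** is leftmost-occurrence Hamming matching of the 21-nt
core (substitutions only, no indels; default 0 mismatches). A core
truncated by the read end is accepted when ≥ `min_core_prefix = 12`
bases remain: 12 is short enough to rescue most truncated-adapter reads
and long enough that a chance suffix match in adapter-free sequence
(4^-12 ≈ 6e-8 per position) is negligible at desk scale. The four
bases 5′ of the core belong to the adapter oligo and are never counted
as target.

**Placement** replaces a general-purpose aligner with an exhaustive
scan over the transcript set — exact matching via substring search on a
concatenated text, mismatched matching via a vectorised sliding-window
Hamming comparison, both strands. Only a *unique best* placement is
accepted; ties are discarded as ambiguous (a multi-mapping fragment
carries no usable junction). Reverse-strand placements are rejected as
antisense: the ligation chemistry fixes the read in the sense
orientation of the target. A SAM reader (`events_from_sam`) accepts
placements from an external aligner instead.

**Junction** = placement start + clipped length − 1, 1-based: the last
target base before the adapter, i.e. the RNA 3′ terminus the ligase
acted on. Targets shorter than `min_target_len = 15` nt are discarded
(reason-coded) as too short to place uniquely.

**Aggregation.** Per-gene distinct-target and event counts; per-domain
counts with inclusive bounds, an event inside two overlapping domains
counting once in each (domains on the tmRNA genuinely overlap).
Optional deduplication collapses events identical in (transcript,
junction, random-base string) — the NNNN bases act as a UMI; off by
default since library-level duplication behaviour is unknown.

**Domain enrichment** is the binomial upper tail with success
probability L_domain/L_transcript and n = events on the transcript,
BH-adjusted within each transcript — the natural length-weighted null
of junctions falling uniformly along the molecule. **Junction
composition** reports column-stochastic base frequencies for the target
3′ flank and the adapter random bases plus per-column information
content 2 − H (bits); flat columns (≈ 0 bits) mean no sequence
preference.

## Translation kinetics

**Model.** After induction, ribosomes initiate continuously; no
full-length reporter exists until the first ribosome finishes at
*T* = L/v (L = 774 aa, v = elongation speed), after which the
completion flux ramps and accumulated product grows ∝ (t − T)². Hence
√signal is linear in t with X-intercept *T* (Schleif plot), and
v = L/T. The induction delay is absorbed into the intercept; only a
single translation time is reported.

**Point selection.** Background is subtracted and the signal floored at
0 before the square root. With an explicit `noise_floor`, points with
√signal strictly above it enter one OLS fit. The default is adaptive:
an initial fit over points above 2× the pre-onset baseline scatter
(samples below 5% of the maximum) is refined by keeping points whose
*fitted* √signal exceeds 3× the residual scatter, then refitting (≤ 5
iterations, usually 1–2). This targets the region where the plot is
linear above the noise, which is what one fits by eye on a real Schleif
plot. A simple fixed floor at 2× the baseline scatter is not robust:
√ of noise-dominated points is biased and drags the X-intercept, giving
15–60% median speed error at additive noise of 5% of the final signal,
versus 2–4% (durations 300–900 s, 200 replicates) for the adaptive
rule. On noise-free data every positive sample is used and the fit is
exact to float precision. The X-intercept comes from the OLS
coefficients (−b/m), not interpolation, and is scale-free.

Degenerate inputs raise: all-zero signal and non-positive slope are "no
productive synthesis"; fewer than 2 usable points, or a non-positive
X-intercept (series starting mid-accumulation), are errors rather than
estimates.

**Fidelity** is mu_reporter/mu_wt from Miller-unit tables; replicate
tables are averaged with the standard deviation of per-replicate ratios
reported.

## Synthetic data

The generators produce exactly the structure the estimators assume,
plus truth tables sufficient to score recovery; all are byte-reproducible
given a seed (per-transcript streams are keyed by CRC32 of the id, so
outputs do not depend on iteration order).

* **Transcriptomes**: uniform-random sequences per RNA class
  (tRNA/rRNA/ncRNA/tmRNA/CDS/pseudogene), lengths uniform in a range;
  the first tmRNA carries the eight-domain annotation (TLD, MLD, H2,
  H5, PK1–PK4) as fractional intervals of its length, two of which
  overlap as on the real molecule.
* **Coverage**: a per-transcript positive rate profile — smoothed white
  noise in log-rate, correlation length ≈ 10 nt, sd ≈ 0.25 log-units —
  shared between samples, so intact genes correlate perfectly before
  noise. A low-frequency random walk was rejected: its drift lets an
  intact declining profile mimic its own truncation and destroys
  damaged/intact separability. Damage multiplies the expected rate by
  1 − f + f·retain_5p upstream of the cleavage site and
  1 − f + f·retain_3p downstream. Noise is Poisson or none (expected
  values rounded to keep counts integral).
* **Reads**: exactly round(frac·n) adapter-bearing reads,
  `target[(j−k+1)..j] + NNNN + core` truncated to the read length, with
  fragment lengths uniform in 20–50 nt; background reads are genuine
  sense-strand transcript fragments screened to contain no detectable
  adapter, so false events are absent by construction.
* **Kinetics**: 0 before T, amplitude·(t − T)² after, sampled on a
  fixed grid from t = 0; Gaussian noise floored at 0. **Fidelity**:
  mean-preserving lognormal multiplicative noise at a stated CV.

What the generators do *not* emulate — and what passing tests therefore
do not establish about real libraries: sequencing errors and quality
variation, PCR duplicates, fragment-length and positional-bias
distributions beyond the smooth rate model, antisense transcription,
and genome-scale mapping ambiguity. Defaults used throughout the tests
and examples (depth 100×, 200-gene universes, 10,000-read libraries,
20-s sampling over 10 min) are desk-scale stand-ins for the real
experiments, chosen so every check runs in seconds while keeping each
statistic in its well-powered regime.

## Known limitations

* The damage threshold call is heuristic (see above); the ranking and
  the class-enrichment test are the defensible outputs.
* The exhaustive mapper is quadratic in (reads × reference) for
  mismatched placement and is intended for transcript sets of hundreds
  of sequences, not genomes; use the SAM entry point beyond that.
* Domain enrichment conditions on the total events per transcript and
  assumes independent junctions; clustered fragmentation would inflate
  significance.
* The Schleif estimator assumes the quadratic-onset accumulation model;
  saturation late in a long time course would bias the fitted slope and
  is not modelled.
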