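# rtcseq

Computational companions to the bacterial **Rtc RNA-repair system**
(RtcB RNA ligase / RtcA cyclase, controlled by the σ54-dependent
activator RtcR). Oxidative stress and ribotoxins break RNA, leaving
3′-phosphate or 2′,3′-cyclic-phosphate ends; RtcB re-ligates them. This
package implements, at desk scale, the three analyses used to
characterise that system from sequencing and reporter data, each paired
with a seeded synthetic-data generator so the whole pipeline can be
exercised and scored against ground truth without any external download.

It is written for microbial RNA-biology groups who have per-base
coverage tracks, adapter-capture sequencing reads, or β-galactosidase
induction time courses and want the corresponding statistics as tested,
scriptable building blocks.

## What it computes

**1. Damaged-transcript detection** (`rtcseq.integrity`). For each gene
with per-base coverage vectors *x*, *y* in two samples, the statistic is
the Pearson correlation

&nbsp;&nbsp;&nbsp;&nbsp;PCC = cov(*x*, *y*) / (σ_x σ_y),

computed on raw window-1 counts (PCC is invariant to library-size
scaling). Cleavage changes the *shape* of coverage, so damaged genes
fall in a descending-PCC ranking; genes below a threshold are called
damaged and the damaged set is tested for RNA-class over-representation
with a one-sided hypergeometric test (Benjamini–Hochberg across
classes). A hypergeometric overlap test for two gene sets is included.

**2. Ligation-junction mapping** (`rtcseq.ligation`). RtcB ligates the
adapter 5′-NNNNTGGAATTGTCGGGTGCCAAGG-3′ onto 3′-P/2′,3′-cyclic-P RNA
ends. Reads therefore look like `target-3′-fragment + NNNN + core`.
The caller finds the leftmost core occurrence (Hamming matching,
substitutions only), clips core and random bases, places the remaining
target on the transcript set by exhaustive scan (exact or ≤ *k*
mismatches, both strands), and calls the junction as the 1-based
coordinate of the last target base — the ligated 3′ terminus. Events
are aggregated per gene and per structural domain (e.g. the tmRNA
pseudoknots PK1–PK4); domain enrichment is a length-weighted binomial
upper tail, P(X ≥ obs) with X ~ Bin(n_events, L_domain/L_transcript).
Junction flanks are summarised as base-frequency matrices with
per-column information content.

**3. Translation kinetics** (`rtcseq.kinetics`). In an induction time
course of the 774-aa FusA-LacZα reporter, √signal is linear in time
(a Schleif plot) and its X-intercept is the time *T* to translate the
reporter once; elongation speed is *v* = 774/*T* aa/s. Fidelity is
normalized miscoding: Miller units of a frameshift or premature-stop
reporter over the wild-type reporter.

## Worked example

```python
from rtcseq import synth
from rtcseq.kinetics import SchleifModel, percent_speed_reduction

wt = SchleifModel.from_series(synth.gen_schleif(9.9, noise_sd=0)).fit()
mut = SchleifModel.from_series(synth.gen_schleif(4.7, noise_sd=0)).fit()
print(wt.summary())
print(f"speed reduction: {percent_speed_reduction(wt.speed, mut.speed):.1f}%")
```

prints

```
Schleif-plot elongation-speed estimate
======================================
reporter length:     774 aa
points fitted:       27
slope:               1 sqrt(AU)/s
X-intercept:         78.18 s (translation time)
elongation speed:    9.9 aa/s
R^2:                 1.000000
speed reduction: 52.5%
```

i.e. a noise-free time course generated at 9.9 aa/s has its quadratic
onset at 774/9.9 ≈ 78.2 s, the estimator recovers exactly that
X-intercept, and the wild-type-vs-mutant comparison shows a ~52%
elongation-speed reduction.

The same pattern drives the other stages, e.g.:

```python
from rtcseq import IntegrityModel, LigationModel
res = IntegrityModel.from_bedgraphs("A.bedgraph", "B.bedgraph", transcripts).fit()
print(res.summary())          # ranked PCC table, damage calls, class enrichment
lig = LigationModel(reads, transcripts, domains).fit()
print(lig.summary())          # events, targets, per-domain binomial enrichment
```

Everything is also available from the shell via the `rtcseq` console
script (`rtcseq synth …`, `rtcseq integrity score …`,
`rtcseq ligmap call …`, `rtcseq kinetics speed …`).

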