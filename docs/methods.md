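# Methods

## Data model

All coordinates are 0-based half-open (BED-native) throughout; 1-based site
labels appear only in rendered output. A per-read call carries the natural-log
likelihood ratio (LLR) of methylated over unmethylated at one motif group;
grouped CpG calls (nanopolish-style `num_motifs > 1`) are split into
single-site records before any summarization, each site inheriting the group
LLR — the convention used by the standard frequency calculators. The
mitochondrial genome is treated as circular everywhere: read coverage,
context trimers, smoothing windows and read spans all wrap.

The molecule strand is the biological object of interest: mtDNA's heavy (H)
and light (L) strands are transcribed and replicated differently and are
summarized separately at every stage. The mapping from the reference strand
symbol is a configuration (`plus_is`, default `'+' → L`), not an assumption.

## Read-level calling

A call is methylated iff LLR ≥ t, unmethylated iff LLR ≤ −t, and ambiguous
in between, with t = 2.0 by default — the threshold widely used for
nanopore CpG callers; it is exposed everywhere as `threshold`/
`--llr-threshold`. Boundaries are inclusive. Ambiguous calls are counted
and reported but excluded from every beta denominator, matching the
"called sites" convention; sites with zero called reads are omitted rather
than emitted with NaN.

## Background calibration

The fully-unmethylated control (whole-genome-amplified DNA) defines the
technical false-positive rate per strand as methylated calls over called
calls, pooled at the read-call level rather than over distinct sites:
call-level pooling is the natural reading of the defining ratio and gives
the calibration maximal precision. A Wilson 95% interval accompanies the
point estimate. Heavy and light strands always get separate models.

Detection above background is an exact one-sided binomial tail
P(X ≥ n_meth | n = called coverage, p = FPR) with Benjamini–Hochberg
correction per strand, plus the requirement β > FPR (a site cannot be
"detected" below the noise floor however large its coverage). The exact
tail with BH is the simplest calibrated test against a known per-call error
rate; on FU-mode simulations tested against their own model the detected
fraction stays below the nominal 5%.

## Filters

- **Read length.** Every read whose aligned span is below 8798 bp — the
  length of the longest known NUMT — is removed; a span of exactly 8798 bp
  survives ("below" is strict). The span of a circular molecule is the
  shortest arc containing all of the read's calls (genome length minus the
  largest inter-call gap), so full-length reads that wrap past the origin
  are not penalized.
- **Coverage.** A site is kept only if its called coverage is ≥ 10× in
  *every* sample ("less than 10×" is strict; 10 survives). Sites absent
  from a sample count as zero coverage there.
- **NUMT regions.** The NUMT-only parallel analysis takes the calls or
  sites whose position lies inside any region (half-open containment of the
  single-base position); regions are merged before the scan.

## Differential methylation

The per-site test is a beta-binomial regression Wald test with an arcsine
link, reimplemented in closed form rather than wrapped, so every numerical
choice is explicit:

1. Continuity-corrected proportion p̂ = (X + 0.5)/(N + 1), link
   Y = arcsin(2p̂ − 1).
2. Replicate variance on the Y scale v = (1 + (N − 1)φ)/N. This is the
   delta-method variance for this link: (dY/dp)² = 1/(p(1−p)) exactly
   cancels the mean factor of the beta-binomial variance of p̂, which is
   the point of the transform. (The 1/(4N) form sometimes quoted belongs to
   the arcsin√p half-angle variant; using it here would double every Wald
   statistic, and measured null type-I error confirms ~0.33 instead of the
   nominal 0.05.)
3. Dispersion φ per site by method of moments from replicate scatter within
   each group (weighted by degrees of freedom), clipped to [0, 0.99] and
   shrunk toward the cross-site median: φ* = λ·median + (1 − λ)·φ̂ with
   λ = 0.5 by default. Sites without replicate variance take the median;
   with no replicates anywhere φ = 0 with a warning.
4. Group means are inverse-variance weighted means of Y;
   Wald = (m₁ − m₂)/√(1/ΣW₁ + 1/ΣW₂); two-sided normal p; BH across tested
   sites. Effects map back through μ = (sin m + 1)/2, so the proportion-scale
   `diff` and the Y-scale `diff_y` always share a sign.

The paired (multifactor) design regresses Y on
[intercept, patient indicators, tumor/normal] by weighted least squares with
the same weights, testing the group coefficient; coefficient covariance is
model-based (inverse of the weighted normal matrix) since the weights are
known variances. Dispersion for the paired design comes from the variance of
within-pair Y differences, in which patient baselines cancel — estimating it
from raw group scatter would fold between-patient variability into φ and
erase the benefit of pairing. One pair degenerates to [intercept, group]
(still full rank) with φ = 0 and a warning; rank-deficient sites are skipped
and logged.

Significance gating is deliberately two-threshold: |Δβ| ≥ δ with δ = 0.05
by default (0.10 available as a stricter preset for negative-control
comparisons) *and* p (or FDR, selectable) < 0.05. Smoothing
(coverage-weighted mean of β over ± window/2, circular) is off by default:
the mitochondrial genome is short and deeply covered; a 500 bp window is the
default when it is enabled for nuclear runs.

Global distribution comparisons use Mann–Whitney U (unpaired) or Wilcoxon
signed-rank (paired), exact for ≤ 25 (informative) observations and
normal-approximated with continuity correction above; identical paired
vectors return p = 1 by convention, and fewer than 3 informative
observations is an error rather than a meaningless p-value.

## Region aggregation

Region sets of heterogeneous widths are overlaid by rescaling each region —
expanded by a flank defaulting to one region width — to the relative axis
[−1, 1] around its center. Site betas inside are assigned to `n_bins` bins
(odd, default 21, so a center bin exists); bin means are coverage-weighted
across regions, and the total bin observation count equals the number of
(site, region) overlaps. Platform agreement is Pearson correlation over
bins populated in both profiles, or over position-matched single sites.

## qMSP

β = 1/(1 + 2^(Ct_m − Ct_u)), algebraically equal to M/(M + U) with
M = 2^(−Ct_m), U = 2^(−Ct_u) but immune to underflow at large cycle
numbers. The complement identity β(a, b) + β(b, a) = 1 holds to machine
precision and is property-tested.

## Synthetic data generator

The generator reproduces the statistical structure the analysis relies on,
not the physics of the sequencer. A read is a whole molecule linearized at a
configurable cut site (mimicking enzymatic linearization before sequencing),
assigned H or L strand by a Bernoulli draw (`strand_h_fraction`, default
0.5 — strand imbalance is exercised in tests but not assumed), with length
either full (the default) or Gaussian-truncated, wrapping the 16,569 bp
circular reference (rCRS length; the sequence itself is random at 44% GC).
Every cytosine of the molecule's strand that the read covers receives a
true state ~ Bernoulli(p_site) and an LLR ~ N(+μ, σ) if methylated,
N(−μ, σ) otherwise (defaults μ = 4, σ = 2.5). The two-Gaussian emitter is
the simplest model with a closed-form per-call error rate,

    FPR(t) = Φ(−(t+μ)/σ) / [Φ(−(t+μ)/σ) + Φ((μ−t)/σ)] ≈ 0.0103 at defaults,

which makes the background-calibration stage testable against an analytic
oracle. Modes: FU forces p_site = ε (default 0); FM sets CpG sites to
`fm_level` (default 1) with a fraction `fm_failure_fraction` (default 0.05)
of reads entirely unmethylated, modeling incomplete methyltransferase
treatment, while CpH stays at ε; tissue mode takes arbitrary per-site,
per-strand probabilities. NUMT decoys are linear reads of at most 8798 bp
with their own (nuclear-level, default 0.8) methylation probability, so the
read-length filter separates them from full-length molecules exactly.
Heteroplasmy-like mixtures are modeled per read (mixture of molecule
classes), matching single-molecule readout.

The cohort generator produces paired tumor/normal count tables directly:
per pair and site, a baseline drawn from a Beta distribution around
`base_meth` (default 0.3) with between-subject dispersion `phi_between`
(default 0.05); the tumor member shifted by `delta_true` at effect sites
(clipped to [0, 1] with a warning); member-level proportions add
replicate-level beta-binomial dispersion `phi_within` (default 0.02); counts
are binomial at the configured coverage.

What the generator does *not* emulate — sequence-dependent error (e.g. G
homopolymers), basecaller-specific LLR distributions, indels, mapping
ambiguity, real NUMT sequence homology — bounds what green tests show:
they demonstrate that the statistical machinery is correct under its stated
model, not that a particular instrument meets these error rates.

## Problem sizes and determinism

The statistical acceptance checks run at deliberately moderate scale —
~2×10⁵ calls × 10 seeds for background calibration, 50 small FU runs for
detection, 20 × 1000 sites for the null type-I error, 50 paired cohorts of
30 sites for recovery — sizes at which the binomial/simulation tolerances
(3 SEs, the [0.03, 0.07] type-I band, ±0.03 effect recovery) are already
tight. All simulations are reproducible from a single integer seed; the
acceptance script derives independent child streams per analysis from its
`--seed`.

## Known limitations

- The background model assumes a homogeneous per-call FPR per strand; no
  per-site error heterogeneity.
- The dispersion estimator is method-of-moments with fixed-λ shrinkage, not
  an empirical-Bayes fit; with very few replicates the Wald test leans on
  the shrinkage target.
- The paired design supports patient pairing only; no further covariates.
- Region-level DMR merging, 5hmC/6mA contexts and per-read haplotype
  phasing are out of scope.
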