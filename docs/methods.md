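# Methods

This note documents the statistical model behind the package, the defaults
and why they hold, the synthetic-data generators and what they do and do not
emulate, and the numerically delicate choices.

## Agreement model (deductive task)

One coding pass assigns each (participant segment, code) cell a boolean; the
study-shaped instance is 124 segments × 10 codes = 1240 cells. A coder is
compared against the adjudicated reference standard through the 2×2 table
(tp, fp, fn, tn), with the reference as the truth axis. Two aggregations are
exposed, because "overall agreement" is ambiguous in this design:

* **pooled** — all segment×code cells concatenated into one binary vector
  (the default for summary rows and the non-inferiority effect);
* **per code** — each code's column scored separately (used for the per-code
  κ table, where degenerate codes are flagged undefined rather than dropped
  silently).

Cohen's κ corrects observed agreement by the marginal-product chance term
p_e; Gwet's AC1 corrects by γ_e = 2π̂(1−π̂) with π̂ the mean positive
propensity. At the study's mean prevalence (~7.8%) a coder with sensitivity
0.30 and specificity 0.98 has population pooled values p_o ≈ 0.927,
AC1 ≈ 0.918, κ ≈ 0.356: identical data, radically different chance
corrections. Reporting both is the point, not a redundancy.

Undefined metrics are two different situations and are handled differently:
an empty table (n = 0) violates a precondition and raises; degenerate
marginals (e.g. both raters constant and equal, p_e = 1) are *expected* in
resampled low-prevalence data and return NaN, so bootstrap replicates can
drop and count them. A bootstrap run aborts only when more than half of its
replicates are undefined.

## Bootstrap

Confidence intervals are percentile bootstrap with **segment-level
resampling**: a replicate draws whole segments with replacement and every
code label of a drawn segment moves together, preserving within-segment
dependence across codes. Defaults: B = 1000 replicates, 95% intervals, one
`numpy` Generator per run seeded by a single integer, replicates consuming
draws in a fixed order — identical seeds give identical intervals. The
percentile (not BCa) flavor is used as the minimal-assumption default.
Group summary rows ("human mean", "model mean") are the arithmetic mean of
per-coder point estimates, with CIs from bootstrapping the mean over
resamples shared by all group members.

Measured behaviour (recomputed by the test suite and acceptance script): the
95% percentile CI for pooled κ at the study's design covers the true
population value in ≈93–96% of 500 simulations.

## Non-inferiority and superiority testing

**Deductive.** Effect for model m: Δ = AC1(m) − mean over humans of AC1(h),
all vs. the reference. Each bootstrap replicate applies ONE shared segment
resample to the model and every human and recomputes Δ, so the difference is
paired. The one-sided p-value for H0: Δ ≤ −δ (δ = 0.03 AC1 units, reflecting
inter-human variation in pilot coding) uses the add-one rule

    p = (1 + #{Δ* ≤ −δ}) / (B + 1),

so a reported p is never exactly zero at finite B; with B = 1000 the
smallest reportable p is ≈ 0.001. Superiority reuses the same machinery with
margin 0. Measured type-I error at the margin boundary (a model whose
population AC1 sits exactly 0.03 below the human value, constructed by
inverting AC1 in the specificity argument) is ≈ 0.05 at α = 0.05.

**Inductive.** Likert scores 1–5 are treated as approximately interval data.
For model m, d_i = score(m, code i) − mean over humans of score(h, code i);
H0: mean(d) ≤ −δ (δ = 0.5 points) is tested by a one-sample one-sided t-test,
t = (d̄ + δ)/(s_d/√n), df = n − 1. Zero-spread differences are degenerate:
p is declared 0 when d̄ > −δ and 1 otherwise, and flagged. Shift
equivariance holds exactly: adding δ to every difference turns the
non-inferiority test into the superiority test.

**Multiplicity.** Holm step-down adjustment is applied across the models
compared within one task; the non-inferiority and superiority families are
adjusted separately, and verdicts are read from adjusted p-values only.

## Quote audit

The four-class taxonomy (exact / partial / no_match / researcher_segment) is
made computable by a reproducible default matcher: text is normalized
(case-fold, whitespace collapse, typographic-to-ASCII punctuation, terminal
punctuation stripped) and similarity is the longest common substring divided
by the shorter string's length. Exact requires the normalized quote to be a
substring of the claimed segment (or of some segment when none is claimed);
partial requires similarity ≥ 0.5; the researcher-segment class takes
precedence over text matching because coding facilitator speech is a rule
violation regardless of verbatimness — this also keeps the four classes
disjoint so counts sum to totals. The original audit this framework models
was human judgement, including whether a quote semantically supports its
code; that judgement is not computable here and is carried by a
`manual_override` field that always wins, letting audited datasets be
replayed exactly. An unknown claimed segment id is logged and classed
no_match rather than raised, since it is itself an error mode of the coder
under audit.

Rates per model, as percentages of quotes emitted: strict = no_match/total;
expanded = (no_match + researcher_segment)/total; comprehensive = (no_match +
researcher_segment + partial)/total. Across models, unweighted means and
sample SDs (n−1) are taken over the per-model percentages (and over raw
counts for the count block).

## Synthetic-data generators

* **Reference standard**: per-code prevalences drawn once from
  N(0.078, 0.032²) clipped to (0.005, 0.5) and frozen into the spec object;
  cells are independent Bernoulli draws. Independence across codes is a
  deliberate simplification — real codes co-occur — so simulated CIs may be
  slightly narrower than real ones; no dependence structure is imposed
  because none is identified.
* **Coders**: a (sensitivity, specificity) operating point applied
  independently per cell. Defaults (0.34, 0.97) for humans and (0.30, 0.98)
  for models are the group operating points of the deductive comparison.
  The generating point is recoverable within ±0.03 over 200 replicates, and
  large simulations (50,000 segments) match the closed-form population
  metrics within ±0.01.
* **Likert tables**: score = round-and-clamp(base + shift + normal noise).
  Default base means are uniform in [3.0, 4.7] (the upper-middle range of
  observed human scores) with noise SD 0.8, chosen so adjacent-integer
  disagreement between analysts is common, as in the observed table.
* **Transcripts + quotes**: pseudo-word segments (no natural language, by
  design — the audit operates on substring structure, not semantics) with a
  facilitator fraction of 0.2, and quote records realizing a prescribed
  class mixture. Partial records keep ~70% of the quote verbatim and append
  tokens from a disjoint character alphabet, placing similarity well inside
  (0.5, 1); fabricated records use only that alphabet, landing far below
  0.5. Because corruption is constructed away from the threshold, the
  audit's class equals the generating class essentially always (measured
  100% at 500 records), which is what makes the closed loop a test of the
  classifier rather than of the threshold.

What passing these simulations does **not** show: performance on real
transcripts with semantic paraphrase (the matcher is lexical), correlated
codes, or analyst drift over a session. The bundled study tables cover the
real-data path for the inductive and audit stages; the deductive stage's
study matrices are not published in-text, which is why its validation is
property-based.

## Numerical and design choices

* Sub-seeds for multi-run experiments are derived arithmetically from one
  master seed; every generator is a fresh `default_rng`.
* Machine-readable outputs round floats to 6 decimals at serialization so
  re-runs are byte-identical; report tables round to printed precision
  (percentages 1 dp, coefficients 2 dp, Likert means 3 dp) only at render
  time.
* The reported problem sizes for the simulation studies — 200 seeds for
  operating-point consistency, 500 simulations × B = 1000 for CI coverage,
  500 replicates × B = 200 for boundary type-I error — were chosen to put
  Monte-Carlo error comfortably inside the assertion bands (binomial SE
  ≈ 0.01 at 500 draws) while keeping each study in seconds.
* Likert inputs are validated to integers 1–5 at the container boundary;
  the t-machinery itself accepts real-valued differences.

## Known limitations

* κ/AC1 are implemented for two raters and binary labels only (the design
  compares each coder against one reference); no Fleiss/multi-rater forms.
* The quote matcher has no semantic model: a fluent paraphrase of real
  evidence is classed no_match, which overstates strict hallucination
  relative to a human audit; the override field exists for exactly that gap.
* The deductive bootstrap p has resolution 1/(B+1); claims like p < 0.0001
  require B ≥ 10⁴, not the default 1000.
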