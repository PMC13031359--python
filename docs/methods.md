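# Methods

This note documents the models implemented in `fretsort`, the defaults of the
synthetic-data generators, the numerical choices, and the limits of what
passing tests demonstrate.

## Sensitized-emission FRET from three-channel cytometry

Per sample, the package works on per-channel **medians** of the event table
(the mean is available but never the default; medians are robust to the
heavy right tail of expression distributions). Background medians from an
empty-vector sample are subtracted channel-wise; a non-positive corrected
median raises an error, because the biosensor signal is expected to dominate
autofluorescence by about two orders of magnitude. Samples that legitimately
lack one channel (donor-only, acceptor-only controls) restrict the
positivity check to the channels they use.

The corrected efficiency is

E = (m₂ − S₂ m₃ − S₁ m₁) / (m₂ − S₂ m₃ + (α − S₁) m₁) × 100 %,

which is exactly scale-invariant in the channel medians. Negative sensitized
emission is reported, not clamped, and flagged `negative_E`: negative
controls scatter around zero and the sign is informative.

**α calibration.** For one-to-one donor:acceptor samples define
R₁ = (m₂ − S₂ m₃ − S₁ m₁)/m₁ and R_F = (m₂ − S₁ m₁)/(S₂ m₃). Under 1:1
stoichiometry y = 1/(R_F − 1) is linear in x = 1/R₁ with slope/intercept = α.
The fit is unweighted ordinary least squares over all provided points
(replicates pooled, not averaged). Samples with R₁ ≤ 0 or R_F ≤ 1 carry no
usable sensitized emission and are excluded with a warning. Degenerate
conditions raise: fewer than two usable points, all abscissae identical, or
|intercept| below 10⁻¹² of the leading term. When no calibration set exists,
the constant α = 0.739 for the mTurquoise2–mNeonGreen pair is available as a
documented fallback.

**Acceptor photobleaching.** Both the pre- and post-bleach donor time series
are fit by straight lines against time and both lines are extrapolated to
the single bleach instant; this corrects for donor photobleaching during
acquisition. E = (F_AB − F_BB)/F_AB × 100 %. A post-bleach level at or below
the pre-bleach level yields E ≤ 0 with the `negative_E` flag.

## Binding models

**Dose response.** E(c) = E₀ + (E∞ − E₀)·cʰ/(K_Dʰ + cʰ), fit by bounded
least squares with K_D parameterized on the log scale. The Hill coefficient
is restricted to [0.3, 4]: the sensors are single-site binders, so extreme
apparent cooperativity signals a degenerate fit rather than biology.
Multi-start initialization (the dose nearest the half response plus the
geometric dose quartiles) guards against sigmoid local minima; the
half-saturation constant is reported directly as K_D. Fits require ≥ 5
distinct concentrations; a flat response raises an unidentifiability error.
Standard errors are asymptotic (Jacobian-based, delta method for K_D).

**Occupancy.** (E_sample − E_apo)/(E_sat − E_apo), references labelled by
ligand state so the formula serves both FRET signs. Linear interpolation
between reference strains is an assumption of this package, not a derived
result; values outside [0, 1] are returned unclamped with a flag, and a
dynamic range below 1 percentage point (configurable) is rejected.

**Dissociation kinetics.** Single-exponential relaxation
R(t) = R∞ + (R₀ − R∞)e^(−k_off·(t−t₀)) on the segment between a removal
event and the next event, requiring ≥ 6 points. R₀ is a free parameter
rather than being pinned to the pre-removal plateau, because sub-saturating
additions may not have fully equilibrated before washout. A constant segment
returns k_off = 0 with a `constant_trace` flag. Single-exponential decay is
the implemented default; multi-exponential kinetics are out of scope.

## Sort-seq analysis

**Barcode extraction** follows linked-adapter semantics: 3′ quality trimming
at Q20 (BWA-style partial-sum rule, as implemented by common read trimmers),
then U1 and U2 located in order, each tolerating ⌊0.1·length⌋ substitutions
and no indels; the insert is reverse-complemented and counted when ≥ 20 bp.
Every read lands in exactly one tally (counted / quality / no-adapter /
short), and the accounting identity is asserted. Barcode-to-map matching is
exact-only — no 1-mismatch rescue — per common barcoded-transposon practice.

**Enrichment.** e_g = (c_g,s/T_s)/(c_g,u/T_u): depth normalization first,
then division by the matched unsorted reference, cancelling
library-composition differences between biosensor transformations. No
pseudocounts anywhere: zero unsorted reads make the enrichment undefined and
the gene is excluded from fold changes. The read filter excludes a gene only
when its raw count is below threshold (default 200) in **every** sample; the
stricter any-sample reading is a config switch. Each sorting cycle is
analyzed independently against the same unsorted reference.

**Cyber-T.** Per group, the per-gene sample variance is shrunk toward a
background estimated from genes of similar abundance: genes are ranked by
mean value, the standard deviations of the w nearest genes (window w = 101,
full window shifted at the edges, shrunk with a warning when w exceeds the
gene count) are averaged and squared, and the regularized variance is
(ν₀σ₀² + (n−1)s²)/(ν₀ + n − 2) with prior ν₀ = 6 pseudo-observations.
The t statistic uses the regularized variances and n₁ + n₂ − 2 + 2ν₀
degrees of freedom. Averaging standard deviations (not variances) in the
window follows the published tool; Monte Carlo confirms it calibrates the
two-replicate null to an empirical type-I rate of ≈ 0.056 at p < 0.05.
At ν₀ = 0 the variance divisor (n − 2) keeps a (n−1)/(n−2) factor relative
to the classical pooled estimate, so the reduction to Student's t is
asymptotic in the replicate number; the test suite checks this convergence.
Inputs are log₂ enrichments per replicate; the reported log₂FC is the mean
over replicates of log₂(e_high) − log₂(e_low).

## Synthetic-data generators

**Cytometry.** Events follow I₁ = N·k_D1·(1−E), I₂ = N·(k_D2(1−E) + k_A2 +
E·k_sen), I₃ = N·k_A3, each channel multiplied by Gaussian noise (CV 5 %)
and offset by Gaussian autofluorescence background. The implied corrections
are exact by construction: S₁ = k_D2/k_D1 = 0.55, S₂ = k_A2/k_A3 = 0.30,
α = k_sen/k_D1 = 0.739 — so noise-free samples invert the estimator
identically and every recovery test has an analytic oracle. This is a
deliberate trade: spectral detail, photobleaching during acquisition and
instrument compensation are not modelled. Expression N is lognormal with
median 5,000 a.u. and log-SD 0.4 (a realistically broad population);
background means (30, 25, 40 a.u.) stay below 2 % of signal. Default 30,000
events per sample. Because all three channels share the per-cell factor N,
channel-median errors are strongly correlated and mostly cancel in the
efficiency — which is why the median pipeline recovers E to well within one
percentage point at this depth.

**Screen.** Each gene's mutant multiplies a baseline c-di-GMP level (median
100 nM, per-cell lognormal spread log-SD 0.35) by its effect; occupancy
follows the Hill curve of a mid-affinity sensor (K_D 100 nM, h 1, E₀ 18 %,
E∞ 38 % — placed near the baseline so both directions of effect are
resolvable); the cell's FRET ratio follows the photophysical model. Sorting
is modelled on the **ratio**, not the efficiency, as on a real sorter. The
log ratio of each mutant is a Gaussian mixture (Gauss–Hermite quadrature
over ligand noise; measurement term √2·CV); the population gate threshold at
the configured tail fraction (default 1.5 %, within the 1–2 % practice) is
found by root finding and pool composition is updated by each mutant's
collection probability — fully probabilistic, no discretization, so
selection monotonicity in the effect size holds exactly. The collection
probability blends the gate probability with a 2 % gate-independent
carryover (`sort_impurity`, i.e. 98 % sort purity, a typical instrument
figure); without it a perfect gate would drive strong-effect mutants to
exactly zero reads in the opposite tail, which the no-pseudocount analysis
would then discard. Additive background is neglected in the sorted ratio
(it is < 2 % of signal). Growth between cycles is not modelled; a per-gene
fitness hook exists but defaults to neutral. Reads are drawn multinomially
per pool (default 10⁶ per pool — desk scale; the study sequenced ~8×10⁶
reads per sample over a much larger library) and written as gzip FASTQ reads
pad + U1 + revcomp(barcode) + U2 + pad at uniform Q40. Defaults: 2,000
genes × 3 barcodes, 20 causal genes with 4–16× effects (half up, half
down), two biological replicates with independent lognormal barcode
abundances (log-SD 0.5), one sorting cycle sequenced (at this read depth a
second cycle pushes opposite-tail counts of strong hits toward single
reads; multi-cycle simulation and ×2/×3 analysis remain available).

What passing recovery tests show — and do not show: they validate the
estimators against data whose generative structure matches the estimators'
assumptions (exact 1:1 stoichiometry, single-site binding,
single-exponential kinetics, substitution-free reads). They do not test
robustness to spectral cross-talk beyond the S₁/S₂/α model, aggregation,
growth-coupled selection, PCR jackpotting, or sequencing error.

## Interfaces and numerical constants

Event input is CSV (`event,I1,I2,I3`); FCS container parsing is not included
— export to CSV upstream. Zero-denominator and zero-intercept guards use a
relative tolerance of 10⁻¹² of the leading term. All stochastic generators
take explicit seeds and are deterministic given them (byte-identical FASTQ
included). The test suite and the acceptance script run on a single CPU in
a few minutes; problem sizes (30,000 events, 2,000 genes, 10⁶ reads/pool)
are the package's documented study conditions.
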