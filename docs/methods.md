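# Methods

`grainqtl` implements the statistical genetics of a grain-shape QTL study
in a biparental recombinant inbred line (RIL) population: trait geometry,
simulation, trial ANOVA, linkage-map construction and inclusive composite
interval mapping (ICIM). This note records the models, the defaults and
the design choices that were genuinely open.

## Grain-shape geometry

A grain's 2-D outline is modelled as an ellipse with full major-axis
length GL (grain length, mm) and full minor-axis length GW (grain width,
mm). The seven characters and their exact relations:

| character | definition | relation |
|---|---|---|
| GL, GW | axis lengths, mm | GL ≥ GW > 0 |
| LW | length-to-width ratio | GL/GW |
| GA | area, mm² | π·GL·GW/4 |
| GD | equal-area circle diameter, mm | √(GL·GW) = √(4·GA/π) |
| GR | roundness | GW/GL = 4·GA/(π·GL²) = 1/LW |
| GC | circumference, mm | π[1.5(a+b) − √(ab)], a = GL/2, b = GW/2 |

**Axis convention.** GL and GW are *full* axis lengths. Published
accounts of this trait system sometimes print GA = π·GL·GW and the GC
approximation with full axes; those forms are dimensionally inconsistent
with GD = √(GL·GW) and GR = GW/GL. Only the semi-axis forms above make
all identities (LW·GR = 1, GD² = GL·GW, GD = √(4GA/π), GW ≤ GD ≤ GL)
simultaneously exact, so that convention is adopted throughout.

**Circumference accuracy.** GC uses a closed-form perimeter
approximation, exact for circles. Against the elliptic-integral
perimeter its relative error grows with aspect ratio: ~0.0003% at
LW = 1.2, 0.045% at LW = 1.9, 0.06% at LW = 2, 0.32% at LW = 3, 0.71% at
LW = 4. It is therefore accurate to 0.05% only for LW ≲ 1.9; for
slender *indica*-type grains the approximation is a few tenths of a
percent optimistic. The exact formula (not an alternative
approximation) is what this trait system defines, so the package keeps
it and documents the error curve; the test suite pins the curve against
a quadrature oracle.

`validate_trait_table` checks measured tables against the identities at
a default relative tolerance of 1e-6 (measured traits are stored
rounded).

## Synthetic RIL studies

The generator exists so every downstream stage is testable without
deposited data. It emulates the statistical structure of a
215-line × 143-marker, 12-chromosome rice RIL trial grown in 4
environments with 2 replications.

**Meiosis and descent.** Lines descend by single seed descent from an F1
of two fully homozygous parents. Crossovers are a Poisson process on the
Morgan scale (Haldane, no interference): adjacent loci d cM apart
recombine with r = (1 − e^(−2d/100))/2. Default 11 selfing generations
(F12); residual heterozygous calls — expected fraction 2^(−11) ≈ 0.05% —
are recorded as *missing* because every downstream statistic treats the
population as two homozygous classes. Marker allele frequencies have
expectation 0.5; `distort_segregation` resamples chosen markers to a
target frequency to emulate segregation distortion.

**Default map.** 12 chromosomes, 143 markers (15, 14, 14, 12, 12, 12,
11, 12, 10, 9, 11, 11 per chromosome), evenly spaced at ≈11.25 cM,
total 1474.3 cM.

**Phenotypes.** For each directly simulated trait,
y_ijk = μ + R_k/j + Σ_q a_q·x_iq + E_j + GE_ij + ε_ijk with x = +1 for
the B-parent allele, E_j fixed environment shifts, R ~ N(0, σ²_rep) per
(environment, replication), GE ~ N(0, σ²_GE) per line × environment and
ε ~ N(0, σ²_ε) per plot. QTL are simulated as extra loci through the
same meioses, so marker–QTL linkage is genuine. Setting all variances to
zero makes the model exact (used by degenerate-case tests).

**Default trait models.** GL (mean 5.8 mm): one major QTL a = +0.43 on
chromosome 3 at 112 cM plus four minors (+0.18, +0.17, +0.16, +0.15) and
a 12-locus polygenic background (|a| = 0.065, alternating sign, one
locus per chromosome). The background lifts the genotypic variance to
≈0.35 mm², the magnitude of a high-heritability grain-length trial, and
puts the major-QTL PVE at ≈50% (0.43² / ≈0.36). GW (mean 2.8 mm): major
a = −0.12 on chromosome 5 at 15 cM (PVE ≈ 30%), three minors, 10
background loci (σ²_G ≈ 0.045 mm²). Environment, G×E, block and residual
variances (GL: 0.0139/0.002/0.0111; GW: 0.0021/0.0005/0.0026) are small
relative to σ²_G, giving plot-level heritabilities near 0.9. The other
five characters are derived per observation from (GL, GW) through the
ellipse model, which reproduces the strong pleiotropy and the
LW–GR ≈ −1 correlation such trials show.

**What the generator does not emulate:** genotyping error, field spatial
trends, selection during SSD, crossover interference, non-elliptical
grain outlines, and cross-over G×E (favorable alleles never switch).
Passing tests therefore demonstrate correctness of the estimators under
this generative model, not robustness to those artefacts.

## ANOVA, variance components, heritability

Balanced complete data only (the generator produces balanced trials;
unbalanced input is a hard error with a per-cell report — no silent
imputation). Sums of squares come from marginal means of the balanced
layout, so the decomposition is exact; F-tests use the residual mean
square as denominator for every source, consistent with the component
estimator below.

Components are method-of-moments:
σ²_G = (MS_G − MS_ε)/(e·r), σ²_GE = (MS_GE − MS_ε)/r, σ²_ε = MS_ε.
Note the genotype numerator contrasts against the *pooled error*, not
MS_GE; this matches the arithmetic used in the grain-trial literature
this package follows and slightly inflates σ²_G by σ²_GE/e when G×E is
present. The textbook expected-mean-squares ladder is available via
`ems="standard"`. Negative estimates are flagged, never truncated —
truncation would silently move heritabilities.

Broad-sense heritability excludes the environment main effect:
H²_plot = σ²_G/(σ²_G + σ²_GE + σ²_ε) and
H²_mean = σ²_G/(σ²_G + σ²_GE/e + σ²_ε/(e·r)); H²_mean ≥ H²_plot whenever
e·r > 1 and components are non-negative. Applying these formulas to
reference components of the motivating trial reproduces its plot-level
heritabilities to ~4 decimals; its *mean-level* values are slightly
higher than the formula yields from the same components (≈0.994 vs
≈0.986 for grain length), an inconsistency in the source numbers that
this package does not attempt to match.

## Linkage maps

Observed recombinant fraction R̂ between two markers = discordant /
informative lines (pairs under 30 informative lines, and all pairs of a
monomorphic marker, are unknown). For selfed RILs R = 2r/(1+2r), so the
per-meiosis fraction is recovered as r = R/(2(1−R)), clamped to
[0, 0.5] with a flag. Distances default to Haldane
(d = −50·ln(1−2r)) because the simulator has no interference, making
round-trip tests close exactly in expectation; Kosambi
(d = 25·ln((1+2r)/(1−2r))) is available by flag.

Grouping uses anchor assignments when given (the intended workflow —
physical marker positions anchor chromosomes); without anchors,
single-linkage joining at R < 0.35. Ordering minimizes SARF (sum of
adjacent recombination fractions): nearest-neighbor tours from every
start, best kept, improved by 2-opt segment reversals to a local
optimum, then a rippling pass — a window of 8 markers slides one
position at a time and every window permutation (8! = 40 320, evaluated
vectorized) is scored by whole-order SARF. Ties break lexicographically
by marker id and orders are reported up to reversal (first marker id ≤
last). On ≤8-marker groups the combination attains the exhaustive
optimum in testing; window size is configurable for speed.

The interval summary reports means both per interval and per marker
(some summaries in the field divide total length by marker count rather
than interval count); adjacent R > 0.5 caps the interval at 50 cM with a
counter.

## ICIM

Scanning is per trait × environment on line means over replications.

1. **Cofactors:** stepwise regression on all markers encoded A → +1,
   B → −1, missing → 0 (the 1:1 expectation mean). Forward inclusion at
   p_entry = 0.001, backward elimination at p_removal = 0.002 (defaults
   from common ICIM practice), partial p-values from F tests on residual
   sums of squares; ties break to the leftmost map position, and a
   collinear duplicate can never co-enter (its residualized column
   vanishes). A perfect fit forces p → 0.
2. **Adjustment:** at each scanned interval, Δy subtracts every selected
   cofactor's contribution *except the two flanking markers*.
3. **Mixture scan:** grid at 1 cM (configurable). Per-line class priors
   P(QQ), P(qq) condition on the flanking calls through a two-state
   Markov chain on RIL-scale fractions (the no-double-crossover
   normalization); a missing flank conditions on the other alone, two
   missing flanks give (0.5, 0.5). The two-component common-variance
   normal mixture is fitted by EM, initialized from probability-weighted
   class means, converged at relative log-likelihood change < 1e-8 or
   200 iterations, vectorized across all grid positions.
   LOD = log10(L1/L0) against a single-normal null, clamped at 0 (EM is
   a local optimizer). Additive effect a = (μ_B − μ_A)/2, so a > 0 means
   the B-parent allele increases the trait; PVE% = 100·a²/s²_y with s²_y
   the variance of the unadjusted line means (±1 coding makes a² the
   locus's additive variance). The PVE closed form is a documented
   package choice — mapping software keeps its internal formula private,
   and exact numeric agreement with any particular implementation is not
   claimed.
4. **Threshold:** permute line labels, re-run the *full* scan including
   cofactor reselection (a conservative, literal permutation of the
   whole procedure; a fast mode scanning without cofactors is available
   and labelled approximate), take the empirical (1−α) quantile of
   genome-wide maxima; maxima can be pooled across traits before the
   quantile. Default n_perm = 1000 per trait, α = 0.05.
5. **Calling:** the declaration unit is the marker interval. An interval
   hosts a QTL if any environment has a supra-threshold *local* LOD
   maximum inside it (plateaus count once, at their first grid point;
   chromosome ends count when above the inner neighbor). Two merges
   keep one locus from being reported twice: consecutive local maxima
   separated by a LOD dip of less than 1 (a common EM artifact when a
   peak straddles a marker, where class priors degenerate exactly at
   the marker) collapse to the higher peak, and significant intervals
   sharing a flanking marker form one region, reported at the interval
   holding the best peak. The record carries every environment's own
   within-region peak — position, LOD, PVE, additive effect — with a
   per-environment significance flag, sub-threshold environments
   included. Names are
   q<trait><chromosome>, with -1/-2… ordinal suffixes by position when
   a chromosome hosts several QTL for the trait. Records across traits
   sharing an identical flanking-marker pair consolidate into one
   cluster row listing, per environment, the QTL significant there.

## Problem sizes in the validation suite

The statistical acceptance checks run at the scale the estimators are
meant for where that is affordable, and at reduced scale where the full
design would be disproportionate: QTL parameter recovery uses 100
replicates of the full 215 × 143 × 4-environment study with one
permutation threshold (200 permutations) shared across replicates, since
the detection statistics (major-QTL LOD ≈ 25–35 against a threshold
≈ 3) are insensitive to threshold noise; type-I-error calibration uses
200 replicates of a 100-line, 30-marker, 3-chromosome genome with a
100-permutation threshold recomputed inside every replicate, because the
rejection *rate* is exactly the quantity that does depend on the
per-replicate threshold; marker-order recovery uses 100 replicates of a
15-marker chromosome at n = 215. `scripts/acceptance.py` re-measures the
same quantities at moderately reduced replicate counts and records the
problem size next to every number it reports.

## Known limitations

* Single-trait, single-environment additive scans only: no joint
  multi-environment model, no epistasis (2-D) scan, no dominance (RILs
  are homozygous).
* The ANOVA requires balanced data by design.
* Map distances are two-point; no multipoint maximum-likelihood
  re-estimation.
* The three-locus RIL process is not exactly Markov; flanking-marker
  conditioning uses the standard Markov approximation (the forward
  simulation shows class-probability errors below 0.02 for 10 cM
  intervals).
* GC inherits the perimeter-approximation bias described above.
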