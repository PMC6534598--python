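# Methods

## Genetic model

The *Tcb1* locus is modeled as a single Mendelian locus with four haplotypes
distinguished by two boolean flags (male-functional, female-functional) and
one quantitative attribute, the silk expression level of the female barrier
gene relative to a reference gene. Expression is attached to alleles, not
plants, so epigenetically silenced lineages and *mop1* revertants are
representable as expression changes on an intact allele.

**Gametes.** Two-locus gamete frequencies between *Tcb1* and the linked
endosperm marker *su1* follow the standard recombination-fraction
parameterization: parental classes at (1−r)/2 each, recombinant classes at
r/2. The default r = 0.06 treats the ~6 cM map distance as a recombination
fraction; at this distance the difference between map distance and fraction
is below half a percent and far below the sampling noise of any ear. The
kernel-color locus *r1* sits on another chromosome and assorts
independently, implemented by splitting each chromosome-4 gamete class
evenly across the parent's *r1* alleles.

**Acceptance rule.** A silk is barrier-active iff some allele is
female-functional with expression ≥ threshold (default 0.5 on the
relative-to-reference scale, i.e. half the full-strength level used as the
unit). An active silk accepts a grain with probability 1 if any haplotype in
the grain is male-functional — the OR rule, matching the dominance of the
male function observed with heterodiploid pollen — and otherwise with
probability `leak`, the residual siring rate of incompatible pollen
(default 0.03, inside the observed 0–7% band; configurable per female).
Ovules are never selected: the barrier acts on pollen tubes in the silk,
before fertilization. Transmission of the chromosome-4 duplication in
heterodiploid carriers is a configuration parameter (default 0.5); no
measured value exists.

**Screen expectation.** In an open-pollinated block of repulsion
heterozygotes (*Tcb1-s Su1 / tcb1 su1*), a barrier ear accepts only the
*Tcb1-s* pollen class, of which fraction r carries *su1*; with ovules
unselected (*su1* ovule probability 1/2) the sugary-kernel fraction is r/2
exactly. A barrier-less ear accepts the whole cloud (*su1* probability 1/2),
giving 1/4 for every r. These are closed forms, independent of population
size.

## Simulators

Kernel sires are independent multinomial draws over (donor, gamete) classes
with weight = mixing weight × acceptance bias × acceptance probability.
There is no silk-position or pollen-depletion effect, and no spatial model
of kernel sectors on an ear — nothing constrains them. The acceptance bias
(default 60% *tcb1* : 40% *Tcb1-s* on a neutral ear for an equal mix) is a
single per-kernel siring weight per haplotype class; whether it reflects
viability, germination, or tube growth is not distinguishable at the kernel
level and is not modeled further. Bias and barrier act multiplicatively:
bias captures competition among accepted grains, the barrier captures
rejection.

The screen simulator (defaults: 6000 plants, 300 kernels/ear, r = 0.06,
leak = 0 — the 3% expectation assumes complete rejection) draws each ear's
sugary count from the accepted-pollen distribution and emits the hidden
barrier status for scoring. The reversion simulator gives each female a
reversion Bernoulli draw (default probability 0.18, the middle of the
observed ~14–22% band, over the historical 36 females); reverted females
move from the silenced base expression (0.05) to a reverted level (0.6)
above the threshold and mount a partial barrier whose leak is drawn
uniformly from (0, 0.15) — a monotone step mapping from expression to
barrier, since only a correlation and a threshold are established, not a
functional form. Non-reverted females behave as *tcb1*.

All simulators consume a mandatory integer seed through
`numpy.random.default_rng`; fixed seeds give byte-identical outputs.

## Scoring statistics

The two-tailed exact test on a 2×2 kernel table uses the conventional
Fisher rule — sum all tables with the observed margins whose point
hypergeometric probability does not exceed the observed table's —
delegated to `scipy.stats.fisher_exact` and verified exhaustively against
an integer-arithmetic enumeration oracle for every table with N ≤ 30 in the
test suite. Tier thresholds are exactly p < 10⁻⁴ (strong) and
10⁻⁴ ≤ p < 10⁻² (partial), and count only when the *tcb1*-sired fraction is
lower on the test ear; the same significance in the opposite direction is
classified `none`.

Barrier strength is the odds ratio of compatible:incompatible kernels
between test and control ears. Zero cells get an additive 0.5
(Haldane–Anscombe) correction applied to all four cells, only when a zero
occurs. The statistic is transposition-symmetric (BS(test,control) =
1/BS(control,test)) and scale-invariant in expectation.

Screen outliers are flagged by a one-sided exact binomial tail
P(X ≥ observed) under the r/2 null with Bonferroni correction over ears —
strict family-wise control chosen because a screen of ~6000 ears is
examined once; the historical screen used visual inspection. No
overdispersion/GLM modeling of ear-to-ear heterogeneity is attempted.

## qPCR

Amplification efficiency is assumed exactly 2 (no standard curve is
modeled). Technical replicates are averaged within biological replicate
first; the per-biological-replicate ΔCt yields a relative expression, and
mean and SEM (ddof = 1) are taken over biological replicates. The
alternative — ΔCt of means — differs only in noise weighting; the
technical-first order was chosen because technical replicates share a cDNA
prep and their average is the natural per-sample estimate. Undetermined Cts
are missing data, not ceiling values. The expression–barrier association is
a Spearman rank correlation (no functional form is assumed), with a report
of whether below-threshold lines show barrier strength ≈ 1.

## Divergence dating

Mismatches are counted over pre-aligned sequences, case-insensitively,
excluding any column with a gap or non-ACGT symbol in either sequence
(ambiguity codes are excluded rather than partially matched). Dating uses
the strict clock T = d/(2µ) with µ = 3.3×10⁻⁸ substitutions/site/year by
default, a rate consistent with the maize literature; at d ≈ 0.0116 a
Jukes–Cantor multiple-hit correction would shift T by <1%, so none is
applied. No alignment or Bayesian phylogenetics is included.

## Synthetic data

Each fixture generator derives its pseudo-random stream from
(seed, design-code), so adding a design never perturbs existing fixtures.
Generated Ct values are baseline − log₂(expression) + N(0, σ) per technical
replicate, so at σ = 0 the pipeline recovers planted folds exactly.
Sequence pairs plant exactly the requested number of substitutions.
Fixtures emulate the *designs* of the historical experiments — kernel
counts, replicate structure, sequence geometry — under the model above;
they do not emulate ear-to-ear biological heterogeneity, position effects,
amplification-efficiency drift, or alignment error, so passing recovery
tests demonstrates correctness of the estimators under the stated model,
not robustness to those real-data features.

## Problem sizes

Closed forms are exact and instant. Simulation-based checks use 10⁴–10⁵
kernels (binomial standard errors of 0.3–0.5 percentage points, small
against the 3-vs-25% and 40-vs-60% contrasts of interest) and a few hundred
to two thousand ears for screen and reversion studies — sizes at which all
stochastic checks resolve their targets at 3 standard errors.

## Known limitations

- The leak is a single per-female constant; real ears show a 0–7% range
  whose sources (silk age, environment) are unmodeled.
- The expression→barrier mapping is a step function; nothing between "no
  barrier" and the partial-leak band is represented.
- The acceptance bias is constant across ears and mixes.
- `exact_test_2x2` requires counts; percentage data must be converted to
  counts by the caller.
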