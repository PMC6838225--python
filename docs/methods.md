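# Methods

This note documents the models implemented in `clockcomp`, the default
parameter values and why they were chosen, the numerical conventions, and
what the synthetic-data generator does and does not emulate.

## Chi-square periodogram and chronotyping

For a candidate period *P* (hours) the constant-condition recording is
folded into *K* = ⌊duration/*P*⌋ complete cycles of *B* = round(*P*/Δ)
phase bins (Δ the recording bin width).  The statistic is

    Q_P = N · Σ_h n_h (M_h − M̄)² / Σ_i (x_i − M̄)²

with *M*<sub>h</sub> the phase-bin means, *n*<sub>h</sub> the number of
points in phase bin *h*, *M̄* the grand mean and *N* the number of points
used.  When every phase bin holds exactly *K* points this equals the
classical folded-matrix form N·K·Σ(M_h − M̄)²/Σ(x_i − M̄)².  The
implementation assigns each bin midpoint to a phase bin by its time
modulo *P*, which reduces exactly to the K×B matrix folding whenever *P*
is a whole number of bins and lets the scan use a period grid finer than
the bin width.  Under a
flat null Q_P ~ χ² with *B* − 1 degrees of freedom; a fly is rhythmic
when Q_P at the spectrum peak exceeds the per-period 95% quantile
(p ≤ 0.05), the peak being the grid point maximising Q_P minus its
threshold.

Conventions:

* **Grid** 14–35 h in 0.1-h steps (covers all genotype periods with wide
  margins).  No multiple-testing correction across grid points, mirroring
  common periodogram practice.  Consequence, documented and tested: on a
  *flat* Poisson series the 211-point scan crosses the per-period 5% line
  roughly half the time, so an arrhythmic fly can carry a spurious weak
  "rhythmic" flag.  The spurious peaks are barely above the line
  (Q_P/threshold ≈ 1.0–1.3), whereas true rhythms sit far above it
  (ratios ≫ 2); automated classification of genuinely arrhythmic
  genotypes should therefore be read with that caveat, exactly as manual
  periodogram reading does.
* **Binning** 1-min acquisition aggregated to 10-min bins before scanning
  (degrees-of-freedom/speed trade-off; results are insensitive between 5
  and 15 min).
* **Incomplete trailing cycles are discarded**; zero-variance series get
  Q_P = 0 (non-rhythmic); peak ties break toward the shorter period
  (argmax on an increasing grid).
* **Class boundaries** 22 h and 26 h separate the three rhythmic genotype
  means (19.0, 24.3, 27.6 h) with ≥ 1.6 h margin on either side;
  boundaries are parameters of `classify_genotype`.
* **Profiles**: average activity profiles fold complete LD cycles per fly
  (mean over days) and then average over flies, ZT0 = lights-on; SEM is
  across flies.  Morning activity is the profile sum over ZT ∈ [0, 3).

## Drift-null simulator

One vial holds integer counts (wildtype males, mutant males; homozygous
wildtype, heterozygous, homozygous mutant females).  Per generation with
*N* = 400 offspring: sons *s* ~ Binomial(*N*, ½); mutant sons ~
Binomial(*s*, *q*) with *q* the maternal mutant-allele frequency
(het/2 + homMut)/females; daughter genotypes ~ Multinomial(*N* − *s*;
(1−*p*)(1−*q*), *p*(1−*q*)+(1−*p*)*q*, *pq*) with *p* the paternal mutant
frequency.  This is panmictic gamete-pool sampling — no explicit pair
formation — which matches the binomial/multinomial protocol description.
Censuses at generations 0, 3, 6, … draw min(32, males) males per vial
without replacement (hypergeometric); censused males come from extra
late-hatching flies and do not deplete the breeding pool.  Census 0 is
the founding population, whose male mutant frequency is exactly ½ by
construction (15 + 15 founders), so both envelopes collapse to [0.5, 0.5]
there.

* **Population size** fixed at 400 (the protocol's approximate carrying
  capacity); constant-*N* keeps the null model minimal.
* **Envelopes**: 2.5%/97.5% empirical quantiles (linear interpolation) of
  the across-10-vial *mean* frequency over replicates, separately for the
  population frequency and the 32-male sample frequency.  The default
  replicate count is 10⁵; the test suite and acceptance checks use 10⁴,
  where quantile noise is ≈ 0.003 — small against envelope widths of
  0.06–0.15.
* **Extinction**: if a vial ever loses all males or all females it is
  frozen at the nearest fixed allele frequency.  With *N* = 400 this is
  astronomically unlikely (2⁻⁴⁰⁰ per generation) and exists only so the
  simulator is total; frozen vials stay in the across-vial mean.
* **Determinism**: one seeded generator drives vectorised replicate
  batches; identical seeds give bit-identical envelopes.

## Mate-preference estimation

Arms: *alpha* = wildtype male marked (female chooses an *unmarked*
mutant with probability p_α), *beta* = mutant male marked.  With
α = p_α/(1 − p_α) and β = (1 − p_β)/p_β, the additive model A, a_m, a_x
gives α = (A + a_m)/(A + a_x) and β = A/(A + a_m + a_x), and

    v_m = α (1 + (1 − βα)/(β(1 + α))) = α(1 + β)/(β(1 + α)) = (A + a_m)/A .

The algebraic simplification shows v_m > 0 whenever α, β > 0, so after
boundary clamping no Monte-Carlo replicate can go degenerate; the guard
mapping a non-positive v_m to the nearer boundary of p_m is retained but
unreachable.  Properties tested: v_m recovery to 10⁻¹² over randomised
additive models, invariance of p_m under rescaling (A, a_m, a_x) by any
c > 0, and complete cancellation of the marker effect a_x.

* **Monte-Carlo CI**: redraw k_α ~ Binomial(n_α, p̂_α) and k_β ~
  Binomial(n_β, p̂_β), push through the same algebra, take 2.5%/97.5%
  quantiles of p_m over 10⁵ replicates; significant iff 0.5 is outside.
* **Boundary draws** (k = 0 or n) are clamped to 1/(2n) and 1 − 1/(2n)
  so every replicate stays defined with the replicate count fixed; the
  clamped fraction is reported.  The point estimate uses the raw rates
  when interior, else the clamped value with a warning.  Clamping makes
  the interval mildly conservative at small arms: simulated coverage of a
  true p_m = 0.7 at arm sizes 140/280 is ~95–98%.
* **Quantiles** are linear-interpolation empirical quantiles throughout
  the package.

## Fitness assays

Survival uses pooled proportions (Σpupae/Σeggs, Σadults/Σpupae) with
exact Clopper–Pearson 95% intervals via the beta quantile; with equal
eggs per vial the pooled egg→pupa estimate equals the per-vial mean.
When no pupae emerged the pupa→adult rate is reported absent.  Count
assays (sperm, offspring) report n, mean, and SD with the n−1
denominator; a single value gets SD 0 by convention.  Group summaries do
no inferential testing.

## Competition trajectories

Per-vial mutant frequency is mutant-classified calls over total calls;
the across-vial mean is unweighted even when call counts differ (the mean
of vial frequencies, not the pooled-fly frequency).  Vials where the
mutant yields no sampled males stay in the mean at frequency 0 by
default — a 32-male census cannot prove the allele is gone — with a
`drop_lost` alternative that removes zero-frequency vials.  Envelope
flags compare the mean against the 32-male *sample* envelope (the
matching sampling process); the population band is available as an
option.

## Synthetic-data generator

The generator defines the study conditions for every test:

* **Activity**: counts per bin ~ Poisson(λ(t)); λ is a baseline plus two
  circular-Gaussian bouts (morning, evening).  Under LD the bouts anchor
  to lights-on/off (ZT0/ZT12 for a 24-h day) and dark bins multiply λ by
  a suppression factor; under DD the profile recurs with the genotype's
  free-running period τ; under LL, and for arrhythmic genotypes in DD,
  λ is constant.  Arrhythmic genotypes under LD get narrow bouts at the
  light transitions, mimicking masking responses.  Default τ values are
  the reported genotype periods (24.3, 19.0, 27.6 h, arrhythmic);
  amplitudes/widths/phases are qualitative defaults chosen to reproduce
  the published profile shapes (bimodal wildtype with ~2 counts/min
  bouts over a 0.15 counts/min baseline; reduced morning and advanced
  evening bout for the short mutant; broad, high morning bout for the
  long mutant, whose ZT0–3 activity then exceeds wildtype, which exceeds
  the short mutant) — they are not digitised figure values.
* **Competition with selection**: the neutral generation step is
  re-weighted — viabilities multiply the son genotype probabilities and
  the daughter genotype probabilities (heterozygote viability defaults
  to the wildtype value, i.e. a recessive cost), and mate preference
  p_m acts as an odds multiplier on the paternal mutant frequency per
  mother genotype, everything renormalised before sampling.  Neutral
  parameters reduce the step to the drift null exactly.
* **Trials / survival / counts**: binomial chains at the specified
  rates; counts are negative-binomial with shape mean/3, i.e. variance
  ≈ 4 × mean, reflecting the strong overdispersion of the offspring
  data; shape → ∞ recovers Poisson.

What the generator does **not** emulate: temperature and humidity
effects, outdoor light, activity-level ageing, the gradual period
lengthening observed in long-period mutants during competition,
between-fly variance in τ beyond Poisson noise, and any non-additive
attractiveness.  Passing tests therefore demonstrate correctness of the
estimators under the stated stochastic models, not robustness to those
real-data features.

## Problem sizes

The test suite and the acceptance script run the assays at the study's
scales where those are cheap (10 vials × 100 eggs; 60 flies per genotype;
8 sperm counts; arm sizes 140/280 with 10⁵ Monte-Carlo replicates) and
use 10⁴ protocol replicates for drift envelopes and 200 repetitions for
coverage/detection rates, sizes at which the Monte-Carlo error is an
order of magnitude below every tolerance tested.
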