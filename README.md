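# clockcomp

Analysis toolkit for long-term competition assays between wildtype
*Drosophila* and the classical X-linked clock mutants (*per*<sup>s</sup>,
*per*<sup>l</sup>, *per*<sup>0</sup>).  In these experiments, mixed
populations founded with 15 + 15 flies of each genotype per vial are
propagated for dozens of generations (~400 offspring per transfer), and
every third generation 32 males per vial are genotyped *behaviourally*:
because the *period* locus is X-linked, a male's free-running locomotor
period in constant darkness reveals its allele (≈19 h short, ≈24 h
wildtype-like, ≈28 h long, or arrhythmic).  The scientific question is
whether the mutant frequency trajectories can be explained by genetic
drift alone, or require selection — and, downstream, which fitness
component (developmental survival, mating success, mate preference,
fecundity) drives any selection found.

The package provides the four computational stages of that pipeline, plus
a synthetic-data generator so everything is testable without recordings:

* **Chronotyping** (`clockcomp.chronotype`) — chi-square (Sokolove–Bushell)
  periodogram.  For a candidate period *P*, fold the recording into *K*
  complete cycles × *B* phase bins and compute

  *Q*<sub>P</sub> = *N K* Σ<sub>h</sub>(*M*<sub>h</sub> − *M̄*)² / Σ<sub>i</sub>(*x*<sub>i</sub> − *M̄*)²,

  compared against the χ²<sub>B−1</sub> 5% quantile; the peak period τ of
  rhythmic flies is classed short (τ < 22 h), wildtype-like (22–26 h) or
  long (τ > 26 h).  Also: average Zeitgeber-time activity profiles and
  morning-activity (ZT 0–3) summaries.
* **Drift null** (`clockcomp.drift_null`) — forward simulation of the
  exact protocol (X-linked locus, binomial sex/male-genotype and
  multinomial female-genotype sampling, hypergeometric 32-male censuses).
  10⁵ replicates give per-census 95% confidence envelopes for the
  across-vial mean mutant frequency, both for the whole population and
  for 32-male samples.
* **Mate preference** (`clockcomp.preference`) — separates the paint-mark
  effect *a*<sub>x</sub> from the genotype effect *a*<sub>m</sub> on male
  attractiveness using both marking arrangements.  With α = p<sub>α</sub>/(1 −
  p<sub>α</sub>) and β = (1 − p<sub>β</sub>)/p<sub>β</sub>, the relative
  attractiveness v<sub>m</sub> = α(1 + (1 − βα)/(β(1 + α))) = (A +
  a<sub>m</sub>)/A is marker-free, and p<sub>m</sub> = v<sub>m</sub>/(1 +
  v<sub>m</sub>) is the probability a female chooses the mutant male.
  Confidence intervals are Monte-Carlo (binomial resampling of both arms,
  10⁵ replicates).
* **Fitness assays** (`clockcomp.fitness_assays`) — pooled egg→pupa and
  pupa→adult survival with exact Clopper–Pearson intervals; sperm-count
  and offspring summaries.
* **Competition analysis** (`clockcomp.competition`) — census calls →
  per-vial and mean frequency trajectories, drift-envelope flags, and a
  trajectory/envelope overlay plot.
* **Synthetic data** (`clockcomp.synthetic`) — Poisson activity series
  with genotype-specific bimodal profiles and free-running periods,
  competition simulations with optional viability/mating selection,
  binomial mating trials and survival assays, negative-binomial count
  assays.

## Worked example

```python
import clockcomp as cc

# chronotype one synthetic short-period mutant from 14 days of DD activity
fly = cc.gen_activity(cc.DEFAULT_GENOTYPES["per_s"], cc.dd_regime(14), seed=1)
call = cc.classify_genotype(cc.chi_square_periodogram(fly))
print(call.genotype_class, call.tau)            # -> short 19.0

# neutral drift envelope vs. a competition with halved mutant viability
cfg = cc.DriftConfig(n_censuses=5, replicates=10_000, seed=2)
env = cc.neutral_envelopes(cfg)
sel = cc.SelectionParams(viability_male_mut=0.5, viability_female_mm=0.5)
records = cc.gen_competition(cfg, sel, seed=3)
traj = cc.census_frequencies(records, mutant_classes=("short",))
print(traj.mean.round(3), cc.envelope_flags(traj, env))
# -> [0.5   0.203 0.109 0.034 0.012 0.016] [False  True  True  True  True  True]

# mating preference with a marker effect: v_m = 1.5, so true p_m = 0.6
model = cc.AdditiveAttractiveness(A=1.0, a_m=0.5, a_x=0.2)
arms = cc.gen_mating_trials(model, n_per_arm=280, mating_success=0.5, seed=4)
est = cc.mc_confidence_interval(*arms, seed=5)
print(round(est.p_m, 3), tuple(round(x, 3) for x in est.ci95), est.significant)
# -> 0.63 (0.573, 0.688) True
```

The first block reads: the periodogram peak of the simulated fly sits at
19.0 h, so it is classed a short-period mutant.  The second: under
halved mutant viability the across-vial mean mutant frequency collapses
from 0.5 to ~0.02 within five censuses (15 generations) and is flagged
outside the neutral 95% envelope from census 1 on — drift alone cannot
produce this.  The third: from 2 × 280 choice trials the estimated
preference for mutant males is 0.63 (95% CI 0.57–0.69), significantly
above 0.5 and close to the generating value 0.6 despite the marker
effect.

## Documentation

`docs/methods.md` describes the models, default parameters, numerical
conventions and known limitations.
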