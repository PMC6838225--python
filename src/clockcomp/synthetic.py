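"""Synthetic inputs with the statistical structure the analysis assumes.

The competition study recorded locomotor activity, census genotype counts,
two-male mating trials and developmental-survival assays.  No raw data are
bundled here; instead every input is generated from an explicit stochastic
model so each analysis stage can be tested end-to-end:

* activity: inhomogeneous Poisson counts with a bimodal (morning/evening)
  rate profile anchored to lights-on/off under LD and recurring with the
  genotype's free-running period tau under DD; arrhythmic genotypes have a
  flat rate (with lights-on/off response peaks under LD only, mimicking
  masking);
* competition: the drift-null protocol extended with viability and mating
  weights on the offspring genotype probabilities;
* mating trials: binomial choices at the additive-attractiveness arm
  probabilities;
* survival assays: binomial egg->pupa and pupa->adult chains;
* count assays: negative-binomial draws (overdispersed relative to
  Poisson).

Default free-running periods (24.3 / 19.0 / 27.6 h, arrhythmic) and
survival rates are the study's reported genotype values; activity-rate
amplitudes are qualitative defaults chosen to reproduce the shape of the
published profiles (bimodal wildtype, advanced evening bout in the short
mutant, broad elevated morning bout in the long mutant, flat responder for
the arrhythmic null), not digitised figure values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np

from .chronotype import GenotypeCall, chi_square_periodogram, classify_genotype
from .competition import CensusRecord
from .drift_null import DriftConfig, _pop_freq, _sample_arrays
from .fitness_assays import SurvivalAssay
from .io_dam import (ActivitySeries, DomainError, LightRegime, ValidationError,
                     dd_regime)
from .preference import (ARM_MUTANT_MARKED, ARM_WILDTYPE_MARKED,
                         AdditiveAttractiveness, MatingTrialSet)

__all__ = [
    "TAU",
    "EGG_TO_PUPA",
    "PUPA_TO_ADULT",
    "SPERM_MEAN",
    "GenotypeParams",
    "SelectionParams",
    "DEFAULT_GENOTYPES",
    "gen_activity",
    "gen_competition",
    "gen_mating_trials",
    "gen_survival_assay",
    "gen_counts",
]

#: reported free-running periods (h) used as generator ground truth;
#: None = arrhythmic.
TAU = {"wildtype": 24.3, "per_s": 19.0, "per_l": 27.6, "per_0": None}

#: reported pooled developmental survival rates used as generator defaults.
EGG_TO_PUPA = {"wildtype": 0.863, "per_s": 0.472, "per_l": 0.466,
               "per_0": 0.768}
PUPA_TO_ADULT = {"wildtype": 0.971, "per_s": 0.971, "per_l": 0.968,
                 "per_0": 0.992}

#: reported mean transferred sperm per successful mating.
SPERM_MEAN = {"wildtype": 1257, "per_s": 949}

#: default negative-binomial shape: variance ~ 4x mean, reflecting the
#: strong overdispersion of the offspring counts.  shape k = mean / 3 gives
#: var = mean + mean^2/k = 4 * mean.
DEFAULT_VARIANCE_RATIO = 4.0


@dataclass(frozen=True)
class GenotypeParams:
    """Activity-rate model for one genotype.

    Rates are counts per 1-min bin.  Peak phases are hours after
    lights-on (LD) or after subjective lights-on (DD, where the pattern
    recurs with period ``tau``); widths are Gaussian sigmas in hours.
    ``dark_suppression`` multiplies the rate during dark bins (masking).
    """

    label: str
    tau: float | None
    morning_phase: float = 0.0
    morning_width: float = 1.0
    morning_amp: float = 1.5
    evening_phase: float = 12.0
    evening_width: float = 1.2
    evening_amp: float = 2.0
    baseline: float = 0.15
    dark_suppression: float = 0.4

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.morning_amp < 0 or self.evening_amp < 0:
            raise ValidationError("rates must be non-negative")
        if self.morning_width <= 0 or self.evening_width <= 0:
            raise ValidationError("peak widths must be positive")
        if not 0.0 <= self.dark_suppression <= 1.0:
            raise ValidationError("dark suppression must lie in [0, 1]")


DEFAULT_GENOTYPES = {
    "wildtype": GenotypeParams(
        label="wildtype", tau=TAU["wildtype"],
        morning_phase=0.0, morning_width=1.0, morning_amp=1.5,
        evening_phase=12.0, evening_width=1.2, evening_amp=2.0,
        baseline=0.15, dark_suppression=0.4),
    # advanced, weaker evening bout; reduced morning activity
    "per_s": GenotypeParams(
        label="per_s", tau=TAU["per_s"],
        morning_phase=0.0, morning_width=1.0, morning_amp=0.7,
        evening_phase=8.0, evening_width=1.5, evening_amp=1.8,
        baseline=0.15, dark_suppression=0.3),
    # broad, high morning bout stretching to midday; evening after dark
    "per_l": GenotypeParams(
        label="per_l", tau=TAU["per_l"],
        morning_phase=1.5, morning_width=3.0, morning_amp=2.5,
        evening_phase=13.0, evening_width=1.5, evening_amp=1.5,
        baseline=0.15, dark_suppression=0.3),
    # flat with lights-on/off response spikes (masking only)
    "per_0": GenotypeParams(
        label="per_0", tau=None,
        morning_phase=0.0, morning_width=0.3, morning_amp=1.5,
        evening_phase=12.0, evening_width=0.3, evening_amp=1.5,
        baseline=0.8, dark_suppression=0.5),
}


@dataclass(frozen=True)
class SelectionParams:
    """Fitness components applied on top of the neutral protocol.

    Viabilities are egg-to-adult survival probabilities relative to any
    common scale (only ratios matter after renormalisation).  The
    heterozygote viability defaults to the wildtype value (recessive
    cost).  ``preference_pm`` is the probability that a choosing female
    takes a mutant over a wildtype father, per female genotype;
    ``mating_success`` scales how often mutant fathers sire offspring.
    """

    viability_male_wt: float = 1.0
    viability_male_mut: float = 1.0
    viability_female_ww: float = 1.0
    viability_female_het: float | None = None
    viability_female_mm: float = 1.0
    preference_pm: dict = field(default_factory=dict)  # female genotype -> p_m
    mating_success_mut: float = 1.0

    def __post_init__(self) -> None:
        v = (self.viability_male_wt, self.viability_male_mut,
             self.viability_female_ww, self.viability_female_mm,
             self.mating_success_mut)
        if any(x < 0 for x in v):
            raise ValidationError("fitness components must be >= 0")
        if (self.viability_male_wt == 0 and self.viability_male_mut == 0):
            raise DomainError("all male viabilities are zero")
        for pm in self.preference_pm.values():
            if not 0.0 < pm < 1.0:
                raise ValidationError("preference p_m must lie in (0, 1)")

    @property
    def v_het(self) -> float:
        return (self.viability_female_ww
                if self.viability_female_het is None
                else self.viability_female_het)

    def father_weight(self, female_genotype: str) -> float:
        """Odds multiplier for a mutant father given the mother's genotype."""
        pm = self.preference_pm.get(female_genotype, 0.5)
        return (pm / (1.0 - pm)) * self.mating_success_mut


NEUTRAL = SelectionParams()


# ---------------------------------------------------------------------------
# Activity
# ---------------------------------------------------------------------------

def _circular_peak(phase: np.ndarray, center: float, width: float,
                   amp: float, cycle: float) -> np.ndarray:
    d = np.mod(phase - center + cycle / 2.0, cycle) - cycle / 2.0
    return amp * np.exp(-0.5 * (d / width) ** 2)


def _rate_profile(params: GenotypeParams, regime: LightRegime,
                  bin_width: int) -> np.ndarray:
    """Expected counts per bin over the whole regime."""
    lam = np.empty(regime.total_bins)
    for seg, a, b in regime.segment_slices():
        n = b - a
        t = (np.arange(n) + 0.5) * bin_width / 60.0  # hours in segment
        if seg.mode == "LD":
            zt = np.mod(t, seg.T)
            rate = np.full(n, params.baseline)
            rate += _circular_peak(zt, params.morning_phase,
                                   params.morning_width, params.morning_amp,
                                   seg.T)
            rate += _circular_peak(zt, params.evening_phase,
                                   params.evening_width, params.evening_amp,
                                   seg.T)
            dark = zt >= seg.T * seg.light_fraction
            rate[dark] *= params.dark_suppression
        elif seg.mode == "DD":
            if params.tau is None:
                rate = np.full(n, params.baseline * params.dark_suppression)
            else:
                phase = np.mod(t, params.tau)
                rate = np.full(n, params.baseline)
                rate += _circular_peak(phase, params.morning_phase,
                                       params.morning_width,
                                       params.morning_amp, params.tau)
                rate += _circular_peak(phase, params.evening_phase,
                                       params.evening_width,
                                       params.evening_amp, params.tau)
                rate *= params.dark_suppression
        else:  # LL: constant light renders all genotypes arrhythmic
            rate = np.full(n, params.baseline)
        lam[a:b] = rate * (bin_width / 1.0)  # params are per 1-min bin
    return lam


def gen_activity(params: GenotypeParams, regime: LightRegime,
                 bin_width: int = 1,
                 seed: int | np.random.Generator | None = None,
                 fly_id: str | None = None,
                 start: datetime = datetime(2014, 6, 1)) -> ActivitySeries:
    """Poisson beam-cross counts for one fly under the given regime."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    lam = _rate_profile(params, regime, bin_width)
    counts = rng.poisson(lam)
    return ActivitySeries(
        fly_id=fly_id or f"synthetic-{params.label}",
        bin_width=bin_width,
        start=start,
        counts=counts,
        regime=regime,
    )


# ---------------------------------------------------------------------------
# Competition with selection
# ---------------------------------------------------------------------------

def _advance_selected(mw, mm, fww, fhet, fmm, n_offspring,
                      sel: SelectionParams, rng):
    """One generation with viability and mating weights (vectorised)."""
    males = mw + mm
    females = fww + fhet + fmm
    alive = (males > 0) & (females > 0)
    p = np.where(alive, mm / np.maximum(males, 1), 0.0)
    q_num = fhet / 2.0 + fmm
    q = np.where(alive, q_num / np.maximum(females, 1), 0.0)

    ftot = np.maximum(females, 1)
    f_ww = fww / ftot
    f_het = fhet / ftot
    f_mm = fmm / ftot

    # effective paternal mutant probability per mother genotype: the
    # preference and mating-success terms act as an odds multiplier on p
    def p_eff(genotype: str) -> np.ndarray:
        w = sel.father_weight(genotype)
        with np.errstate(invalid="ignore"):
            return np.where(p > 0, p * w / (p * w + (1.0 - p)), 0.0)

    p_ww, p_het, p_mm_ = p_eff("WT/WT"), p_eff("WT/mut"), p_eff("mut/mut")

    # maternal transmission of the mutant allele is 0, 1/2, 1 by genotype
    son_q = f_het * 0.5 + f_mm * 1.0
    dau_mm = f_ww * 0.0 + f_het * 0.5 * p_het + f_mm * 1.0 * p_mm_
    dau_ww = (f_ww * (1.0 - p_ww) + f_het * 0.5 * (1.0 - p_het))
    dau_het = np.clip(1.0 - dau_mm - dau_ww, 0.0, 1.0)

    # viability weighting, renormalised within each sex
    son_mut_w = son_q * sel.viability_male_mut
    son_wt_w = (1.0 - son_q) * sel.viability_male_wt
    tot = son_mut_w + son_wt_w
    son_pr = np.where(tot > 0, son_mut_w / np.maximum(tot, 1e-300), 0.0)

    w_ww = dau_ww * sel.viability_female_ww
    w_het = dau_het * sel.v_het
    w_mm = dau_mm * sel.viability_female_mm
    wtot = np.maximum(w_ww + w_het + w_mm, 1e-300)
    w_ww, w_het, w_mm = w_ww / wtot, w_het / wtot, w_mm / wtot

    sons = rng.binomial(n_offspring, 0.5, size=mw.shape)
    sons_mut = rng.binomial(sons, son_pr)
    daughters = n_offspring - sons
    d_ww = rng.binomial(daughters, w_ww)
    rest = daughters - d_ww
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(w_ww < 1.0, w_het / np.maximum(1.0 - w_ww, 1e-300), 0.0)
    d_het = rng.binomial(rest, np.clip(cond, 0.0, 1.0))
    d_mm = rest - d_het

    return (
        np.where(alive, sons - sons_mut, mw),
        np.where(alive, sons_mut, mm),
        np.where(alive, d_ww, fww),
        np.where(alive, d_het, fhet),
        np.where(alive, d_mm, fmm),
    )


def simulate_selected_frequencies(config: DriftConfig,
                                  selection: SelectionParams,
                                  n_replicates: int,
                                  rng: np.random.Generator,
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Selected analogue of the drift-null batch simulator.

    Returns ``(pop, samp)`` frequencies of shape
    ``(n_replicates, n_censuses + 1, n_vials)``.
    """
    shape = (n_replicates, config.n_vials)
    f = config.founders
    mw = np.full(shape, f, np.int64)
    mm = np.full(shape, f, np.int64)
    fww = np.full(shape, f, np.int64)
    fhet = np.zeros(shape, np.int64)
    fmm = np.full(shape, f, np.int64)

    pop = np.empty((n_replicates, config.n_censuses + 1, config.n_vials))
    samp = np.empty_like(pop)
    pop[:, 0] = _pop_freq(mw, mm)
    samp[:, 0] = _sample_arrays(mw, mm, config.sample_size, rng)
    for ci in range(1, config.n_censuses + 1):
        for _ in range(config.census_every):
            mw, mm, fww, fhet, fmm = _advance_selected(
                mw, mm, fww, fhet, fmm, config.offspring, selection, rng)
        pop[:, ci] = _pop_freq(mw, mm)
        samp[:, ci] = _sample_arrays(mw, mm, config.sample_size, rng)
    return pop, samp


def gen_competition(config: DriftConfig,
                    selection: SelectionParams = NEUTRAL,
                    seed: int | np.random.Generator | None = None,
                    mutant_class: str = "short",
                    mutant_tau: float | None = 19.0,
                    experiment: str = "synthetic",
                    via_activity: bool = False,
                    activity_params: dict | None = None,
                    ) -> list[CensusRecord]:
    """Simulate one competition experiment and emit census genotype calls.

    By default the sampled males' genotypes are emitted directly (a mutant
    male is called ``mutant_class`` with period ``mutant_tau``, a wildtype
    male ``wildtype_like`` at 24.3 h).  With ``via_activity`` each sampled
    male instead gets a synthetic DD recording which is chronotyped through
    the periodogram — the full pipeline, at ~100x the cost.
    """
    if mutant_class == "arrhythmic" and mutant_tau is not None:
        raise ValidationError("arrhythmic mutants carry no tau")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    shape = (1, config.n_vials)
    fnd = config.founders
    mw = np.full(shape, fnd, np.int64)
    mm = np.full(shape, fnd, np.int64)
    fww = np.full(shape, fnd, np.int64)
    fhet = np.zeros(shape, np.int64)
    fmm = np.full(shape, fnd, np.int64)

    params = activity_params or DEFAULT_GENOTYPES
    records: list[CensusRecord] = []

    def census(ci: int) -> None:
        males = (mw + mm)[0]
        for v in range(config.n_vials):
            total = int(males[v])
            if total == 0:
                records.append(CensusRecord(experiment, f"vial{v + 1:02d}",
                                            ci, []))
                continue
            k = min(config.sample_size, total)
            n_mut = int(rng.hypergeometric(int(mm[0, v]), int(mw[0, v]), k))
            calls = []
            for i in range(k):
                is_mut = i < n_mut
                fid = f"{experiment}-c{ci}-v{v + 1}-m{i + 1}"
                if via_activity:
                    label = mutant_class if is_mut else "wildtype_like"
                    gp = _activity_params_for(label, params, mutant_tau)
                    series = gen_activity(gp, dd_regime(10.0), seed=rng,
                                          fly_id=fid)
                    calls.append(classify_genotype(
                        chi_square_periodogram(series)))
                elif is_mut:
                    calls.append(GenotypeCall(fid, mutant_class, mutant_tau))
                else:
                    calls.append(GenotypeCall(fid, "wildtype_like", 24.3))
            records.append(CensusRecord(experiment, f"vial{v + 1:02d}", ci,
                                        calls))

    census(0)
    for ci in range(1, config.n_censuses + 1):
        for _ in range(config.census_every):
            mw, mm, fww, fhet, fmm = _advance_selected(
                mw, mm, fww, fhet, fmm, config.offspring, selection, rng)
        census(ci)
    return records


def _activity_params_for(label: str, params: dict,
                         mutant_tau: float | None) -> GenotypeParams:
    by_class = {"short": "per_s", "long": "per_l", "arrhythmic": "per_0",
                "wildtype_like": "wildtype"}
    gp = params[by_class[label]]
    if label not in ("wildtype_like", "arrhythmic") and mutant_tau is not None:
        gp = replace(gp, tau=mutant_tau)
    return gp


# ---------------------------------------------------------------------------
# Mating trials, survival, counts
# ---------------------------------------------------------------------------

def gen_mating_trials(model: AdditiveAttractiveness,
                      n_per_arm: int,
                      mating_success: float = 0.3,
                      seed: int | np.random.Generator | None = None,
                      female_genotype: str = "WT/WT",
                      male_genotype: str = "per_s",
                      ) -> tuple[MatingTrialSet, MatingTrialSet]:
    """Simulate the two marked-male arms of a choice experiment.

    Returns ``(wildtype_marked_arm, mutant_marked_arm)``: matings are
    binomial at the overall mating-success rate, and within matings the
    female picks the mutant with the model's arm probability.
    """
    if not 0.0 < mating_success <= 1.0:
        raise DomainError("mating success must lie in (0, 1]")
    if n_per_arm < 1:
        raise DomainError("need at least one trial per arm")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    m_a = int(rng.binomial(n_per_arm, mating_success))
    m_b = int(rng.binomial(n_per_arm, mating_success))
    k_a = int(rng.binomial(m_a, model.p_alpha)) if m_a else 0
    k_b = int(rng.binomial(m_b, model.p_beta)) if m_b else 0
    arm_a = MatingTrialSet(female_genotype, male_genotype,
                           ARM_WILDTYPE_MARKED, n_per_arm, m_a, k_a)
    arm_b = MatingTrialSet(female_genotype, male_genotype,
                           ARM_MUTANT_MARKED, n_per_arm, m_b, k_b)
    return arm_a, arm_b


def gen_survival_assay(rates: dict[str, tuple[float, float]] | None = None,
                       n_vials: int = 10, eggs_per_vial: int = 100,
                       seed: int | np.random.Generator | None = None,
                       ) -> dict[str, SurvivalAssay]:
    """Binomial developmental-survival assays, one per genotype.

    ``rates`` maps genotype to (egg->pupa, pupa->adult) probabilities; the
    default is the reported genotype rates.  Per vial, pupae are binomial
    in the eggs and adults binomial in the pupae.
    """
    if rates is None:
        rates = {g: (EGG_TO_PUPA[g], PUPA_TO_ADULT[g]) for g in EGG_TO_PUPA}
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = {}
    for genotype, (s_e, s_p) in rates.items():
        if not (0.0 <= s_e <= 1.0 and 0.0 <= s_p <= 1.0):
            raise DomainError("survival rates must lie in [0, 1]")
        pupae = rng.binomial(eggs_per_vial, s_e, size=n_vials)
        adults = rng.binomial(pupae, s_p)
        out[genotype] = SurvivalAssay(
            genotype=genotype,
            eggs=[eggs_per_vial] * n_vials,
            pupae=pupae.tolist(),
            adults=adults.tolist(),
        )
    return out


def gen_counts(mean: float, n: int,
               dispersion: float | None = None,
               seed: int | np.random.Generator | None = None) -> list[int]:
    """Overdispersed count draws (sperm numbers, offspring per female).

    Negative binomial with the given mean and gamma shape ``dispersion``
    (variance = mean + mean^2/dispersion).  The default shape mean/3 gives
    variance ~ 4x the mean; ``dispersion=inf`` degenerates to Poisson.
    """
    if mean < 0:
        raise DomainError("mean must be >= 0")
    if n < 1:
        raise DomainError("need n >= 1 draws")
    if dispersion is None:
        dispersion = mean / (DEFAULT_VARIANCE_RATIO - 1.0)
    if dispersion <= 0:
        raise DomainError("dispersion must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if mean == 0:
        return [0] * n
    if np.isinf(dispersion):
        return rng.poisson(mean, size=n).astype(int).tolist()
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n).astype(int).tolist()
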