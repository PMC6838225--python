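"""Mate-choice attractiveness estimation from two-male trials.

A single female is offered one mutant and one wildtype male; one of the two
males carries a white paint mark so the genotypes can be told apart.  The
mark itself may change attractiveness, so the design runs both versions:
the *alpha* arm marks the wildtype male (the female chooses an unmarked
mutant with probability p_alpha) and the *beta* arm marks the mutant (she
chooses a marked mutant with probability p_beta).  Under an additive model
with base attractiveness A, a mutant effect a_m and a marker effect a_x,

    alpha = p_alpha / (1 - p_alpha) = (A + a_m) / (A + a_x)
    1/beta = (1 - p_beta) / p_beta ... beta = A / (A + a_m + a_x)

and the marker effect cancels out of the relative attractiveness of mutant
over wildtype males,

    v_m = alpha * (1 + (1 - beta*alpha) / (beta * (1 + alpha)))
        = (A + a_m) / A,

giving the preference probability p_m = v_m / (1 + v_m): the chance a
female picks the mutant were neither male marked.  No closed-form interval
exists for p_m, so the confidence interval is Monte-Carlo: redraw the two
arm counts from binomials at the observed rates, push each draw through the
same algebra, and take the empirical 2.5% / 97.5% quantiles.  A preference
is significant when 0.5 lies outside that interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitness_assays import exact_binomial_ci
from .io_dam import DomainError, ValidationError, log

__all__ = [
    "ARM_WILDTYPE_MARKED",
    "ARM_MUTANT_MARKED",
    "MatingTrialSet",
    "AdditiveAttractiveness",
    "PreferenceEstimate",
    "choice_ratios",
    "relative_attractiveness",
    "preference_probability",
    "mc_confidence_interval",
    "mating_success",
]

#: arm labels: which of the two males carried the paint mark.
ARM_WILDTYPE_MARKED = "wildtype_marked"   # female chose an unmarked mutant (alpha)
ARM_MUTANT_MARKED = "mutant_marked"       # female chose a marked mutant (beta)


@dataclass(frozen=True)
class MatingTrialSet:
    """Aggregated outcomes of one arm of a choice experiment."""

    female_genotype: str        # "WT/WT", "WT/mut" or "mut/mut"
    male_genotype: str          # which mutant the wildtype male competed with
    arm: str                    # ARM_WILDTYPE_MARKED or ARM_MUTANT_MARKED
    trials: int
    matings: int
    chose_mutant: int

    def __post_init__(self) -> None:
        if self.arm not in (ARM_WILDTYPE_MARKED, ARM_MUTANT_MARKED):
            raise ValidationError(f"unknown arm {self.arm!r}")
        if not 0 <= self.chose_mutant <= self.matings <= self.trials:
            raise ValidationError(
                "need 0 <= chose_mutant <= matings <= trials"
            )


@dataclass(frozen=True)
class AdditiveAttractiveness:
    """Forward additive model: base A, mutant effect a_m, marker effect a_x."""

    A: float = 1.0
    a_m: float = 0.0
    a_x: float = 0.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValidationError("base attractiveness must be positive")
        for s in (self.A + self.a_m, self.A + self.a_x,
                  self.A + self.a_m + self.a_x):
            if s <= 0:
                raise ValidationError("all attractiveness sums must be positive")

    @property
    def p_alpha(self) -> float:
        """P(choose unmarked mutant over marked wildtype)."""
        return (self.A + self.a_m) / (2 * self.A + self.a_x + self.a_m)

    @property
    def p_beta(self) -> float:
        """P(choose marked mutant over unmarked wildtype)."""
        return (self.A + self.a_m + self.a_x) / (2 * self.A + self.a_x + self.a_m)

    @property
    def v_m(self) -> float:
        return (self.A + self.a_m) / self.A

    @property
    def p_m(self) -> float:
        return self.v_m / (1.0 + self.v_m)


@dataclass
class PreferenceEstimate:
    p_alpha_hat: float
    p_beta_hat: float
    alpha: float
    beta: float
    v_m: float
    p_m: float
    ci95: tuple[float, float]
    significant: bool
    clamped_fraction: float
    n_replicates: int

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValidationError("CI bounds must satisfy 0 <= lo <= hi <= 1")


def choice_ratios(p_alpha, p_beta):
    """Turn the two arm probabilities into the odds ratios alpha and beta."""
    p_alpha = np.asarray(p_alpha, dtype=float)
    p_beta = np.asarray(p_beta, dtype=float)
    if np.any((p_alpha <= 0) | (p_alpha >= 1) | (p_beta <= 0) | (p_beta >= 1)):
        raise DomainError("arm probabilities must lie strictly in (0, 1)")
    alpha = p_alpha / (1.0 - p_alpha)
    beta = (1.0 - p_beta) / p_beta
    if alpha.ndim == 0:
        return float(alpha), float(beta)
    return alpha, beta


def relative_attractiveness(alpha, beta):
    """Mutant-over-wildtype attractiveness ratio v_m from the two odds."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(alpha <= 0) or np.any(beta <= 0):
        raise DomainError("alpha and beta must be positive")
    v = alpha * (1.0 + (1.0 - beta * alpha) / (beta * (1.0 + alpha)))
    return float(v) if v.ndim == 0 else v


def preference_probability(v_m):
    """Probability of choosing the mutant male, p_m = v_m / (1 + v_m)."""
    v = np.asarray(v_m, dtype=float)
    if np.any(v <= 0):
        raise DomainError("v_m must be positive")
    p = v / (1.0 + v)
    return float(p) if p.ndim == 0 else p


def _clamp(k: np.ndarray, n: int) -> np.ndarray:
    """Empirical rates with boundary draws pulled inside (0, 1).

    k = 0 and k = n would make the odds ratios 0 or infinite; they are
    mapped to 1/(2n) and 1 - 1/(2n) so every replicate stays defined.
    """
    return np.clip(k / n, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))


def mc_confidence_interval(trial_alpha: MatingTrialSet,
                           trial_beta: MatingTrialSet,
                           n_replicates: int = 100_000,
                           seed: int | np.random.Generator | None = None,
                           ) -> PreferenceEstimate:
    """Point estimate and Monte-Carlo 95% CI for the preference p_m.

    ``trial_alpha`` must be the wildtype-marked arm and ``trial_beta`` the
    mutant-marked arm.  Per replicate the two mutant-choice counts are
    redrawn from binomials at the observed arm rates and pushed through the
    same ratio algebra; the CI is the 2.5%/97.5% quantile pair of the
    resulting p_m values, and the preference is significant iff 0.5 falls
    outside it.  Boundary draws (k = 0 or k = n) are clamped inside (0, 1);
    their fraction is reported.
    """
    if trial_alpha.arm != ARM_WILDTYPE_MARKED:
        raise DomainError("trial_alpha must be the wildtype-marked arm")
    if trial_beta.arm != ARM_MUTANT_MARKED:
        raise DomainError("trial_beta must be the mutant-marked arm")
    if trial_alpha.matings < 1 or trial_beta.matings < 1:
        raise DomainError("both arms need at least one mating")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    n_a, n_b = trial_alpha.matings, trial_beta.matings
    pa_raw = trial_alpha.chose_mutant / n_a
    pb_raw = trial_beta.chose_mutant / n_b
    pa_hat = float(np.clip(pa_raw, 1.0 / (2 * n_a), 1.0 - 1.0 / (2 * n_a)))
    pb_hat = float(np.clip(pb_raw, 1.0 / (2 * n_b), 1.0 - 1.0 / (2 * n_b)))
    if pa_hat != pa_raw or pb_hat != pb_raw:
        log.warning("boundary arm rate clamped for the point estimate "
                    "(p_alpha=%.4g, p_beta=%.4g)", pa_raw, pb_raw)

    alpha, beta = choice_ratios(pa_hat, pb_hat)
    v_m = relative_attractiveness(alpha, beta)
    p_m = preference_probability(v_m)

    k_a = rng.binomial(n_a, pa_hat, size=n_replicates)
    k_b = rng.binomial(n_b, pb_hat, size=n_replicates)
    clamped = (k_a == 0) | (k_a == n_a) | (k_b == 0) | (k_b == n_b)
    pa_r = _clamp(k_a, n_a)
    pb_r = _clamp(k_b, n_b)
    alpha_r, beta_r = choice_ratios(pa_r, pb_r)
    v_r = alpha_r * (1.0 + (1.0 - beta_r * alpha_r) / (beta_r * (1.0 + alpha_r)))
    p_r = np.where(v_r > 0, v_r / (1.0 + v_r),
                   np.where(alpha_r >= 1.0, 1.0, 0.0))
    degenerate = v_r <= 0
    if degenerate.any():  # unreachable for clamped interior rates; kept as guard
        log.warning("%d Monte-Carlo replicates had non-positive v_m",
                    int(degenerate.sum()))
    lo, hi = np.quantile(p_r, [0.025, 0.975])
    return PreferenceEstimate(
        p_alpha_hat=pa_hat,
        p_beta_hat=pb_hat,
        alpha=alpha,
        beta=beta,
        v_m=v_m,
        p_m=p_m,
        ci95=(float(lo), float(hi)),
        significant=not (lo <= 0.5 <= hi),
        clamped_fraction=float((clamped | degenerate).mean()),
        n_replicates=n_replicates,
    )


def mating_success(trials: list[MatingTrialSet]) -> pd.DataFrame:
    """Proportion of trials ending in a mating, with exact 95% CIs.

    Arms are pooled within each female-genotype x male-genotype cell;
    intervals are Clopper-Pearson.
    """
    if not trials:
        raise DomainError("no trials given")
    df = pd.DataFrame([{
        "female_genotype": t.female_genotype,
        "male_genotype": t.male_genotype,
        "trials": t.trials,
        "matings": t.matings,
    } for t in trials])
    grouped = df.groupby(["female_genotype", "male_genotype"], sort=True).sum()
    rows = []
    for (fg, mg), row in grouped.iterrows():
        n, k = int(row["trials"]), int(row["matings"])
        if n < 1:
            raise DomainError(f"cell {fg} x {mg} has no trials")
        lo, hi = exact_binomial_ci(k, n)
        rows.append({
            "female_genotype": fg, "male_genotype": mg,
            "trials": n, "matings": k,
            "proportion": k / n, "ci_low": lo, "ci_high": hi,
        })
    return pd.DataFrame(rows)
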