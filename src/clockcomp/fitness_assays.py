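"""Descriptive estimators for the fitness side-assays.

Covers the developmental-survival assay (10 vials x 100 eggs per genotype,
scored for pupae and emerged adults), the sperm-transfer counts, and the
per-female offspring counts.  Point estimates are pooled proportions with
exact Clopper-Pearson binomial intervals, or plain means with sample
standard deviations for count data; hypothesis testing is deliberately out
of scope here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .io_dam import DomainError, ValidationError, log

__all__ = [
    "SurvivalAssay",
    "SurvivalRates",
    "CountSummary",
    "exact_binomial_ci",
    "survival_rates",
    "summarize_counts",
    "offspring_table",
]


def exact_binomial_ci(k: int, n: int, level: float = 0.95,
                      ) -> tuple[float, float]:
    """Clopper-Pearson interval for a binomial proportion."""
    if n < 1 or not 0 <= k <= n:
        raise DomainError(f"invalid binomial counts {k}/{n}")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
    # the beta quantile is undefined at the boundaries; the exact interval
    # closes there
    lo = 0.0 if math.isnan(lo) else float(lo)
    hi = 1.0 if math.isnan(hi) else float(hi)
    return lo, hi


@dataclass
class SurvivalAssay:
    """Per-vial egg, pupa and adult counts for one genotype."""

    genotype: str
    eggs: Sequence[int]
    pupae: Sequence[int]
    adults: Sequence[int]

    def __post_init__(self) -> None:
        self.eggs = list(int(v) for v in self.eggs)
        self.pupae = list(int(v) for v in self.pupae)
        self.adults = list(int(v) for v in self.adults)
        if not (len(self.eggs) == len(self.pupae) == len(self.adults)):
            raise ValidationError("egg/pupa/adult vectors differ in length")
        if not self.eggs:
            raise ValidationError("assay needs at least one vial")
        for e, p, a in zip(self.eggs, self.pupae, self.adults):
            if not 0 <= a <= p <= e:
                raise ValidationError(
                    f"need 0 <= adults <= pupae <= eggs, got {a}/{p}/{e}"
                )


@dataclass
class SurvivalRates:
    """Pooled developmental survival proportions with exact 95% CIs."""

    genotype: str
    s_e: float                           # egg -> pupa
    s_e_ci: tuple[float, float]
    s_p: float | None                    # pupa -> adult; None if no pupae
    s_p_ci: tuple[float, float] | None
    eggs: int
    pupae: int
    adults: int


@dataclass
class CountSummary:
    label: str
    values: list[int]
    n: int
    mean: float
    sd: float  # n-1 denominator; 0.0 by convention for a single value


def survival_rates(assay: SurvivalAssay, level: float = 0.95) -> SurvivalRates:
    """Pooled egg->pupa and pupa->adult survival with exact binomial CIs.

    Pooling over vials (rather than averaging per-vial rates) matches the
    binomial interval construction; with equal egg numbers per vial the two
    coincide for s_e.  If no pupae emerged, s_p is undefined and reported
    absent.
    """
    eggs, pupae, adults = sum(assay.eggs), sum(assay.pupae), sum(assay.adults)
    s_e = pupae / eggs
    s_e_ci = exact_binomial_ci(pupae, eggs, level)
    if pupae == 0:
        log.warning("assay %s produced no pupae; s_p undefined", assay.genotype)
        s_p, s_p_ci = None, None
    else:
        s_p = adults / pupae
        s_p_ci = exact_binomial_ci(adults, pupae, level)
    return SurvivalRates(genotype=assay.genotype, s_e=s_e, s_e_ci=s_e_ci,
                         s_p=s_p, s_p_ci=s_p_ci,
                         eggs=eggs, pupae=pupae, adults=adults)


def summarize_counts(label: str, values: Sequence[int]) -> CountSummary:
    """Mean and sample SD of a count assay (sperm numbers, offspring)."""
    vals = [int(v) for v in values]
    if not vals:
        raise DomainError("no values to summarize")
    if any(v < 0 for v in vals):
        raise ValidationError("counts must be non-negative")
    arr = np.asarray(vals, dtype=float)
    sd = float(arr.std(ddof=1)) if len(vals) > 1 else 0.0
    return CountSummary(label=label, values=vals, n=len(vals),
                        mean=float(arr.mean()), sd=sd)


def offspring_table(counts: Mapping[tuple[str, str], Sequence[int]],
                    ) -> list[CountSummary]:
    """Group per-female offspring counts by (female genotype, mate genotype).

    Empty groups are omitted.  Purely descriptive: group means, SDs and ns.
    """
    out = []
    for (female, male), values in sorted(counts.items()):
        if len(values) == 0:
            continue
        out.append(summarize_counts(f"{female} x {male}", values))
    return out
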