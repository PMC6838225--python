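"""Neutral forward simulation of the X-linked competition protocol.

Each vial is founded with 15 virgin females and 15 males of the wildtype and
15 + 15 of one clock mutant, then propagated with ~400 offspring per
14-day generation.  The clock locus is X-linked, so males are hemizygous
(wildtype or mutant) and females carry two alleles (homozygous wildtype,
heterozygous, homozygous mutant).  Under neutrality and panmixia the next
generation is drawn from the parental gamete pool:

* number of sons s ~ Binomial(N, 1/2) (random sex determination),
* mutant sons ~ Binomial(s, q) with q the maternal mutant-allele frequency,
* daughter genotypes ~ Multinomial(N - s; (1-p)(1-q), p(1-q)+(1-p)q, pq)
  with p the paternal mutant frequency.

Every third generation a census samples 32 males per vial without
replacement (hypergeometric).  Replicating the whole protocol many times
and taking the 2.5% / 97.5% quantiles of the across-vial mean frequency
yields the 95% drift envelope — the band that trajectories must leave
before selection can be invoked.  Envelopes are computed separately for the
true population frequency and for the 32-male sample frequency, whose extra
sampling noise makes it the wider band.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_dam import DomainError, ValidationError

__all__ = [
    "VialState",
    "DriftConfig",
    "DriftEnvelope",
    "advance_generation",
    "sample_census",
    "simulate_trajectory",
    "neutral_envelopes",
]


@dataclass
class VialState:
    """Genotype counts in one vial at one generation."""

    generation: int = 0
    males_wt: int = 15
    males_mut: int = 15
    females_ww: int = 15
    females_het: int = 0
    females_mm: int = 15

    def __post_init__(self) -> None:
        counts = (self.males_wt, self.males_mut, self.females_ww,
                  self.females_het, self.females_mm)
        if any(c < 0 for c in counts):
            raise ValidationError("negative genotype counts")
        if self.generation < 0:
            raise ValidationError("generation must be >= 0")

    @property
    def males_total(self) -> int:
        return self.males_wt + self.males_mut

    @property
    def females_total(self) -> int:
        return self.females_ww + self.females_het + self.females_mm

    @property
    def extinct(self) -> bool:
        return self.males_total == 0 or self.females_total == 0

    @property
    def male_mutant_frequency(self) -> float:
        if self.males_total == 0:
            raise DomainError("no males in vial")
        return self.males_mut / self.males_total


@dataclass
class DriftConfig:
    """Protocol constants of the long-term competition assay."""

    n_vials: int = 10
    founders: int = 15          # per sex per genotype
    offspring: int = 400        # N flies per new generation
    census_every: int = 3       # generations between censuses
    sample_size: int = 32       # males genotyped per vial per census
    n_censuses: int = 20        # censuses after the founding census
    replicates: int = 100_000
    seed: int | None = None

    def __post_init__(self) -> None:
        positive = (self.n_vials, self.founders, self.offspring,
                    self.census_every, self.sample_size, self.n_censuses,
                    self.replicates)
        if any(v <= 0 for v in positive):
            raise ValidationError("all DriftConfig sizes must be positive")
        if self.sample_size > self.offspring // 2:
            raise ValidationError(
                "census sample exceeds the expected male count"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "DriftConfig":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})

    @property
    def census_generations(self) -> np.ndarray:
        """Generations at which a census happens (0, 3, 6, ...)."""
        return np.arange(self.n_censuses + 1) * self.census_every


@dataclass
class DriftEnvelope:
    """Per-census 95% quantile bands of the across-vial mean frequency."""

    censuses: np.ndarray
    pop_lo: np.ndarray
    pop_hi: np.ndarray
    samp_lo: np.ndarray
    samp_hi: np.ndarray
    level: float = 0.95

    def __post_init__(self) -> None:
        for lo, hi in ((self.pop_lo, self.pop_hi),
                       (self.samp_lo, self.samp_hi)):
            lo, hi = np.asarray(lo, float), np.asarray(hi, float)
            if np.any(lo < -1e-12) or np.any(hi > 1 + 1e-12) or np.any(lo > hi):
                raise ValidationError("envelope bounds must satisfy "
                                      "0 <= lower <= upper <= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "census": self.censuses,
            "pop_lo": self.pop_lo, "pop_hi": self.pop_hi,
            "samp_lo": self.samp_lo, "samp_hi": self.samp_hi,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DriftEnvelope":
        df = pd.read_csv(path)
        return cls(censuses=df["census"].to_numpy(),
                   pop_lo=df["pop_lo"].to_numpy(),
                   pop_hi=df["pop_hi"].to_numpy(),
                   samp_lo=df["samp_lo"].to_numpy(),
                   samp_hi=df["samp_hi"].to_numpy())


# ---------------------------------------------------------------------------
# Vectorised core: parallel vials as flat integer arrays
# ---------------------------------------------------------------------------

def _advance_arrays(mw, mm, fww, fhet, fmm, n_offspring, rng,
                    frozen=None, frozen_freq=None):
    """One neutral generation for an array of vials, in place semantics.

    ``frozen`` marks vials that lost a sex (kept at ``frozen_freq``); with
    N = 400 this is astronomically unlikely but handled for completeness.
    """
    males = mw + mm
    females = fww + fhet + fmm
    alive = (males > 0) & (females > 0)
    if frozen is not None:
        newly_dead = ~alive & ~frozen
        if newly_dead.any():
            # freeze at the nearest fixed allele of the last pool
            allele = np.zeros_like(mw, dtype=float)
            tot = 2.0 * females + males
            ok = tot > 0
            allele[ok] = ((fhet + 2 * fmm + mm)[ok]) / tot[ok]
            frozen_freq[newly_dead] = np.round(allele[newly_dead])
            frozen |= newly_dead

    p = np.where(alive, mm / np.maximum(males, 1), 0.0)
    q = np.where(alive, (fhet / 2.0 + fmm) / np.maximum(females, 1), 0.0)

    sons = rng.binomial(n_offspring, 0.5, size=mw.shape)
    sons_mut = rng.binomial(sons, q)
    daughters = n_offspring - sons
    pr_ww = (1.0 - p) * (1.0 - q)
    pr_het = p * (1.0 - q) + (1.0 - p) * q
    d_ww = rng.binomial(daughters, pr_ww)
    rest = daughters - d_ww
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(pr_ww < 1.0, pr_het / np.maximum(1.0 - pr_ww, 1e-300), 0.0)
    d_het = rng.binomial(rest, np.clip(cond, 0.0, 1.0))
    d_mm = rest - d_het

    # dead vials keep their last counts (reported via frozen_freq)
    return (
        np.where(alive, sons - sons_mut, mw),
        np.where(alive, sons_mut, mm),
        np.where(alive, d_ww, fww),
        np.where(alive, d_het, fhet),
        np.where(alive, d_mm, fmm),
    )


def _pop_freq(mw, mm, frozen=None, frozen_freq=None):
    males = mw + mm
    out = np.where(males > 0, mm / np.maximum(males, 1), 0.0)
    if frozen is not None and frozen.any():
        out = np.where(frozen, frozen_freq, out)
    return out


def _sample_arrays(mw, mm, n, rng, frozen=None, frozen_freq=None):
    males = mw + mm
    ok = males > 0
    k = np.minimum(n, males)
    drawn = np.zeros_like(mw, dtype=float)
    if ok.any():
        got = rng.hypergeometric(np.maximum(mm, 0)[ok], np.maximum(mw, 0)[ok],
                                 k[ok])
        drawn[ok] = got / k[ok]
    if frozen is not None and frozen.any():
        drawn = np.where(frozen, frozen_freq, drawn)
    return drawn


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def advance_generation(state: VialState, n_offspring: int,
                       rng: np.random.Generator) -> VialState:
    """Breed one vial forward one generation under neutrality."""
    if state.extinct:
        raise DomainError("cannot breed an extinct vial")
    arrays = tuple(np.array([v]) for v in
                   (state.males_wt, state.males_mut, state.females_ww,
                    state.females_het, state.females_mm))
    mw, mm, fww, fhet, fmm = _advance_arrays(*arrays, n_offspring, rng)
    return VialState(
        generation=state.generation + 1,
        males_wt=int(mw[0]), males_mut=int(mm[0]),
        females_ww=int(fww[0]), females_het=int(fhet[0]),
        females_mm=int(fmm[0]),
    )


def sample_census(state: VialState, n: int = 32,
                  rng: np.random.Generator | None = None) -> int:
    """Draw min(n, males) males without replacement; return the mutant count.

    The censused males come from extra late-hatching flies, so sampling
    leaves the breeding state untouched.
    """
    if state.males_total == 0:
        raise DomainError("no males to census")
    rng = np.random.default_rng() if rng is None else rng
    k = min(n, state.males_total)
    return int(rng.hypergeometric(state.males_mut, state.males_wt, k))


def simulate_trajectory(config: DriftConfig,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one replicate of the protocol across all vials.

    Returns ``(pop_freq, samp_freq)`` with shape
    ``(n_censuses + 1, n_vials)``; census 0 is the founding population
    (frequency exactly 1/2 by construction).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pop, samp = _simulate_batch(config, n_replicates=1, rng=rng)
    return pop[0], samp[0]


def _simulate_batch(config: DriftConfig, n_replicates: int,
                    rng: np.random.Generator,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised replicates: arrays (R, n_censuses + 1, n_vials)."""
    shape = (n_replicates, config.n_vials)
    f = config.founders
    mw = np.full(shape, f, dtype=np.int64)
    mm = np.full(shape, f, dtype=np.int64)
    fww = np.full(shape, f, dtype=np.int64)
    fhet = np.zeros(shape, dtype=np.int64)
    fmm = np.full(shape, f, dtype=np.int64)
    frozen = np.zeros(shape, dtype=bool)
    frozen_freq = np.zeros(shape, dtype=float)

    n_c = config.n_censuses
    pop = np.empty((n_replicates, n_c + 1, config.n_vials))
    samp = np.empty_like(pop)
    pop[:, 0] = _pop_freq(mw, mm)
    samp[:, 0] = _sample_arrays(mw, mm, config.sample_size, rng)

    for ci in range(1, n_c + 1):
        for _ in range(config.census_every):
            mw, mm, fww, fhet, fmm = _advance_arrays(
                mw, mm, fww, fhet, fmm, config.offspring, rng,
                frozen=frozen, frozen_freq=frozen_freq)
        pop[:, ci] = _pop_freq(mw, mm, frozen, frozen_freq)
        samp[:, ci] = _sample_arrays(mw, mm, config.sample_size, rng,
                                     frozen, frozen_freq)
    return pop, samp


def neutral_envelopes(config: DriftConfig,
                      rng: np.random.Generator | None = None,
                      batch_size: int = 20_000) -> DriftEnvelope:
    """Monte-Carlo 95% envelopes of the across-vial mean mutant frequency.

    Runs ``config.replicates`` independent protocol replicates (in
    vectorised batches from one seeded generator) and takes the empirical
    2.5% / 97.5% quantiles per census, separately for the population
    frequency and the 32-male sample frequency.
    """
    if config.replicates < 1000:
        raise DomainError("need at least 1000 replicates for stable quantiles")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pop_means = []
    samp_means = []
    left = config.replicates
    while left > 0:
        b = min(batch_size, left)
        pop, samp = _simulate_batch(config, b, rng)
        pop_means.append(pop.mean(axis=2))    # across-vial mean, (b, C+1)
        samp_means.append(samp.mean(axis=2))
        left -= b
    pop_m = np.concatenate(pop_means)
    samp_m = np.concatenate(samp_means)
    qs = [(1 - 0.95) / 2, 1 - (1 - 0.95) / 2]
    pop_lo, pop_hi = np.quantile(pop_m, qs, axis=0)
    samp_lo, samp_hi = np.quantile(samp_m, qs, axis=0)
    return DriftEnvelope(
        censuses=np.arange(config.n_censuses + 1),
        pop_lo=pop_lo, pop_hi=pop_hi,
        samp_lo=samp_lo, samp_hi=samp_hi,
    )
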