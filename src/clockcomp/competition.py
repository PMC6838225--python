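"""Mutant-frequency trajectories from census genotype calls.

Each census genotypes up to 32 males per vial from their free-running
behaviour.  This module turns those calls into per-vial mutant frequencies
and an unweighted across-vial mean trajectory, compares the mean against
neutral drift envelopes, and provides the exact binomial interval used for
single-census proportion plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chronotype import GENOTYPE_CLASSES, GenotypeCall
from .drift_null import DriftEnvelope
from .fitness_assays import exact_binomial_ci
from .io_dam import DomainError, ValidationError, log

__all__ = [
    "CensusRecord",
    "FrequencyTrajectory",
    "census_frequencies",
    "envelope_flags",
    "proportion_with_ci",
    "plot_overlay",
]


@dataclass
class CensusRecord:
    """Genotype calls for the males sampled from one vial at one census."""

    experiment: str
    vial: str
    census: int
    calls: list[GenotypeCall]

    def __post_init__(self) -> None:
        if self.census < 0:
            raise ValidationError("census index must be >= 0")
        if len(self.calls) > 32:
            raise ValidationError("at most 32 sampled males per vial-census")


@dataclass
class FrequencyTrajectory:
    """Per-vial and mean mutant frequencies per census."""

    censuses: np.ndarray                 # sorted census indices
    vials: list[str]
    vial_freq: np.ndarray                # (n_censuses, n_vials), NaN = absent
    mean: np.ndarray                     # unweighted across-vial mean
    n_vials: np.ndarray                  # vials contributing per census

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.vial_freq, columns=self.vials)
        df.insert(0, "census", self.censuses)
        df["mean"] = self.mean
        df["n_vials"] = self.n_vials
        return df


def census_frequencies(records: Iterable[CensusRecord],
                       mutant_classes: Sequence[str] = ("short", "long",
                                                        "arrhythmic"),
                       drop_lost: bool = False) -> FrequencyTrajectory:
    """Per-vial mutant frequency and its unweighted across-vial mean.

    ``mutant_classes`` names the genotype classes counted as mutant (in a
    real experiment a single class: the competing mutant; the wildtype is
    always ``wildtype_like``).  Vial-censuses without calls are excluded
    with a warning.  Vials where the mutant has (apparently) vanished stay
    in the mean at frequency 0 by default; ``drop_lost`` instead removes
    zero-frequency vials from the mean — a census of 32 males cannot prove
    the mutant is truly gone, so both conventions are offered.
    """
    bad = set(mutant_classes) - set(GENOTYPE_CLASSES)
    if bad:
        raise ValidationError(f"unknown mutant classes {sorted(bad)}")
    recs = list(records)
    if not recs:
        raise DomainError("no census records")
    censuses = sorted({r.census for r in recs})
    vials = sorted({(r.experiment, r.vial) for r in recs})
    freq = np.full((len(censuses), len(vials)), np.nan)
    c_index = {c: i for i, c in enumerate(censuses)}
    v_index = {v: j for j, v in enumerate(vials)}
    for r in recs:
        if not r.calls:
            log.warning("vial %s census %d has no calls; excluded",
                        r.vial, r.census)
            continue
        k = sum(c.genotype_class in mutant_classes for c in r.calls)
        freq[c_index[r.census], v_index[(r.experiment, r.vial)]] = (
            k / len(r.calls))
    work = np.where(drop_lost & (freq == 0.0), np.nan, freq)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(work, axis=1)
    n_vials = np.sum(~np.isnan(work), axis=1)
    return FrequencyTrajectory(
        censuses=np.asarray(censuses),
        vials=[f"{e}:{v}" for e, v in vials],
        vial_freq=freq,
        mean=mean,
        n_vials=n_vials,
    )


def envelope_flags(trajectory: FrequencyTrajectory,
                   envelope: DriftEnvelope,
                   band: str = "sample") -> np.ndarray:
    """Flag censuses where the mean trajectory leaves the drift envelope.

    ``band`` selects the 32-male sample envelope (the right comparison for
    censused frequencies) or the population envelope.  Censuses must align
    exactly between trajectory and envelope.
    """
    if band not in ("sample", "population"):
        raise DomainError("band must be 'sample' or 'population'")
    env_index = {int(c): i for i, c in enumerate(envelope.censuses)}
    missing = [int(c) for c in trajectory.censuses if int(c) not in env_index]
    if missing:
        raise DomainError(f"envelope lacks censuses {missing}")
    idx = [env_index[int(c)] for c in trajectory.censuses]
    lo = (envelope.samp_lo if band == "sample" else envelope.pop_lo)[idx]
    hi = (envelope.samp_hi if band == "sample" else envelope.pop_hi)[idx]
    m = trajectory.mean
    return (m < lo) | (m > hi)


def proportion_with_ci(mutant: int, total: int,
                       ) -> tuple[float, tuple[float, float]]:
    """Mutant proportion at one census with its exact binomial 95% CI."""
    if total < 1:
        raise DomainError("need at least one sampled male")
    if not 0 <= mutant <= total:
        raise DomainError("mutant count outside [0, total]")
    return mutant / total, exact_binomial_ci(mutant, total)


def plot_overlay(trajectory: FrequencyTrajectory,
                 envelope: DriftEnvelope | None,
                 path: str | Path,
                 title: str = "") -> None:
    """Per-vial trajectories, their mean, and the drift envelopes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for j, name in enumerate(trajectory.vials):
        ax.plot(trajectory.censuses, trajectory.vial_freq[:, j],
                lw=0.8, alpha=0.6, label=None)
    ax.plot(trajectory.censuses, trajectory.mean, "k-", lw=2.2, label="mean")
    if envelope is not None:
        ax.plot(envelope.censuses, envelope.pop_lo, "--", color="gray",
                label="population 95%")
        ax.plot(envelope.censuses, envelope.pop_hi, "--", color="gray")
        ax.plot(envelope.censuses, envelope.samp_lo, "--", color="black",
                lw=1.0, label="32-male sample 95%")
        ax.plot(envelope.censuses, envelope.samp_hi, "--", color="black",
                lw=1.0)
    ax.set_xlabel("census")
    ax.set_ylabel("mutant male frequency")
    ax.set_ylim(-0.02, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
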