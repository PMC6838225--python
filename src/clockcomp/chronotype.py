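"""Rhythmicity testing and genotype calling from locomotor activity.

The free-running period of a fly in constant darkness identifies its clock
genotype: because the clock locus sits on the X chromosome, a male's single
allele is read directly from its behaviour (short period, ~24 h, long
period, or arrhythmic).  Period estimation uses the chi-square periodogram:
for a candidate period ``P`` the recording is folded into ``K`` complete
cycles of ``B`` phase bins and the statistic

    Q_P = N * K * sum_h (M_h - Mbar)^2 / sum_i (x_i - Mbar)^2

is compared against the chi-square quantile with ``B - 1`` degrees of
freedom (M_h are the phase-bin means over cycles, Mbar the grand mean and
N = K*B the number of points used).  Under a flat null Q_P is approximately
chi-square distributed; a peak exceeding the 5% quantile marks the fly
rhythmic at that period.

Candidate periods need not be whole multiples of the recording bin: points
are assigned to the ``B`` phase bins by their bin-midpoint phase, which
reduces to the exact K x B folding whenever P is an integer number of bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_dam import ActivitySeries, DomainError, ValidationError

__all__ = [
    "GENOTYPE_CLASSES",
    "PeriodogramResult",
    "GenotypeCall",
    "AverageProfile",
    "fold_qp",
    "chi_square_periodogram",
    "classify_genotype",
    "average_profile",
    "morning_activity",
]

GENOTYPE_CLASSES = ("short", "wildtype_like", "long", "arrhythmic")

#: class boundaries in hours: rhythmic flies with tau below SHORT_MAX are
#: "short", above LONG_MIN "long", in between "wildtype_like".  Chosen to
#: separate the three rhythmic genotype means (19.0 / 24.3 / 27.6 h) with a
#: margin of at least 1.6 h on either side.
SHORT_MAX = 22.0
LONG_MIN = 26.0

DEFAULT_GRID = np.round(np.arange(14.0, 35.0 + 1e-9, 0.1), 10)
PERIODOGRAM_BIN = 10  # minutes; aggregated from 1-min acquisition


@dataclass
class PeriodogramResult:
    """Chi-square periodogram spectrum with its significance line."""

    fly_id: str
    periods: np.ndarray           # hours, strictly increasing
    qp: np.ndarray                # statistic per period, >= 0
    threshold: np.ndarray         # chi-square quantile per period
    df: np.ndarray                # degrees of freedom per period
    peak_period: float            # hours
    peak_qp: float
    rhythmic: bool
    level: float = 0.05


@dataclass(frozen=True)
class GenotypeCall:
    fly_id: str
    genotype_class: str
    tau: float | None  # hours; None iff arrhythmic

    def __post_init__(self) -> None:
        if self.genotype_class not in GENOTYPE_CLASSES:
            raise ValidationError(
                f"unknown genotype class {self.genotype_class!r}"
            )
        if (self.tau is None) != (self.genotype_class == "arrhythmic"):
            raise ValidationError("tau must be absent iff arrhythmic")


@dataclass
class AverageProfile:
    """Mean activity per Zeitgeber-time bin over days, then over flies."""

    zt: np.ndarray        # bin start times in hours, ZT0 = lights-on
    mean: np.ndarray      # counts per bin
    sem: np.ndarray       # across-fly standard error
    bin_width: int        # minutes
    T: float              # cycle length, hours
    n_flies: int
    n_days: int


def _qp_statistic(counts: np.ndarray, bin_width: int, period: float,
                  ) -> tuple[float, int]:
    total_min = len(counts) * bin_width
    p_min = period * 60.0
    k = int(total_min // p_min)
    if k < 2:
        raise DomainError(
            f"need >= 2 complete cycles of {period} h, have {total_min / 60:.1f} h"
        )
    b = max(2, int(round(p_min / bin_width)))
    used = int(np.floor(k * p_min / bin_width))
    x = np.asarray(counts[:used], dtype=float)
    grand = x.mean()
    ss = float(((x - grand) ** 2).sum())
    if ss == 0.0:
        return 0.0, b - 1
    t = (np.arange(used) + 0.5) * bin_width
    h = np.minimum((np.mod(t, p_min) / p_min * b).astype(np.intp), b - 1)
    occ = np.bincount(h, minlength=b).astype(float)
    sums = np.bincount(h, weights=x, minlength=b)
    valid = occ > 0
    m = sums[valid] / occ[valid]
    between = float((occ[valid] * (m - grand) ** 2).sum())
    qp = used * between / ss
    return qp, int(valid.sum()) - 1


def fold_qp(series: ActivitySeries, period: float) -> tuple[float, int]:
    """Fold a constant-condition recording at ``period`` hours.

    Returns the chi-square periodogram statistic and its degrees of
    freedom.  The series should already be restricted to a single DD or LL
    segment (see :meth:`ActivitySeries.segment`); any incomplete trailing
    cycle is discarded.  A zero-variance series yields Q_P = 0.
    """
    if period <= 0:
        raise DomainError("test period must be positive")
    return _qp_statistic(series.counts, series.bin_width, period)


def chi_square_periodogram(series: ActivitySeries,
                           grid: Sequence[float] | None = None,
                           level: float = 0.05,
                           bin_width: int = PERIODOGRAM_BIN,
                           ) -> PeriodogramResult:
    """Scan a period grid and call rhythmicity at significance ``level``.

    The peak is the grid point maximising the excess of Q_P over its
    chi-square threshold; the fly is rhythmic iff that excess is positive
    (p <= level at the peak).  Ties break toward the shorter period.
    """
    grid_arr = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid_arr.size == 0:
        raise DomainError("empty period grid")
    if np.any(np.diff(grid_arr) <= 0):
        raise DomainError("period grid must be strictly increasing")
    work = series.rebin(bin_width) if bin_width > series.bin_width else series

    qp = np.empty(grid_arr.size)
    df = np.empty(grid_arr.size, dtype=int)
    for i, p in enumerate(grid_arr):
        qp[i], df[i] = _qp_statistic(work.counts, work.bin_width, p)
    threshold = stats.chi2.ppf(1.0 - level, df)
    excess = qp - threshold
    peak = int(np.argmax(excess))  # first max = shortest period
    return PeriodogramResult(
        fly_id=series.fly_id,
        periods=grid_arr,
        qp=qp,
        threshold=threshold,
        df=df,
        peak_period=float(grid_arr[peak]),
        peak_qp=float(qp[peak]),
        rhythmic=bool(excess[peak] > 0),
        level=level,
    )


def classify_genotype(result: PeriodogramResult,
                      short_max: float = SHORT_MAX,
                      long_min: float = LONG_MIN) -> GenotypeCall:
    """Map a periodogram result to a genotype class.

    Non-rhythmic flies are arrhythmic; rhythmic flies are classed by their
    peak period against the ``short_max`` / ``long_min`` boundaries.
    """
    if not result.rhythmic:
        return GenotypeCall(result.fly_id, "arrhythmic", None)
    tau = result.peak_period
    if tau < short_max:
        cls = "short"
    elif tau <= long_min:
        cls = "wildtype_like"
    else:
        cls = "long"
    return GenotypeCall(result.fly_id, cls, tau)


def _fly_profile(series: ActivitySeries) -> tuple[np.ndarray, int]:
    """Per-ZT-bin mean over complete LD cycles for one fly."""
    seg, _, _ = series.regime.first_segment("LD")
    sub = series.segment("LD")
    bins_per_cycle = seg.T * 60.0 / sub.bin_width
    if abs(bins_per_cycle - round(bins_per_cycle)) > 1e-9:
        raise DomainError(
            f"cycle length {seg.T} h is not a whole number of "
            f"{sub.bin_width}-min bins"
        )
    bpc = int(round(bins_per_cycle))
    n_days = sub.n_bins // bpc
    if n_days < 1:
        raise DomainError("need at least one complete LD cycle")
    folded = sub.counts[:n_days * bpc].reshape(n_days, bpc)
    return folded.mean(axis=0), n_days


def average_profile(series_list: Sequence[ActivitySeries]) -> AverageProfile:
    """Average activity profile over days, then over flies (ZT0 = lights-on)."""
    if not series_list:
        raise DomainError("no series given")
    segs = [s.regime.first_segment("LD")[0] for s in series_list]
    t0, lf0 = segs[0].T, segs[0].light_fraction
    bw0 = series_list[0].bin_width
    for seg, s in zip(segs, series_list):
        if seg.T != t0 or seg.light_fraction != lf0 or s.bin_width != bw0:
            raise DomainError("series differ in cycle length, light fraction "
                              "or bin width")
    profiles, days = zip(*(_fly_profile(s) for s in series_list))
    mat = np.vstack(profiles)
    n = mat.shape[0]
    sem = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(mat.shape[1])
    return AverageProfile(
        zt=np.arange(mat.shape[1]) * bw0 / 60.0,
        mean=mat.mean(axis=0),
        sem=sem,
        bin_width=bw0,
        T=t0,
        n_flies=n,
        n_days=int(min(days)),
    )


def morning_activity(source: AverageProfile | ActivitySeries,
                     window: tuple[float, float] = (0.0, 3.0)) -> float:
    """Total beam crosses in the early-day window ZT in [window) per cycle.

    Accepts an averaged profile or a single fly's LD recording (averaged
    over its days first).  The default window is the first 3 h after
    lights-on, the interval in which the morning activity bout of the
    genotypes differs most.
    """
    if isinstance(source, ActivitySeries):
        profile, _ = _fly_profile(source)
        seg, _, _ = source.regime.first_segment("LD")
        zt = np.arange(len(profile)) * source.bin_width / 60.0
        cycle_t = seg.T
    else:
        profile, zt, cycle_t = source.mean, source.zt, source.T
    lo, hi = window
    if hi > cycle_t or lo < 0 or hi <= lo:
        raise DomainError(f"window {window} does not fit a {cycle_t} h cycle")
    sel = (zt >= lo) & (zt < hi)
    return float(profile[sel].sum())
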