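"""Monitor-file and table I/O for the competition pipeline.

Reads and writes the text files produced by infrared beam-cross activity
monitors (one file per 32-channel monitor), the pipeline's CSV tables
(census genotype calls, mating trials, survival assays), and the TOML run
configuration.  Also owns the shared exception hierarchy and logging setup.

The monitor dialect is tab-separated with the fields::

    record_index <TAB> date "d Mon yy" <TAB> time "HH:MM:SS" <TAB> status
    <TAB> count_1 ... count_32

Dates use fixed English month abbreviations so parsing never depends on the
process locale.  The bin width is inferred from consecutive timestamps and
must be a positive whole-minute divisor of 60; files mixing bin widths are
rejected.
"""

from __future__ import annotations

import csv
import logging
import math
import sys
import tomllib
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ClockCompError",
    "DomainError",
    "ParseError",
    "FormatError",
    "ValidationError",
    "LightSegment",
    "LightRegime",
    "ActivitySeries",
    "ld_regime",
    "dd_regime",
    "ll_regime",
    "read_dam",
    "write_dam",
    "read_census_csv",
    "write_census_csv",
    "read_trials_csv",
    "write_trials_csv",
    "read_survival_csv",
    "write_survival_csv",
    "load_config",
    "configure_logging",
]

log = logging.getLogger("clockcomp")


def configure_logging(level: int = logging.INFO) -> None:
    """Send package log lines to standard error with a level prefix."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s: %(message)s"))
    root = logging.getLogger("clockcomp")
    root.handlers[:] = [handler]
    root.setLevel(level)


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class ClockCompError(Exception):
    """Base class for pipeline errors."""


class DomainError(ClockCompError, ValueError):
    """An operation was called outside its mathematical domain."""


class ParseError(ClockCompError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class FormatError(ClockCompError, ValueError):
    """A file parsed but violates the dialect (e.g. non-monotone times)."""


class ValidationError(ClockCompError, ValueError):
    """An in-memory object violates its invariants."""


# ---------------------------------------------------------------------------
# Light regimes and activity series
# ---------------------------------------------------------------------------

_MODES = ("LD", "DD", "LL")


@dataclass(frozen=True)
class LightSegment:
    """One stretch of a lighting schedule.

    mode
        ``"LD"`` (light/dark cycles), ``"DD"`` (constant darkness) or
        ``"LL"`` (constant light).
    T
        Cycle length in hours; meaningful for LD only (a 19-h day is
        LD 9.5:9.5, i.e. ``T=19, light_fraction=0.5``).
    light_fraction
        Fraction of the cycle that is lit, in (0, 1) for LD.  DD and LL
        carry the conventional values 0 and 1.
    duration_bins
        Segment length in whole recording bins.
    """

    mode: str
    duration_bins: int
    T: float = 24.0
    light_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValidationError(f"unknown regime mode {self.mode!r}")
        if self.duration_bins < 0:
            raise ValidationError("segment duration must be >= 0 bins")
        if self.mode == "LD":
            if not self.T > 0:
                raise ValidationError("LD segment needs cycle length T > 0")
            if not 0.0 < self.light_fraction < 1.0:
                raise ValidationError("LD light fraction must lie in (0, 1)")
        elif self.mode == "DD":
            object.__setattr__(self, "light_fraction", 0.0)
        else:  # LL
            object.__setattr__(self, "light_fraction", 1.0)


@dataclass(frozen=True)
class LightRegime:
    """An ordered sequence of light segments covering a recording."""

    segments: tuple[LightSegment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def total_bins(self) -> int:
        return sum(s.duration_bins for s in self.segments)

    def segment_slices(self) -> list[tuple[LightSegment, int, int]]:
        """Return (segment, start_bin, stop_bin) triples."""
        out, pos = [], 0
        for seg in self.segments:
            out.append((seg, pos, pos + seg.duration_bins))
            pos += seg.duration_bins
        return out

    def first_segment(self, *modes: str) -> tuple[LightSegment, int, int]:
        for seg, a, b in self.segment_slices():
            if seg.mode in modes:
                return seg, a, b
        raise DomainError(f"regime has no segment of mode {modes}")

    def light_mask(self, bin_width: int) -> np.ndarray:
        """Boolean light/dark flag per bin (bin midpoints, ZT0 = lights-on)."""
        mask = np.zeros(self.total_bins, dtype=bool)
        for seg, a, b in self.segment_slices():
            if seg.mode == "LL":
                mask[a:b] = True
            elif seg.mode == "LD":
                t = (np.arange(b - a) + 0.5) * bin_width / 60.0
                zt = np.mod(t, seg.T)
                mask[a:b] = zt < seg.T * seg.light_fraction
        return mask


def ld_regime(days: float, T: float = 24.0, bin_width: int = 1,
              light_fraction: float = 0.5) -> LightRegime:
    """A single LD segment spanning ``days`` cycles of length ``T`` hours."""
    bins = int(round(days * T * 60.0 / bin_width))
    return LightRegime((LightSegment("LD", bins, T, light_fraction),))


def dd_regime(days: float, bin_width: int = 1) -> LightRegime:
    """Constant darkness for ``days`` 24-h days."""
    bins = int(round(days * 24.0 * 60.0 / bin_width))
    return LightRegime((LightSegment("DD", bins),))


def ll_regime(days: float, bin_width: int = 1) -> LightRegime:
    """Constant light for ``days`` 24-h days."""
    bins = int(round(days * 24.0 * 60.0 / bin_width))
    return LightRegime((LightSegment("LL", bins),))


@dataclass
class ActivitySeries:
    """Binned beam-cross counts for one fly plus its lighting schedule."""

    fly_id: str
    bin_width: int  # minutes; positive divisor of 60
    start: datetime
    counts: np.ndarray
    regime: LightRegime

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValidationError("counts must be one-dimensional")
        if self.bin_width <= 0 or 60 % self.bin_width != 0:
            raise ValidationError(
                f"bin width {self.bin_width} must be a positive divisor of 60"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative activity counts")
        if self.regime.total_bins != len(self.counts):
            raise ValidationError(
                f"regime covers {self.regime.total_bins} bins but series has "
                f"{len(self.counts)}"
            )

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def segment(self, *modes: str) -> "ActivitySeries":
        """Restrict the series to its first segment of one of ``modes``."""
        seg, a, b = self.regime.first_segment(*modes)
        return ActivitySeries(
            fly_id=self.fly_id,
            bin_width=self.bin_width,
            start=self.start + timedelta(minutes=a * self.bin_width),
            counts=self.counts[a:b],
            regime=LightRegime((seg,)),
        )

    def rebin(self, bin_width: int) -> "ActivitySeries":
        """Aggregate counts into wider bins (e.g. 1-min acquisition → 10-min).

        Trailing bins that do not fill a whole new bin are discarded;
        segment boundaries must fall on the new bin grid.
        """
        if bin_width == self.bin_width:
            return self
        if bin_width % self.bin_width != 0:
            raise DomainError(
                f"cannot rebin {self.bin_width}-min data to {bin_width} min"
            )
        f = bin_width // self.bin_width
        segs = []
        chunks = []
        for seg, a, b in self.regime.segment_slices():
            n_new = (b - a) // f
            chunk = self.counts[a:a + n_new * f].reshape(n_new, f).sum(axis=1)
            chunks.append(chunk)
            segs.append(replace(seg, duration_bins=n_new))
        return ActivitySeries(
            fly_id=self.fly_id,
            bin_width=bin_width,
            start=self.start,
            counts=np.concatenate(chunks) if chunks else np.zeros(0, int),
            regime=LightRegime(tuple(segs)),
        )


# ---------------------------------------------------------------------------
# Monitor files
# ---------------------------------------------------------------------------

N_CHANNELS = 32
_N_META_FIELDS = 4  # record index, date, time, status

_MONTHS = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
           "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")
_MONTH_NUM = {m: i + 1 for i, m in enumerate(_MONTHS)}


def _parse_timestamp(date_s: str, time_s: str, lineno: int) -> datetime:
    try:
        day_s, mon_s, year_s = date_s.split()
        hh, mm, ss = time_s.split(":")
        return datetime(2000 + int(year_s), _MONTH_NUM[mon_s], int(day_s),
                        int(hh), int(mm), int(ss))
    except (ValueError, KeyError) as exc:
        raise ParseError(
            f"line {lineno}: bad timestamp {date_s!r} {time_s!r}"
        ) from exc


def _format_timestamp(ts: datetime) -> tuple[str, str]:
    date_s = f"{ts.day} {_MONTHS[ts.month - 1]} {ts.year % 100:02d}"
    return date_s, ts.strftime("%H:%M:%S")


def read_dam(path: str | Path, regime: LightRegime | None = None,
             ) -> list[ActivitySeries]:
    """Read a 32-channel monitor file into one ActivitySeries per channel.

    The bin width is inferred from consecutive timestamps.  Monitor files
    carry no lighting schedule; pass ``regime`` to attach one, otherwise a
    single DD segment spanning the recording is assumed.
    """
    path = Path(path)
    timestamps: list[datetime] = []
    rows: list[list[int]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != _N_META_FIELDS + N_CHANNELS:
                raise ParseError(
                    f"line {lineno}: expected {_N_META_FIELDS + N_CHANNELS} "
                    f"tab-separated fields, found {len(fields)}"
                )
            ts = _parse_timestamp(fields[1], fields[2], lineno)
            try:
                counts = [int(v) for v in fields[_N_META_FIELDS:]]
            except ValueError as exc:
                raise ParseError(
                    f"line {lineno}: non-integer count field"
                ) from exc
            if any(c < 0 for c in counts):
                raise ParseError(f"line {lineno}: negative count")
            timestamps.append(ts)
            rows.append(counts)

    n = len(rows)
    if n >= 2:
        deltas = {
            (b - a).total_seconds() for a, b in zip(timestamps, timestamps[1:])
        }
        if len(deltas) != 1:
            raise FormatError("mixed or non-uniform bin widths in monitor file")
        delta = deltas.pop()
        if delta <= 0:
            raise FormatError("non-monotone timestamps in monitor file")
        if delta % 60 != 0 or 60 % int(delta // 60) != 0:
            raise FormatError(
                f"bin width {delta} s is not a whole-minute divisor of 60 min"
            )
        bin_width = int(delta // 60)
    else:
        bin_width = 1

    start = timestamps[0] if timestamps else datetime(2000, 1, 1)
    if regime is None:
        regime = LightRegime((LightSegment("DD", n),))
    data = np.asarray(rows, dtype=np.int64).reshape(n, N_CHANNELS)
    return [
        ActivitySeries(
            fly_id=f"{path.stem}#{ch + 1:02d}",
            bin_width=bin_width,
            start=start,
            counts=data[:, ch],
            regime=regime,
        )
        for ch in range(N_CHANNELS)
    ]


def write_dam(series: Sequence[ActivitySeries], path: str | Path) -> None:
    """Write 32 equal-shape series back to the monitor dialect."""
    if len(series) != N_CHANNELS:
        raise ValidationError(f"need exactly {N_CHANNELS} series")
    first = series[0]
    for s in series[1:]:
        if (s.bin_width != first.bin_width or s.start != first.start
                or s.n_bins != first.n_bins):
            raise ValidationError("series differ in bin width, start or length")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for i in range(first.n_bins):
            ts = first.start + timedelta(minutes=i * first.bin_width)
            date_s, time_s = _format_timestamp(ts)
            counts = "\t".join(str(int(s.counts[i])) for s in series)
            fh.write(f"{i + 1}\t{date_s}\t{time_s}\t1\t{counts}\n")


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

_CENSUS_COLUMNS = ["experiment", "vial", "census", "fly_id", "class", "tau"]


def write_census_csv(records: Iterable, path: str | Path) -> None:
    """Write census genotype calls, one row per sampled male."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CENSUS_COLUMNS)
        for rec in records:
            for call in rec.calls:
                tau = "" if call.tau is None else repr(float(call.tau))
                w.writerow([rec.experiment, rec.vial, rec.census,
                            call.fly_id, call.genotype_class, tau])


def read_census_csv(path: str | Path) -> list:
    """Read census genotype calls back into CensusRecord objects."""
    from .chronotype import GENOTYPE_CLASSES, GenotypeCall
    from .competition import CensusRecord

    groups: dict[tuple[str, str, int], list[GenotypeCall]] = {}
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _CENSUS_COLUMNS:
            raise ParseError(
                f"census CSV must have columns {_CENSUS_COLUMNS}, "
                f"found {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            cls = row["class"]
            if cls not in GENOTYPE_CLASSES:
                raise ValidationError(
                    f"line {lineno}: unknown genotype class {cls!r}"
                )
            tau = None if row["tau"] == "" else float(row["tau"])
            key = (row["experiment"], row["vial"], int(row["census"]))
            groups.setdefault(key, []).append(
                GenotypeCall(fly_id=row["fly_id"], genotype_class=cls, tau=tau)
            )
    return [
        CensusRecord(experiment=e, vial=v, census=c, calls=calls)
        for (e, v, c), calls in sorted(groups.items())
    ]


_TRIAL_COLUMNS = ["female_genotype", "male_mutant", "arm",
                  "trials", "matings", "chose_mutant"]


def write_trials_csv(trials: Iterable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_TRIAL_COLUMNS)
        for t in trials:
            w.writerow([t.female_genotype, t.male_genotype, t.arm,
                        t.trials, t.matings, t.chose_mutant])


def read_trials_csv(path: str | Path) -> list:
    from .preference import MatingTrialSet

    out = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _TRIAL_COLUMNS:
            raise ParseError(
                f"trials CSV must have columns {_TRIAL_COLUMNS}, "
                f"found {reader.fieldnames}"
            )
        for row in reader:
            out.append(MatingTrialSet(
                female_genotype=row["female_genotype"],
                male_genotype=row["male_mutant"],
                arm=row["arm"],
                trials=int(row["trials"]),
                matings=int(row["matings"]),
                chose_mutant=int(row["chose_mutant"]),
            ))
    return out


_SURVIVAL_COLUMNS = ["genotype", "vial", "eggs", "pupae", "adults"]


def write_survival_csv(assays: Iterable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_SURVIVAL_COLUMNS)
        for assay in assays:
            for i, (e, p, a) in enumerate(
                    zip(assay.eggs, assay.pupae, assay.adults), start=1):
                w.writerow([assay.genotype, i, e, p, a])


def read_survival_csv(path: str | Path) -> list:
    from .fitness_assays import SurvivalAssay

    groups: dict[str, list[tuple[int, int, int]]] = {}
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _SURVIVAL_COLUMNS:
            raise ParseError(
                f"survival CSV must have columns {_SURVIVAL_COLUMNS}, "
                f"found {reader.fieldnames}"
            )
        for row in reader:
            groups.setdefault(row["genotype"], []).append(
                (int(row["eggs"]), int(row["pupae"]), int(row["adults"]))
            )
    out = []
    for genotype, rows in groups.items():
        eggs, pupae, adults = (list(col) for col in zip(*rows))
        out.append(SurvivalAssay(genotype=genotype, eggs=eggs,
                                 pupae=pupae, adults=adults))
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a TOML run configuration.

    Recognised tables are ``[drift]`` (keys of DriftConfig), ``[chronotype]``
    (grid and class boundaries) and ``[synthetic]``; unknown tables pass
    through untouched so callers can extend the schema.
    """
    with Path(path).open("rb") as fh:
        return tomllib.load(fh)
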