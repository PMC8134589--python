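"""Annual-series data model and table I/O.

Everything downstream operates on contiguous annual records: cumulative
anthropogenic emissions C_E(t), atmospheric CO2 C_A(t), global-mean
temperature anomaly T_A(t), the component emission fluxes F_FF and F_LUC,
and internal-variability residuals.  This module owns the container
(:class:`AnnualSeries`), the ppm <-> GtC conversion through the airborne
mass factor m = 2.12 GtC per ppm, cumulative integration of emission
fluxes, anomaly baselining, low-pass smoothing, nearest-year resampling of
irregular (e.g. ice-core) records, and the delimited-table format
``year,value[,sigma]`` used for all file exchange.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

#: Mass of carbon in the atmosphere per ppm of CO2 (GtC ppm^-1).
M_GTC_PER_PPM: float = 2.12

#: Legal units for each series kind.
_KIND_UNITS = {
    "co2_concentration": {"ppm", "GtC"},
    "cumulative_emission": {"GtC", "ppm"},
    "emission_flux": {"GtC_per_yr"},
    "temperature_anomaly": {"K"},
    "carbon_storage": {"GtC"},
    "residual": {"K"},
}

_CARBON_UNITS = {"ppm", "GtC"}


class UnitsError(ValueError):
    """Raised for an illegal units/kind combination or conversion."""


class AlignmentError(ValueError):
    """Raised when year ranges cannot be reconciled."""


@dataclass(frozen=True)
class AnnualSeries:
    """A contiguous annual record.

    Parameters
    ----------
    years : array-like of int
        Calendar years, strictly increasing with step 1.
    values : array-like of float
        One value per year.
    units : str
        One of ``ppm``, ``GtC``, ``GtC_per_yr``, ``K``.
    kind : str
        One of ``co2_concentration``, ``cumulative_emission``,
        ``emission_flux``, ``temperature_anomaly``, ``carbon_storage``,
        ``residual``.
    """

    years: np.ndarray
    values: np.ndarray
    units: str
    kind: str

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.ndim != 1 or values.ndim != 1:
            raise ValueError("years and values must be 1-D")
        if len(years) != len(values):
            raise ValueError("years and values must have equal length")
        if len(years) < 2:
            raise ValueError("an annual series needs at least 2 years")
        if not np.all(np.diff(years) == 1):
            raise AlignmentError("years must be contiguous with step 1")
        if self.kind not in _KIND_UNITS:
            raise UnitsError(f"unknown series kind {self.kind!r}")
        if self.units not in _KIND_UNITS[self.kind]:
            raise UnitsError(
                f"units {self.units!r} illegal for kind {self.kind!r}"
            )

    def __len__(self) -> int:
        return len(self.years)

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])

    def value_at(self, year: int) -> float:
        """Value in the given calendar year."""
        idx = int(year) - self.start_year
        if idx < 0 or idx >= len(self):
            raise AlignmentError(f"year {year} outside {self.start_year}-{self.end_year}")
        return float(self.values[idx])

    def window(self, start_year: int, end_year: int) -> "AnnualSeries":
        """Sub-series covering [start_year, end_year] inclusive."""
        if start_year < self.start_year or end_year > self.end_year:
            raise AlignmentError(
                f"window {start_year}-{end_year} outside {self.start_year}-{self.end_year}"
            )
        i0 = start_year - self.start_year
        i1 = end_year - self.start_year + 1
        return replace(self, years=self.years[i0:i1], values=self.values[i0:i1])

    def with_values(self, values: np.ndarray, units: str | None = None,
                    kind: str | None = None) -> "AnnualSeries":
        return AnnualSeries(self.years, values,
                            units or self.units, kind or self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "value": self.values})


@dataclass(frozen=True)
class CarbonUnitConstant:
    """The ppm -> GtC conversion factor for atmospheric CO2."""

    m: float = M_GTC_PER_PPM

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("conversion factor must be positive")


@dataclass(frozen=True)
class EmissionRecord:
    """Annual anthropogenic emission fluxes and their 1-sigma uncertainties.

    Fossil-fuel emissions carry a fractional uncertainty (default 5%);
    land-use-change emissions carry a constant absolute uncertainty
    (default 0.7 GtC yr^-1).
    """

    f_ff: AnnualSeries
    f_luc: AnnualSeries
    sigma_ff_frac: float = 0.05
    sigma_luc_abs: float = 0.7

    def __post_init__(self) -> None:
        if self.f_ff.kind != "emission_flux" or self.f_luc.kind != "emission_flux":
            raise UnitsError("emission record requires emission_flux series")
        if not np.array_equal(self.f_ff.years, self.f_luc.years):
            raise AlignmentError("F_FF and F_LUC must cover identical years")
        if self.sigma_ff_frac < 0 or self.sigma_luc_abs < 0:
            raise ValueError("sigmas must be nonnegative")


def cumulative_emissions(rec: EmissionRecord) -> AnnualSeries:
    """Cumulative anthropogenic emissions C_E(t) = sum_{tau<=t} (F_FF+F_LUC).

    A discrete running sum of the annual fluxes from the first year; the
    first value equals the first-year total flux.  Result in GtC.
    """
    total = rec.f_ff.values + rec.f_luc.values
    return AnnualSeries(rec.f_ff.years, np.cumsum(total),
                        units="GtC", kind="cumulative_emission")


def convert_carbon_units(s: AnnualSeries, target_units: str) -> AnnualSeries:
    """Convert a carbon series between ppm and GtC via m = 2.12 GtC ppm^-1."""
    if s.units not in _CARBON_UNITS:
        raise UnitsError(f"cannot carbon-convert series in {s.units!r}")
    if target_units not in _CARBON_UNITS:
        raise UnitsError(f"target units must be ppm or GtC, got {target_units!r}")
    if target_units == s.units:
        return s
    if target_units == "GtC":
        vals = s.values * M_GTC_PER_PPM
    else:
        vals = s.values / M_GTC_PER_PPM
    return AnnualSeries(s.years, vals, units=target_units, kind=s.kind)


def anomaly_relative_to(s: AnnualSeries, base_start: int, base_end: int) -> AnnualSeries:
    """Subtract the mean over the base period [base_start, base_end]."""
    if base_start > base_end:
        raise ValueError("base_start must not exceed base_end")
    if base_start < s.start_year or base_end > s.end_year:
        raise AlignmentError(
            f"base period {base_start}-{base_end} outside series "
            f"{s.start_year}-{s.end_year}"
        )
    base = s.window(base_start, base_end).values
    return s.with_values(s.values - base.mean())


def resample_to_years(points: Sequence[tuple[float, float]] | np.ndarray,
                      units: str = "ppm",
                      kind: str = "co2_concentration") -> AnnualSeries:
    """Resample irregular (year, value) observations to a contiguous annual grid.

    Each observation is assigned to its nearest calendar year; same-year
    collisions are averaged with a logged warning.  Gaps are then filled by
    linear interpolation between assigned years.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (year, value) points")
    yrs = np.rint(pts[:, 0]).astype(int)
    vals = pts[:, 1]
    uniq, inverse, counts = np.unique(yrs, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        logger.warning(
            "resample_to_years: %d same-year collisions averaged",
            int(np.sum(counts > 1)),
        )
    sums = np.zeros(len(uniq))
    np.add.at(sums, inverse, vals)
    means = sums / counts
    if len(uniq) < 2:
        raise ValueError("observations collapse to fewer than 2 distinct years")
    grid = np.arange(uniq[0], uniq[-1] + 1)
    filled = np.interp(grid, uniq, means)
    return AnnualSeries(grid, filled, units=units, kind=kind)


def spline_smooth(s: AnnualSeries, cutoff_years: float) -> AnnualSeries:
    """Low-pass smooth with 50% frequency response at period ``cutoff_years``.

    The standard dendroclimatology reading of an "N-year spline": a
    zero-phase low-pass filter whose amplitude response is 0.5 at period N.
    Implemented as an order-2 Butterworth filter applied forward-backward
    (the squared Butterworth magnitude is exactly 1/2 at its critical
    frequency).  The input mean is preserved.
    """
    if cutoff_years < 2:
        raise ValueError("cutoff_years must be >= 2")
    if cutoff_years >= len(s):
        raise ValueError("cutoff_years must be shorter than the series")
    # annual sampling: critical frequency in half-cycles per year
    wn = 2.0 / cutoff_years
    b, a = signal.butter(2, wn)
    smoothed = signal.filtfilt(b, a, s.values)
    smoothed = smoothed + (s.values.mean() - smoothed.mean())
    return s.with_values(smoothed)


def align_series(series: Iterable[AnnualSeries]) -> list[AnnualSeries]:
    """Restrict all series to their common (intersection) year range."""
    series = list(series)
    if not series:
        raise ValueError("no series to align")
    start = max(s.start_year for s in series)
    end = min(s.end_year for s in series)
    if start > end - 1:  # need >= 2 overlapping years
        raise AlignmentError("series do not overlap over at least 2 years")
    return [s.window(start, end) for s in series]


# ---------------------------------------------------------------------------
# Table I/O: comma-separated, header `year,value[,sigma]`.

def read_series(path: str | Path, units: str, kind: str) -> AnnualSeries:
    """Read a ``year,value[,sigma]`` table as an AnnualSeries (sigma ignored)."""
    df = pd.read_csv(path)
    if "year" not in df.columns or "value" not in df.columns:
        raise ValueError(f"{path}: expected columns year,value[,sigma]")
    return AnnualSeries(df["year"].to_numpy(), df["value"].to_numpy(),
                        units=units, kind=kind)


def write_series(s: AnnualSeries, path: str | Path,
                 sigma: np.ndarray | None = None) -> None:
    """Write the standard ``year,value[,sigma]`` table."""
    df = s.to_frame()
    if sigma is not None:
        df["sigma"] = np.asarray(sigma, dtype=float)
    df.to_csv(path, index=False)


def read_emission_record(path_ff: str | Path, path_luc: str | Path,
                         sigma_ff_frac: float = 0.05,
                         sigma_luc_abs: float = 0.7) -> EmissionRecord:
    """Read fossil-fuel and land-use-change flux tables into an EmissionRecord."""
    f_ff = read_series(path_ff, units="GtC_per_yr", kind="emission_flux")
    f_luc = read_series(path_luc, units="GtC_per_yr", kind="emission_flux")
    return EmissionRecord(f_ff=f_ff, f_luc=f_luc,
                          sigma_ff_frac=sigma_ff_frac,
                          sigma_luc_abs=sigma_luc_abs)
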