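"""Fourier amplitude spectra and the cross-timescale feedback regression.

The central idea: writing cumulative emissions C_E, atmospheric CO2 C_A
and temperature T_A as harmonic sums, the mass balance of the coupled
carbon-climate system

    dC_E = (1 + beta) dC_A + gamma* dT_A

must hold harmonic by harmonic, so the per-harmonic amplitudes a_k, b_k,
c_k of the three series satisfy a_k = (1 + beta) b_k + gamma* c_k.  With
zeta_k = a_k / c_k (the inverse TCRE at timescale N/k) and
eta_k = b_k / c_k (the inverse CO2-climate sensitivity alpha), this is a
straight line across timescales,

    zeta_k = (1 + beta) eta_k + gamma*,

whose slope and intercept give the carbon-concentration feedback beta and
the combined carbon-climate feedback gamma*.  The regression is ordinary
least squares over the harmonics whose timescale falls in a configurable
band.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .series import AlignmentError, AnnualSeries, M_GTC_PER_PPM

logger = logging.getLogger(__name__)

#: Harmonics whose temperature amplitude is below this fraction of the
#: maximum are excluded from ratio estimates (the ratio is undefined).
DENOMINATOR_FLOOR_FRAC = 1e-9


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """One-sided Fourier amplitude spectrum of an annual series.

    Amplitudes use the 2/N convention (a pure sinusoid of amplitude A at
    harmonic k gives amplitude A at k), phases are those of
    ``A sin(omega_k t + phi)`` with t in years since the record start, and
    the mean (k = 0) is removed before the transform.  The trend of the
    record is carried by the low-frequency harmonics: no detrending, no
    taper.
    """

    n_years: int
    k: np.ndarray  # wavenumbers 1..floor(N/2)
    amplitude: np.ndarray
    phase: np.ndarray
    units: str
    kind: str

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies 2 pi k / N (rad yr^-1)."""
        return 2.0 * np.pi * self.k / self.n_years

    @property
    def timescale(self) -> np.ndarray:
        """Periods N / k in years (strictly decreasing in k)."""
        return self.n_years / self.k

    @property
    def is_nyquist(self) -> np.ndarray:
        """True at the phase-degenerate Nyquist harmonic (k = N/2, even N)."""
        return 2 * self.k == self.n_years

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k,
            "timescale_yr": self.timescale,
            "amplitude": self.amplitude,
            "phase": self.phase,
        })


def amplitude_spectrum(s: AnnualSeries) -> AmplitudeSpectrum:
    """FFT amplitude spectrum of an annual series (mean removed, one-sided)."""
    n = len(s)
    if n < 4:
        raise ValueError("need at least 4 years for a spectrum")
    x = s.values - s.values.mean()
    coeffs = np.fft.rfft(x)
    k = np.arange(1, n // 2 + 1)
    amp = 2.0 / n * np.abs(coeffs[1:])
    # x = A sin(wt + phi) has rfft coefficient (N/2) exp(i(phi - pi/2))
    phase = np.angle(coeffs[1:]) + np.pi / 2.0
    phase = np.mod(phase + np.pi, 2.0 * np.pi) - np.pi
    return AmplitudeSpectrum(n_years=n, k=k, amplitude=amp, phase=phase,
                             units=s.units, kind=s.kind)


@dataclass(frozen=True)
class TimescaleEstimates:
    """Per-timescale ratio estimates zeta_k, eta_k (and airborne fraction).

    zeta_k = a_k / c_k is the inverse TCRE; eta_k = b_k / c_k the inverse
    alpha; af_k = b_k / a_k the airborne fraction — all at timescale N/k.
    Harmonics with a temperature amplitude below the denominator floor are
    excluded at construction.
    """

    n_years: int
    table: pd.DataFrame  # columns: k, timescale_yr, zeta, eta, af, is_nyquist

    @property
    def k(self) -> np.ndarray:
        return self.table["k"].to_numpy()

    @property
    def timescale(self) -> np.ndarray:
        return self.table["timescale_yr"].to_numpy()

    @property
    def zeta(self) -> np.ndarray:
        return self.table["zeta"].to_numpy()

    @property
    def eta(self) -> np.ndarray:
        return self.table["eta"].to_numpy()

    @property
    def af(self) -> np.ndarray:
        return self.table["af"].to_numpy()

    def in_band(self, band: tuple[float, float],
                drop_nyquist: bool = True) -> pd.DataFrame:
        lo, hi = band
        if lo > hi:
            raise ValueError("band minimum exceeds maximum")
        t = self.table
        mask = (t["timescale_yr"] >= lo) & (t["timescale_yr"] <= hi)
        if drop_nyquist:
            mask &= ~t["is_nyquist"]
        return t[mask]

    def with_gamma_star(self, beta: float) -> pd.DataFrame:
        """Table extended with gamma*_k = zeta_k - (1 + beta) eta_k."""
        t = self.table.copy()
        t["gamma_star"] = gamma_star_by_timescale(self, beta)
        return t


def zeta_eta(spec_ce: AmplitudeSpectrum, spec_ca: AmplitudeSpectrum,
             spec_ta: AmplitudeSpectrum) -> TimescaleEstimates:
    """Per-harmonic zeta_k = a_k/c_k and eta_k = b_k/c_k (plus AF_k = b_k/a_k).

    The two carbon spectra must be in the same carbon units (GtC for
    GtC K^-1 ratios); the temperature spectrum in K.  Harmonics whose
    temperature amplitude is below the floor are excluded and logged.
    """
    if not (spec_ce.n_years == spec_ca.n_years == spec_ta.n_years):
        raise AlignmentError("spectra must share the record length N")
    if spec_ce.units != spec_ca.units:
        raise ValueError("C_E and C_A spectra must share carbon units")
    c = spec_ta.amplitude
    floor = DENOMINATOR_FLOOR_FRAC * (c.max() if c.size else 0.0)
    keep = c > floor
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("zeta_eta: %d harmonics dropped (temperature amplitude "
                       "below floor)", n_dropped)
    a = spec_ce.amplitude
    af = np.where(a > 0, spec_ca.amplitude / np.where(a > 0, a, 1.0), np.nan)
    table = pd.DataFrame({
        "k": spec_ce.k[keep],
        "timescale_yr": spec_ce.timescale[keep],
        "zeta": spec_ce.amplitude[keep] / c[keep],
        "eta": spec_ca.amplitude[keep] / c[keep],
        "af": af[keep],
        "is_nyquist": spec_ce.is_nyquist[keep],
    })
    return TimescaleEstimates(n_years=spec_ce.n_years, table=table)


@dataclass(frozen=True)
class FeedbackFit:
    """OLS fit of zeta_k on eta_k: slope p = 1 + beta, intercept gamma*."""

    slope: float
    beta: float  # GtC GtC^-1 (slope - 1)
    gamma_star: float  # GtC K^-1
    sigma_slope: float
    sigma_gamma_star: float
    r_squared: float
    band: tuple[float, float]
    n_harmonics: int

    @property
    def beta_gtc_per_ppm(self) -> float:
        """beta in GtC ppm^-1 (multiply the dimensionless form by m)."""
        return self.beta * M_GTC_PER_PPM

    @property
    def sigma_beta(self) -> float:
        return self.sigma_slope

    def summary(self) -> str:
        return "\n".join([
            "Cross-timescale feedback fit  zeta_k = (1 + beta) eta_k + gamma*",
            f"  band: {self.band[0]:g}-{self.band[1]:g} yr"
            f"   harmonics: {self.n_harmonics}   R^2 = {self.r_squared:.4f}",
            f"  slope p     = {self.slope:.4f} +/- {self.sigma_slope:.4f}",
            f"  beta        = {self.beta:.4f} +/- {self.sigma_beta:.4f} GtC GtC^-1"
            f"  ({self.beta_gtc_per_ppm:.4f} GtC ppm^-1)",
            f"  gamma*      = {self.gamma_star:.4f} +/- {self.sigma_gamma_star:.4f} GtC K^-1",
        ])


def fit_beta_gamma_star(est: TimescaleEstimates,
                        band: tuple[float, float] = (2.0, 90.0)) -> FeedbackFit:
    """OLS of zeta_k on eta_k (with intercept) over a timescale band.

    Returns beta = slope - 1 (GtC GtC^-1) and gamma* = intercept
    (GtC K^-1) with their standard OLS errors.  The Nyquist harmonic is
    excluded (phase degenerate); at least 3 harmonics are required.
    """
    sub = est.in_band(band, drop_nyquist=True)
    if len(sub) < 3:
        raise ValueError(f"only {len(sub)} harmonics in band {band}; need >= 3")
    eta = sub["eta"].to_numpy()
    zeta = sub["zeta"].to_numpy()
    if np.ptp(eta) == 0:
        raise ValueError("zero variance in eta_k: regression degenerate")
    res = sm.OLS(zeta, sm.add_constant(eta)).fit()
    intercept, slope = res.params
    sig_int, sig_slope = res.bse
    return FeedbackFit(slope=float(slope), beta=float(slope - 1.0),
                       gamma_star=float(intercept),
                       sigma_slope=float(sig_slope),
                       sigma_gamma_star=float(sig_int),
                       r_squared=float(res.rsquared),
                       band=band, n_harmonics=len(sub))


def gamma_star_by_timescale(est: TimescaleEstimates, beta: float) -> np.ndarray:
    """Per-timescale gamma*_k = zeta_k - (1 + beta) eta_k (GtC K^-1)."""
    return est.zeta - (1.0 + beta) * est.eta


def preindustrial_gamma(eta_k_ppm_per_k: float | np.ndarray,
                        beta: float) -> float | np.ndarray:
    """Preindustrial carbon-climate feedback gamma_k = -m (1 + beta) eta_k.

    For a quasi-equilibrium period with negligible emissions (zeta ~ 0),
    the feedback identity collapses to this closed form; eta_k is in
    ppm K^-1 (reconstruction-based), beta in GtC GtC^-1, gamma in GtC K^-1.
    """
    if beta <= -1:
        raise ValueError("beta must exceed -1")
    return -M_GTC_PER_PPM * (1.0 + beta) * np.asarray(eta_k_ppm_per_k, dtype=float)


def band_statistics(est: TimescaleEstimates, band: tuple[float, float],
                    quantity: str = "zeta",
                    values: np.ndarray | None = None) -> tuple[float, float, int]:
    """Unweighted mean, sample sd and count of a quantity over a timescale band.

    ``quantity`` names a column of the estimates table; alternatively an
    explicit per-harmonic ``values`` array (aligned with the table) may be
    supplied, e.g. a gamma_k profile.  A single-harmonic band reports
    sd = 0 with n = 1.
    """
    t = est.table
    if values is not None:
        col = np.asarray(values, dtype=float)
        if len(col) != len(t):
            raise ValueError("values must align with the estimates table")
    else:
        if quantity not in t.columns:
            raise KeyError(f"unknown quantity {quantity!r}")
        col = t[quantity].to_numpy()
    lo, hi = band
    mask = (t["timescale_yr"].to_numpy() >= lo) & (t["timescale_yr"].to_numpy() <= hi)
    sel = col[mask]
    sel = sel[~np.isnan(sel)]
    n = len(sel)
    if n == 0:
        raise ValueError(f"no harmonics in band {band}")
    mean = float(sel.mean())
    sd = float(sel.std(ddof=1)) if n > 1 else 0.0
    return mean, sd, n
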