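"""Synthetic inputs with the statistical structure the analysis assumes.

The estimators in this package are designed for three kinds of input:
multi-harmonic CO2/temperature covariation obeying the feedback identity
a_k = (1+beta) b_k + gamma* c_k, exponentially growing anthropogenic
emissions, and coupled/uncoupled (COU/BGC/RAD) experiment triplets with a
prescribed bilinear carbon-storage response.  The generators here produce
each of those with known ground-truth parameters, so every downstream
stage can be tested end to end without observational downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fea import ExperimentRun, ExperimentTriplet
from .series import AnnualSeries, M_GTC_PER_PPM, spline_smooth


@dataclass(frozen=True)
class Harmonic:
    """One harmonic component: wavenumber, ppm/K amplitudes, phase (rad)."""

    k: int
    amp_ca: float  # ppm
    amp_ta: float  # K
    phase: float = 0.0


@dataclass(frozen=True)
class HarmonicSpec:
    """A multi-harmonic CO2/temperature system with known feedbacks.

    In ``phase_locked`` mode each harmonic of C_A and T_A shares its phase,
    so the per-harmonic amplitude identity a_k = (1+beta) b_k + gamma* c_k
    holds exactly (the feedback-parameter fit recovers beta and gamma* to
    round-off).  In random-phase mode the C_A and T_A phases are drawn
    independently; the identity then holds for the complex Fourier
    coefficients but not necessarily for the amplitudes, which exposes the
    estimator's phase assumption.
    """

    n_years: int
    harmonics: tuple[Harmonic, ...]
    beta_true: float  # GtC GtC^-1
    gamma_star_true: float  # GtC K^-1
    phase_locked: bool = True
    seed: int | None = None
    start_year: int = 1850

    def __post_init__(self) -> None:
        object.__setattr__(self, "harmonics", tuple(self.harmonics))
        if self.n_years < 4:
            raise ValueError("need at least 4 years")
        for h in self.harmonics:
            if not 1 <= h.k <= self.n_years / 2:
                raise ValueError(
                    f"harmonic k={h.k} aliases: need 1 <= k <= N/2 = {self.n_years / 2}"
                )
            if h.amp_ca < 0 or h.amp_ta < 0:
                raise ValueError("amplitudes must be nonnegative")
            if self.phase_locked:
                combined = ((1.0 + self.beta_true) * M_GTC_PER_PPM * h.amp_ca
                            + self.gamma_star_true * h.amp_ta)
                if combined < 0:
                    raise ValueError(
                        "phase-locked harmonic with negative combined emission "
                        "coefficient: the amplitude identity cannot hold with "
                        f"positive a_k (k={h.k})"
                    )
        if not self.phase_locked and self.seed is None:
            raise ValueError("random-phase mode requires a seed")


def gen_harmonic_system(spec: HarmonicSpec) -> tuple[AnnualSeries, AnnualSeries, AnnualSeries]:
    """Build (C_E, C_A, T_A) from a harmonic spec.

    C_A (ppm) and T_A (K) are harmonic sums; C_E (GtC) is built in the time
    domain as C_E(t) = (1+beta) C_A(t) + gamma* T_A(t) with C_A converted
    to GtC, so the feedback identity is exact by construction.
    """
    n = spec.n_years
    t = np.arange(n, dtype=float)
    ca = np.zeros(n)
    ta = np.zeros(n)
    rng = np.random.default_rng(spec.seed) if not spec.phase_locked else None
    for h in spec.harmonics:
        omega = 2.0 * math.pi * h.k / n
        if spec.phase_locked:
            ph_ca = ph_ta = h.phase
        else:
            ph_ca, ph_ta = rng.uniform(0.0, 2.0 * math.pi, size=2)
        ca += h.amp_ca * np.sin(omega * t + ph_ca)
        ta += h.amp_ta * np.sin(omega * t + ph_ta)
    ce = (1.0 + spec.beta_true) * M_GTC_PER_PPM * ca + spec.gamma_star_true * ta
    years = np.arange(spec.start_year, spec.start_year + n)
    return (
        AnnualSeries(years, ce, units="GtC", kind="cumulative_emission"),
        AnnualSeries(years, ca, units="ppm", kind="co2_concentration"),
        AnnualSeries(years, ta, units="K", kind="temperature_anomaly"),
    )


def gen_exponential_emissions(n_years: int, amplitude: float = 0.27,
                              rate: float = 0.018,
                              amplitude_units: str = "ppm_per_yr",
                              start_year: int = 1850) -> AnnualSeries:
    """Exponentially growing emission flux A * exp(r t), t in years since start.

    The defaults reproduce the exponential fit to industrial-era
    anthropogenic emissions, 0.27 e^{0.018 t} in ppm yr^-1 from 1850.
    Output is always in GtC yr^-1; with ``amplitude_units='ppm_per_yr'``
    the amplitude is converted through m = 2.12 GtC ppm^-1.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if amplitude_units not in {"ppm_per_yr", "GtC_per_yr"}:
        raise ValueError("amplitude_units must be ppm_per_yr or GtC_per_yr")
    t = np.arange(n_years, dtype=float)
    flux = amplitude * np.exp(rate * t)
    if amplitude_units == "ppm_per_yr":
        flux = flux * M_GTC_PER_PPM
    years = np.arange(start_year, start_year + n_years)
    return AnnualSeries(years, flux, units="GtC_per_yr", kind="emission_flux")


def gen_ar1_noise(n_years: int, phi: float, sigma: float, seed: int,
                  start_year: int = 1850) -> AnnualSeries:
    """Stationary AR(1) temperature residual with marginal sd ``sigma``.

    x_t = phi x_{t-1} + w_t with innovation sd sigma*sqrt(1-phi^2), and
    x_0 drawn from the stationary marginal, so the whole series is
    stationary from the first sample.  Reproducible for a fixed seed.
    """
    if abs(phi) >= 1:
        raise ValueError("|phi| must be < 1 for stationarity")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    x = np.zeros(n_years)
    innov_sd = sigma * math.sqrt(1.0 - phi * phi)
    x[0] = rng.normal(0.0, sigma)
    w = rng.normal(0.0, innov_sd, size=n_years - 1)
    for i in range(1, n_years):
        x[i] = phi * x[i - 1] + w[i - 1]
    years = np.arange(start_year, start_year + n_years)
    return AnnualSeries(years, x, units="K", kind="residual")


def gen_icecore_like(s: AnnualSeries, smooth_years: float = 30.0) -> AnnualSeries:
    """Emulate firn-diffusion smoothing of an atmospheric record.

    Gas diffusion before bubble close-off removes inter-annual variability
    from ice-core CO2; this applies the package's low-pass smoother at the
    given cutoff so synthetic records share that loss of high frequencies.
    """
    if smooth_years < 1:
        raise ValueError("smooth_years must be >= 1")
    if smooth_years < 2:
        return s  # below the smoother's resolution: annual record unchanged
    return spline_smooth(s, smooth_years)


@dataclass(frozen=True)
class TripletSpec:
    """Ground truth for a COU/BGC/RAD experiment triplet.

    beta_true (GtC GtC^-1), gamma_true (GtC K^-1) and f_true
    (GtC GtC^-1 K^-1) define the bilinear biosphere carbon response
    dC_B = beta dC_A + gamma dT + f dC_A dT (carbon in GtC); ``s`` is the
    warming per CO2 doubling (K) driving the logarithmic temperature
    response; ``co2_path`` is the prescribed atmospheric CO2 (ppm).
    """

    beta_true: float
    gamma_true: float
    f_true: float
    s: float
    co2_path: AnnualSeries
    seed: int = 0
    noise_sd: float = 0.0  # K, added to the COU/RAD temperature response

    def __post_init__(self) -> None:
        if self.co2_path.units != "ppm":
            raise ValueError("co2_path must be in ppm")
        if np.any(self.co2_path.values <= 0):
            raise ValueError("co2_path must be positive (log forcing)")
        if self.s < 0:
            raise ValueError("climate sensitivity s must be >= 0")


def gen_experiment_triplet(spec: TripletSpec) -> ExperimentTriplet:
    """Generate COU, BGC and RAD runs with prescribed (beta, gamma, f).

    COU: carbon and radiation both see ``co2_path``; dT from the
    logarithmic response, dC_B = beta dC_A + gamma dT + f dC_A dT.
    BGC: carbon sees ``co2_path``, radiation sees the baseline, so
    dT^BGC = 0 and dC_B^BGC = beta dC_A.
    RAD: radiation sees ``co2_path``, carbon sees the baseline, so
    dC_A^RAD (as seen by carbon) = 0 and dC_B^RAD = gamma dT^RAD.
    dC_A^COU equals dC_A^BGC by construction.
    """
    years = spec.co2_path.years
    c0 = spec.co2_path.values[0]
    dca_ppm = spec.co2_path.values - c0
    dca_gtc = M_GTC_PER_PPM * dca_ppm
    dt_forced = (spec.s / math.log(2.0)) * np.log(spec.co2_path.values / c0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        dt_cou = dt_forced + rng.normal(0.0, spec.noise_sd, size=len(years))
        dt_rad = dt_forced + rng.normal(0.0, spec.noise_sd, size=len(years))
    else:
        dt_cou = dt_forced.copy()
        dt_rad = dt_forced.copy()

    def _series(vals, units, kind):
        return AnnualSeries(years, vals, units=units, kind=kind)

    dcb_cou = (spec.beta_true * dca_gtc + spec.gamma_true * dt_cou
               + spec.f_true * dca_gtc * dt_cou)
    cou = ExperimentRun(
        delta_cb=_series(dcb_cou, "GtC", "carbon_storage"),
        delta_ca=_series(dca_ppm, "ppm", "co2_concentration"),
        delta_ta=_series(dt_cou, "K", "temperature_anomaly"),
    )
    bgc = ExperimentRun(
        delta_cb=_series(spec.beta_true * dca_gtc, "GtC", "carbon_storage"),
        delta_ca=_series(dca_ppm, "ppm", "co2_concentration"),
        delta_ta=_series(np.zeros(len(years)), "K", "temperature_anomaly"),
    )
    rad = ExperimentRun(
        delta_cb=_series(spec.gamma_true * dt_rad, "GtC", "carbon_storage"),
        delta_ca=_series(np.zeros(len(years)), "ppm", "co2_concentration"),
        delta_ta=_series(dt_rad, "K", "temperature_anomaly"),
    )
    return ExperimentTriplet(cou=cou, bgc=bgc, rad=rad,
                             reference_year=int(years[0]))
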