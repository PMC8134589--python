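"""Airborne fraction, feedback gain/amplification and uncertainty algebra.

The strength of the climate-carbon cycle feedback loop is summarised by
the gain factor g and the amplification G = 1/(1 - g).  Two equivalent
routes give g:

    g = -gamma* alpha / (1 + beta)          (from the feedback parameters)
    g = 1 - 1 / (AF (1 + beta))             (from the airborne fraction)

with AF = dC_A / dC_E the cumulative airborne fraction and
alpha = dT_A / dC_A the climate sensitivity to atmospheric CO2.  This
module also carries the error-propagation formulas used for ensemble
estimates and for scaling an allowable-emission budget by a ratio of
amplifications.

Unit convention: beta here is the dimensionless GtC GtC^-1 form; a value
in GtC ppm^-1 must be divided by m = 2.12 first (see ``beta_to_gtc``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .series import EmissionRecord, M_GTC_PER_PPM
from .spectral import AmplitudeSpectrum, band_statistics, TimescaleEstimates


class RunawayFeedbackError(ValueError):
    """Raised when g >= 1 (the amplification diverges)."""


def beta_to_gtc(beta: float, units: str = "GtC_per_GtC") -> float:
    """Normalise a beta value to the dimensionless GtC GtC^-1 form.

    The unit tag is mandatory to prevent the factor-2.12 ambiguity between
    the two conventions in which beta is commonly quoted.
    """
    if units == "GtC_per_GtC":
        return beta
    if units == "GtC_per_ppm":
        return beta / M_GTC_PER_PPM
    raise ValueError(f"unknown beta units {units!r}")


def airborne_fraction_spectrum(spec_ca: AmplitudeSpectrum,
                               spec_ce: AmplitudeSpectrum,
                               band: tuple[float, float] | None = None
                               ) -> tuple[np.ndarray, float, float, int]:
    """Per-harmonic airborne fraction AF_k = b_k / a_k and band statistics.

    Both spectra must be in the same carbon units.  Harmonics with a
    degenerate emission amplitude are excluded.  Returns
    ``(af_k, mean, sd, n)`` with the statistics over ``band`` (full range
    when None).
    """
    if spec_ca.n_years != spec_ce.n_years:
        raise ValueError("spectra must share N")
    if spec_ca.units != spec_ce.units:
        raise ValueError("spectra must share carbon units")
    a = spec_ce.amplitude
    floor = 1e-12 * (a.max() if a.size else 0.0)
    keep = a > floor
    af = np.full(len(a), np.nan)
    af[keep] = spec_ca.amplitude[keep] / a[keep]
    ts = spec_ce.timescale
    if band is None:
        band = (float(ts.min()), float(ts.max()))
    mask = keep & (ts >= band[0]) & (ts <= band[1]) & ~spec_ce.is_nyquist
    sel = af[mask]
    if len(sel) == 0:
        raise ValueError(f"no usable harmonics in band {band}")
    mean = float(sel.mean())
    sd = float(sel.std(ddof=1)) if len(sel) > 1 else 0.0
    return af, mean, sd, int(len(sel))


def gain_from_af_beta(af: float, beta_gtc_per_gtc: float) -> float:
    """Feedback gain g = 1 - 1 / (AF (1 + beta))."""
    if af <= 0:
        raise ValueError("airborne fraction must be positive")
    denom = af * (1.0 + beta_gtc_per_gtc)
    if denom == 0:
        raise ZeroDivisionError("AF (1 + beta) is zero")
    return 1.0 - 1.0 / denom


def gain_from_alpha(gamma_star: float, alpha: float,
                    beta_gtc_per_gtc: float) -> tuple[float, float]:
    """Feedback gain g = -gamma* alpha / (1 + beta); also returns alpha*gamma*.

    alpha in K GtC^-1, gamma* in GtC K^-1, beta dimensionless; the product
    alpha*gamma* (GtC GtC^-1) is the diagnostic that competes with beta in
    AF = 1 / (1 + beta + alpha gamma*).
    """
    if 1.0 + beta_gtc_per_gtc <= 0:
        raise ValueError("1 + beta must be positive")
    alpha_gamma = alpha * gamma_star
    return -alpha_gamma / (1.0 + beta_gtc_per_gtc), alpha_gamma


def amplification(g: float) -> float:
    """Feedback amplification G = 1 / (1 - g); requires g < 1."""
    if g >= 1:
        raise RunawayFeedbackError(f"g = {g} >= 1: runaway feedback")
    return 1.0 / (1.0 - g)


def amplification_from_af_beta(af: float, beta_gtc_per_gtc: float) -> float:
    """Feedback amplification G = AF (1 + beta) (equals 1/(1-g))."""
    if af <= 0:
        raise ValueError("airborne fraction must be positive")
    return af * (1.0 + beta_gtc_per_gtc)


def allowable_emissions_scale(base_budget_gtc: float,
                              g_model: float, sigma_g_model: float,
                              g_obs: float, sigma_g_obs: float
                              ) -> dict[str, float]:
    """Rescale an allowable-emission budget by the amplification ratio.

    A budget derived with a model amplification G_model is rescaled to an
    observation-based amplification G_obs as budget * G_model / G_obs
    (weaker observed feedback => more allowable emissions).  The sigma of
    the ratio follows the standard relative-quadrature propagation
    ratio * sqrt((sigma_M/G_M)^2 + (sigma_O/G_O)^2).

    Arguments are the amplifications G (> 0) and their 1-sigma errors.
    Returns budget, sigma_budget (GtC), percent change and sigma_percent.
    """
    if g_model <= 0 or g_obs <= 0:
        raise ValueError("amplifications must be positive")
    ratio = g_model / g_obs
    sigma_ratio = ratio * math.sqrt((sigma_g_model / g_model) ** 2
                                    + (sigma_g_obs / g_obs) ** 2)
    return {
        "budget_gtc": base_budget_gtc * ratio,
        "sigma_budget_gtc": base_budget_gtc * sigma_ratio,
        "percent_change": 100.0 * (g_model - g_obs) / g_obs,
        "sigma_percent": 100.0 * sigma_ratio,
    }


def sigma_emission_flux(rec: EmissionRecord) -> np.ndarray:
    """Per-year 1-sigma of the total emission flux, in quadrature.

    sigma_FE = sqrt((frac * F_FF)^2 + sigma_LUC^2) with the record's
    fractional fossil-fuel and absolute land-use uncertainties.
    """
    s_ff = rec.sigma_ff_frac * rec.f_ff.values
    return np.sqrt(s_ff ** 2 + rec.sigma_luc_abs ** 2)


def ensemble_mean_sigma(estimates: Sequence[tuple[float, float]]
                        ) -> tuple[float, float]:
    """Ensemble mean with propagated sigma = (1/n) sqrt(sum sigma_i^2)."""
    if len(estimates) < 1:
        raise ValueError("need at least one member")
    vals = np.array([v for v, _ in estimates], dtype=float)
    sigs = np.array([s for _, s in estimates], dtype=float)
    n = len(vals)
    return float(vals.mean()), float(np.sqrt(np.sum(sigs ** 2)) / n)


def ensemble_sd(values: Sequence[float]) -> float:
    """Plain sample standard deviation of an ensemble (n >= 2)."""
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("sample sd needs at least 2 members")
    return float(vals.std(ddof=1))


@dataclass(frozen=True)
class GainResult:
    """Feedback gain diagnostics from one consistent set of inputs."""

    af: float
    beta: float  # GtC GtC^-1
    gamma_star: float  # GtC K^-1
    alpha: float  # K GtC^-1
    tcre: float  # K GtC^-1
    alpha_gamma: float  # GtC GtC^-1
    g: float
    G: float
    sigma_g: float = 0.0
    sigma_G: float = 0.0

    def __post_init__(self) -> None:
        if self.g >= 1:
            raise RunawayFeedbackError(f"g = {self.g} >= 1")
        if not math.isclose(self.G, 1.0 / (1.0 - self.g),
                            rel_tol=0.0, abs_tol=1e-12):
            raise ValueError("G must equal 1/(1-g)")

    def summary(self) -> str:
        return "\n".join([
            "Climate-carbon cycle feedback gain",
            f"  AF          = {self.af:.3f}",
            f"  beta        = {self.beta:.4f} GtC GtC^-1"
            f"  ({self.beta * M_GTC_PER_PPM:.4f} GtC ppm^-1)",
            f"  gamma*      = {self.gamma_star:.3f} GtC K^-1",
            f"  alpha       = {self.alpha:.5g} K GtC^-1"
            f"   alpha*gamma* = {self.alpha_gamma:.4f}",
            f"  gain g      = {self.g:.4f} +/- {self.sigma_g:.4f}",
            f"  amplification G = {self.G:.4f} +/- {self.sigma_G:.4f}",
        ])


def gain_result(af: float, beta_gtc_per_gtc: float, gamma_star: float,
                alpha: float, sigma_g: float = 0.0) -> GainResult:
    """Assemble a GainResult from (AF, beta, gamma*, alpha).

    g is taken from the airborne-fraction route; tcre is derived as
    alpha / (G) ... specifically 1/TCRE = (1+beta)/alpha + gamma* per the
    feedback identity, and G = AF (1 + beta).
    """
    g = gain_from_af_beta(af, beta_gtc_per_gtc)
    _, alpha_gamma = gain_from_alpha(gamma_star, alpha, beta_gtc_per_gtc)
    inv_tcre = (1.0 + beta_gtc_per_gtc) / alpha + gamma_star if alpha != 0 else math.inf
    tcre = 1.0 / inv_tcre if inv_tcre != 0 else math.inf
    G = amplification(g)
    # As G = 1/(1-g) ~ 1 + g for small g, sigma_G = sigma_g to first order.
    return GainResult(af=af, beta=beta_gtc_per_gtc, gamma_star=gamma_star,
                      alpha=alpha, tcre=tcre, alpha_gamma=alpha_gamma,
                      g=g, G=G, sigma_g=sigma_g, sigma_G=sigma_g)
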