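"""Model/Results interface to the cross-timescale feedback estimation.

:class:`SpectralFeedbackModel` bundles the full pipeline — align the
annual records, convert carbon to GtC, take amplitude spectra, form the
per-timescale ratios and run the cross-timescale regression — behind a
``fit()`` returning a :class:`SpectralFeedbackResults` that carries the
estimates, their uncertainties, diagnostics, and derived quantities
(airborne fraction, feedback gain, per-timescale gamma* profile), plus
``summary()`` and plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gain as _gain
from .boxmodel import BoxModelParams
from .series import (AnnualSeries, M_GTC_PER_PPM, align_series,
                     convert_carbon_units)
from .spectral import (AmplitudeSpectrum, FeedbackFit, TimescaleEstimates,
                       amplitude_spectrum, band_statistics,
                       fit_beta_gamma_star, gamma_star_by_timescale, zeta_eta)


class SpectralFeedbackModel:
    """Carbon-cycle feedback estimation from (C_E, C_A, T_A) annual records.

    Parameters
    ----------
    c_e : AnnualSeries
        Cumulative anthropogenic emissions (GtC, or ppm — converted).
    c_a : AnnualSeries
        Atmospheric CO2 (ppm or GtC — converted to GtC internally).
    t_a : AnnualSeries
        Global-mean temperature anomaly (K).
    band : (float, float), optional
        Timescale band (years) for the regression; default (2, 90), the
        inter-annual-to-multi-decadal band resolved by an industrial-era
        record.

    Examples
    --------
    >>> model = SpectralFeedbackModel(c_e, c_a, t_a, band=(2, 90))
    >>> res = model.fit()
    >>> res.beta, res.gamma_star
    """

    def __init__(self, c_e: AnnualSeries, c_a: AnnualSeries, t_a: AnnualSeries,
                 band: tuple[float, float] = (2.0, 90.0)):
        if t_a.units != "K":
            raise ValueError("t_a must be a temperature series in K")
        c_e, c_a, t_a = align_series([c_e, c_a, t_a])
        self.c_e = convert_carbon_units(c_e, "GtC")
        self.c_a = convert_carbon_units(c_a, "GtC")
        self.t_a = t_a
        self.band = band

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, band: tuple[float, float] = (2.0, 90.0),
                       ce_units: str = "GtC", ca_units: str = "ppm"
                       ) -> "SpectralFeedbackModel":
        """Build from a frame with columns ``year, c_e, c_a, t_a``."""
        for col in ("year", "c_e", "c_a", "t_a"):
            if col not in df.columns:
                raise ValueError(f"missing column {col!r}")
        years = df["year"].to_numpy()
        return cls(
            AnnualSeries(years, df["c_e"].to_numpy(), ce_units, "cumulative_emission"),
            AnnualSeries(years, df["c_a"].to_numpy(), ca_units, "co2_concentration"),
            AnnualSeries(years, df["t_a"].to_numpy(), "K", "temperature_anomaly"),
            band=band,
        )

    def spectra(self) -> tuple[AmplitudeSpectrum, AmplitudeSpectrum, AmplitudeSpectrum]:
        return (amplitude_spectrum(self.c_e), amplitude_spectrum(self.c_a),
                amplitude_spectrum(self.t_a))

    def fit(self, band: tuple[float, float] | None = None) -> "SpectralFeedbackResults":
        """Run the spectral pipeline and the cross-timescale OLS fit."""
        band = band if band is not None else self.band
        spec_ce, spec_ca, spec_ta = self.spectra()
        estimates = zeta_eta(spec_ce, spec_ca, spec_ta)
        fit = fit_beta_gamma_star(estimates, band=band)
        return SpectralFeedbackResults(self, fit, estimates,
                                       spec_ce, spec_ca, spec_ta)


@dataclass
class SpectralFeedbackResults:
    """Estimates, uncertainties and diagnostics of a spectral feedback fit."""

    model: SpectralFeedbackModel
    fit: FeedbackFit
    estimates: TimescaleEstimates
    spec_ce: AmplitudeSpectrum
    spec_ca: AmplitudeSpectrum
    spec_ta: AmplitudeSpectrum

    # -- primary estimates -------------------------------------------------
    @property
    def beta(self) -> float:
        """Carbon-concentration feedback (GtC GtC^-1)."""
        return self.fit.beta

    @property
    def beta_gtc_per_ppm(self) -> float:
        return self.fit.beta_gtc_per_ppm

    @property
    def gamma_star(self) -> float:
        """Combined carbon-climate feedback (GtC K^-1)."""
        return self.fit.gamma_star

    @property
    def slope(self) -> float:
        return self.fit.slope

    @property
    def sigma_beta(self) -> float:
        return self.fit.sigma_beta

    @property
    def sigma_gamma_star(self) -> float:
        return self.fit.sigma_gamma_star

    @property
    def rsquared(self) -> float:
        return self.fit.r_squared

    # -- derived quantities ------------------------------------------------
    def gamma_star_profile(self) -> pd.DataFrame:
        """Per-timescale gamma*_k = zeta_k - (1 + beta) eta_k."""
        return self.estimates.with_gamma_star(self.beta)

    def band_mean(self, quantity: str, band: tuple[float, float] | None = None
                  ) -> tuple[float, float, int]:
        """(mean, sd, n) of zeta/eta/af over a timescale band."""
        return band_statistics(self.estimates, band or self.fit.band, quantity)

    def airborne_fraction(self, band: tuple[float, float] | None = None
                          ) -> tuple[float, float, int]:
        """Band mean, sd and count of the per-harmonic airborne fraction."""
        _, mean, sd, n = _gain.airborne_fraction_spectrum(
            self.spec_ca, self.spec_ce, band=band or self.fit.band)
        return mean, sd, n

    def gain(self, band: tuple[float, float] | None = None) -> "_gain.GainResult":
        """Feedback gain/amplification from this fit's AF, beta and gamma*.

        alpha is taken as the reciprocal of the band-mean eta (K GtC^-1).
        """
        af, _, _ = self.airborne_fraction(band)
        eta_mean, _, _ = self.band_mean("eta", band)
        alpha = 1.0 / eta_mean
        return _gain.gain_result(af, self.beta, self.gamma_star, alpha,
                                 sigma_g=0.0)

    def to_box_model(self, s: float, c0: float, t0: float = 0.0,
                     epsilon: AnnualSeries | None = None) -> BoxModelParams:
        """Box-model parameters carrying this fit's (beta, gamma*)."""
        return BoxModelParams(beta=self.beta, gamma_star=self.gamma_star,
                              s=s, c0=c0, t0=t0, epsilon=epsilon)

    # -- presentation --------------------------------------------------------
    def summary(self) -> str:
        af, af_sd, af_n = self.airborne_fraction()
        lines = [
            "=" * 64,
            "Spectral climate-carbon cycle feedback fit",
            "=" * 64,
            f"record: {self.model.c_e.start_year}-{self.model.c_e.end_year}"
            f"  (N = {len(self.model.c_e)} yr)",
            self.fit.summary(),
            f"  AF          = {af:.3f} +/- {af_sd:.3f}  (n = {af_n})",
            f"  gain g      = {self.gain().g:.4f}"
            f"   amplification G = {self.gain().G:.4f}",
            "=" * 64,
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Scatter zeta_k vs eta_k in the fit band with the regression line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.estimates.in_band(self.fit.band)
        ax.scatter(sub["eta"], sub["zeta"], s=18,
                   c=np.log10(sub["timescale_yr"]), cmap="viridis")
        xs = np.linspace(sub["eta"].min(), sub["eta"].max(), 50)
        ax.plot(xs, self.slope * xs + self.gamma_star, "k-",
                label=f"slope {self.slope:.2f}")
        ax.set_xlabel(r"$\eta_k = 1/\alpha_k$ (GtC K$^{-1}$)")
        ax.set_ylabel(r"$\zeta_k = 1/\mathrm{TCRE}_k$ (GtC K$^{-1}$)")
        ax.legend()
        return ax
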