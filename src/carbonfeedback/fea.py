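"""Feedback estimators for coupled/uncoupled experiment triplets.

Earth-system-model intercomparisons diagnose the carbon-cycle feedbacks by
differencing three configurations of the same simulation: fully coupled
(COU), biogeochemically coupled (BGC: the carbon cycle sees rising CO2 but
the radiation code does not) and radiatively coupled (RAD: radiation sees
rising CO2 but the carbon cycle does not).  With the bilinear response

    dC_B = beta dC_A + gamma dT_A + f(beta, gamma) dC_A dT_A

the run differences at a fixed horizon isolate beta (from BGC), gamma
(from RAD or COU-BGC) and the nonlinear coefficient f (from the residual
COU - BGC - RAD).  All estimators difference against an explicit reference
year, so they are invariant to constant offsets in the stored pools.

Conventions: dC_B in GtC, dC_A in ppm, dT_A in K; beta is reported in
GtC ppm^-1, gamma in GtC K^-1 and f in GtC ppm^-1 K^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .series import AlignmentError, AnnualSeries

#: Temperature differences smaller than this (K) are degenerate denominators.
TEMP_FLOOR_K = 1e-6
#: CO2 differences smaller than this (ppm) are degenerate denominators.
CO2_FLOOR_PPM = 1e-9


class DegenerateDenominatorError(ZeroDivisionError):
    """Raised when an estimator's denominator is below its floor."""


@dataclass(frozen=True)
class ExperimentRun:
    """One experiment's biosphere carbon, CO2 and temperature series.

    ``delta_cb`` is the combined land+ocean carbon storage (GtC); optional
    ``delta_cl``/``delta_co`` carry the land/ocean split when available.
    Series may be stored as absolute pools or as deltas — estimators always
    difference against the triplet's reference year.
    """

    delta_cb: AnnualSeries
    delta_ca: AnnualSeries
    delta_ta: AnnualSeries
    delta_cl: AnnualSeries | None = None
    delta_co: AnnualSeries | None = None

    def __post_init__(self) -> None:
        for s in (self.delta_ca, self.delta_ta, self.delta_cl, self.delta_co):
            if s is not None and not np.array_equal(s.years, self.delta_cb.years):
                raise AlignmentError("all series of a run must share years")
        if self.delta_cl is not None and self.delta_co is not None:
            if not np.allclose(self.delta_cl.values + self.delta_co.values,
                               self.delta_cb.values, atol=1e-6):
                raise ValueError("delta_cl + delta_co must equal delta_cb")


@dataclass(frozen=True)
class ExperimentTriplet:
    """COU, BGC and RAD runs on a common annual grid.

    The COU and BGC configurations prescribe the same atmospheric CO2, so
    their dC_A series must agree (checked to 1e-6 ppm).
    """

    cou: ExperimentRun
    bgc: ExperimentRun
    rad: ExperimentRun
    reference_year: int | None = None

    def __post_init__(self) -> None:
        years = self.cou.delta_cb.years
        for run in (self.bgc, self.rad):
            if not np.array_equal(run.delta_cb.years, years):
                raise AlignmentError("COU/BGC/RAD runs must share years")
        ref = self.reference_year if self.reference_year is not None else int(years[0])
        object.__setattr__(self, "reference_year", ref)
        if ref < years[0] or ref > years[-1]:
            raise AlignmentError("reference year outside the record")
        dca_cou = self._delta(self.cou.delta_ca, years[-1])
        dca_bgc = self._delta(self.bgc.delta_ca, years[-1])
        if abs(dca_cou - dca_bgc) > 1e-6 * max(1.0, abs(dca_cou)):
            raise ValueError("dC_A^COU must equal dC_A^BGC (shared CO2 path)")

    def _delta(self, s: AnnualSeries, horizon_year: int) -> float:
        return s.value_at(horizon_year) - s.value_at(self.reference_year)

    def deltas(self, horizon_year: int | None = None) -> dict[str, dict[str, float]]:
        """Per-run (dC_B, dC_A, dT_A) from the reference year to the horizon."""
        hz = horizon_year if horizon_year is not None else int(self.cou.delta_cb.years[-1])
        out = {}
        for label, run in (("COU", self.cou), ("BGC", self.bgc), ("RAD", self.rad)):
            out[label] = {
                "dcb": self._delta(run.delta_cb, hz),
                "dca": self._delta(run.delta_ca, hz),
                "dta": self._delta(run.delta_ta, hz),
            }
        return out


def _require(value: float, floor: float, name: str) -> float:
    if abs(value) < floor:
        raise DegenerateDenominatorError(f"{name} = {value:.3g} below floor {floor:g}")
    return value


def beta_bgc(triplet: ExperimentTriplet, horizon_year: int | None = None,
             exact_form: bool = False) -> float:
    """Carbon-concentration feedback from the BGC run (GtC ppm^-1).

    Approximate form: dC_B^BGC / dC_A^BGC (exact when dT^BGC = 0).  The
    exact form also removes the small warming of the BGC run using COU.
    """
    d = triplet.deltas(horizon_year)
    dca = _require(d["BGC"]["dca"], CO2_FLOOR_PPM, "dC_A^BGC")
    if not exact_form:
        return d["BGC"]["dcb"] / dca
    dt_diff = _require(d["COU"]["dta"] - d["BGC"]["dta"], TEMP_FLOOR_K,
                       "dT^COU - dT^BGC")
    num = d["BGC"]["dcb"] * d["COU"]["dta"] - d["COU"]["dcb"] * d["BGC"]["dta"]
    return num / (dca * dt_diff)


def gamma_cou_bgc(triplet: ExperimentTriplet, horizon_year: int | None = None,
                  exact_form: bool = False) -> float:
    """Total (direct + nonlinear) carbon-climate feedback, COU minus BGC (GtC K^-1).

    This is the gamma* of the feedback framework: it includes the
    CO2-dependent nonlinear contribution f dC_A on top of the direct gamma.
    """
    d = triplet.deltas(horizon_year)
    if exact_form:
        denom = _require(d["COU"]["dta"] - d["BGC"]["dta"], TEMP_FLOOR_K,
                         "dT^COU - dT^BGC")
    else:
        denom = _require(d["COU"]["dta"], TEMP_FLOOR_K, "dT^COU")
    return (d["COU"]["dcb"] - d["BGC"]["dcb"]) / denom


def gamma_rad(triplet: ExperimentTriplet, horizon_year: int | None = None) -> float:
    """Direct carbon-climate feedback from the RAD run: dC_B^RAD / dT^RAD (GtC K^-1)."""
    d = triplet.deltas(horizon_year)
    denom = _require(d["RAD"]["dta"], TEMP_FLOOR_K, "dT^RAD")
    return d["RAD"]["dcb"] / denom


def beta_cou_rad(triplet: ExperimentTriplet, horizon_year: int | None = None,
                 exact_form: bool = False) -> float:
    """Carbon-concentration feedback from the COU-RAD pair (GtC ppm^-1).

    Approximate form: (dC_B^COU - dC_B^RAD) / dC_A^COU.  The exact form
    eliminates gamma using the RAD run's own warming:
    beta = (dC_B^COU dT^RAD - dC_B^RAD dT^COU) / (dC_A^COU dT^RAD).
    """
    d = triplet.deltas(horizon_year)
    dca = _require(d["COU"]["dca"], CO2_FLOOR_PPM, "dC_A^COU")
    if not exact_form:
        return (d["COU"]["dcb"] - d["RAD"]["dcb"]) / dca
    dt_rad = _require(d["RAD"]["dta"], TEMP_FLOOR_K, "dT^RAD")
    num = d["COU"]["dcb"] * dt_rad - d["RAD"]["dcb"] * d["COU"]["dta"]
    return num / (dca * dt_rad)


def nonlinear_f(triplet: ExperimentTriplet, horizon_year: int | None = None,
                exact_form: bool = False) -> tuple[float, float, float]:
    """Nonlinear feedback coefficient and its contributions.

    Returns ``(f_nl, f_dca, f_dta)``:
    f_nl = [dC_B^COU - (dC_B^BGC + dC_B^RAD)] / [dC_A^COU dT^COU]
    in GtC ppm^-1 K^-1 (the exact form replaces dT^COU with
    dT^COU - dT^BGC); f_dca = f_nl * dC_A^COU is the contribution to
    gamma* (GtC K^-1); f_dta = f_nl * dT^COU is the contribution to the
    beta-feedback (GtC ppm^-1).
    """
    d = triplet.deltas(horizon_year)
    dca = _require(d["COU"]["dca"], CO2_FLOOR_PPM, "dC_A^COU")
    if exact_form:
        dt = _require(d["COU"]["dta"] - d["BGC"]["dta"], TEMP_FLOOR_K,
                      "dT^COU - dT^BGC")
    else:
        dt = _require(d["COU"]["dta"], TEMP_FLOOR_K, "dT^COU")
    resid = d["COU"]["dcb"] - (d["BGC"]["dcb"] + d["RAD"]["dcb"])
    f_nl = resid / (dca * dt)
    return f_nl, f_nl * dca, f_nl * d["COU"]["dta"]


@dataclass(frozen=True)
class FeedbackDecomposition:
    """Results of the full triplet decomposition at one horizon."""

    beta_bgc: float  # GtC ppm^-1
    beta_cou_rad: float  # GtC ppm^-1
    gamma_rad: float  # GtC K^-1
    gamma_cou_bgc: float  # GtC K^-1
    f_nl: float  # GtC ppm^-1 K^-1
    f_dca: float  # GtC K^-1
    f_dta: float  # GtC ppm^-1
    pct_gamma: float  # 100 * f_dca / gamma_cou_bgc
    pct_beta: float  # 100 * f_dta / beta_bgc
    reference_year: int
    horizon_year: int
    land: "FeedbackDecomposition | None" = None
    ocean: "FeedbackDecomposition | None" = None

    def to_dict(self) -> dict[str, float]:
        return {
            "beta_bgc_gtc_per_ppm": self.beta_bgc,
            "beta_cou_rad_gtc_per_ppm": self.beta_cou_rad,
            "gamma_rad_gtc_per_k": self.gamma_rad,
            "gamma_cou_bgc_gtc_per_k": self.gamma_cou_bgc,
            "f_nl_gtc_per_ppm_per_k": self.f_nl,
            "f_dca_gtc_per_k": self.f_dca,
            "f_dta_gtc_per_ppm": self.f_dta,
            "pct_of_gamma": self.pct_gamma,
            "pct_of_beta": self.pct_beta,
        }

    def summary(self) -> str:
        lines = [
            "Feedback decomposition (COU/BGC/RAD)",
            f"  reference year: {self.reference_year}   horizon: {self.horizon_year}",
            f"  beta^BGC      = {self.beta_bgc:+.4f} GtC ppm^-1",
            f"  beta^COU-RAD  = {self.beta_cou_rad:+.4f} GtC ppm^-1",
            f"  gamma^RAD     = {self.gamma_rad:+.3f} GtC K^-1",
            f"  gamma^COU-BGC = {self.gamma_cou_bgc:+.3f} GtC K^-1  (= gamma*)",
            f"  f(beta,gamma) = {self.f_nl:+.5g} GtC ppm^-1 K^-1",
            f"  f*dC_A        = {self.f_dca:+.3f} GtC K^-1  ({self.pct_gamma:+.1f}% of gamma*)",
            f"  f*dT_A        = {self.f_dta:+.4f} GtC ppm^-1  ({self.pct_beta:+.1f}% of beta)",
        ]
        return "\n".join(lines)


def _sub_triplet(triplet: ExperimentTriplet, pool: str) -> ExperimentTriplet:
    """Triplet whose dC_B is one reservoir's storage (pool in {delta_cl, delta_co})."""

    def swap(run: ExperimentRun) -> ExperimentRun:
        series = getattr(run, pool)
        if series is None:
            raise ValueError(f"run lacks {pool}")
        return ExperimentRun(delta_cb=series, delta_ca=run.delta_ca,
                             delta_ta=run.delta_ta)

    return ExperimentTriplet(cou=swap(triplet.cou), bgc=swap(triplet.bgc),
                             rad=swap(triplet.rad),
                             reference_year=triplet.reference_year)


def decompose(triplet: ExperimentTriplet, horizon_year: int | None = None,
              exact_form: bool = False) -> FeedbackDecomposition:
    """Full feedback decomposition of a triplet at one horizon.

    When the runs carry a land/ocean split, per-reservoir decompositions
    are attached (their feedback parameters sum to the totals).
    """
    hz = horizon_year if horizon_year is not None else int(triplet.cou.delta_cb.years[-1])
    b_bgc = beta_bgc(triplet, hz, exact_form=exact_form)
    b_cr = beta_cou_rad(triplet, hz, exact_form=exact_form)
    g_rad = gamma_rad(triplet, hz)
    g_cb = gamma_cou_bgc(triplet, hz, exact_form=exact_form)
    f_nl, f_dca, f_dta = nonlinear_f(triplet, hz, exact_form=exact_form)
    pct_gamma = 100.0 * f_dca / g_cb if g_cb != 0 else float("nan")
    pct_beta = 100.0 * f_dta / b_bgc if b_bgc != 0 else float("nan")
    land = ocean = None
    has_split = all(r.delta_cl is not None and r.delta_co is not None
                    for r in (triplet.cou, triplet.bgc, triplet.rad))
    if has_split:
        land = decompose(_sub_triplet(triplet, "delta_cl"), hz, exact_form)
        ocean = decompose(_sub_triplet(triplet, "delta_co"), hz, exact_form)
    return FeedbackDecomposition(
        beta_bgc=b_bgc, beta_cou_rad=b_cr, gamma_rad=g_rad, gamma_cou_bgc=g_cb,
        f_nl=f_nl, f_dca=f_dca, f_dta=f_dta,
        pct_gamma=pct_gamma, pct_beta=pct_beta,
        reference_year=triplet.reference_year, horizon_year=hz,
        land=land, ocean=ocean,
    )


def fea_by_timescale(triplet: ExperimentTriplet,
                     window_lengths: Sequence[int]) -> pd.DataFrame:
    """Timescale-resolved beta^BGC and gamma^RAD via sliding windows.

    For each window length (years), the approximate ratio estimators are
    evaluated over every delta spanning that window within the record;
    the mean and sample sd across window positions are reported.
    """
    window_lengths = list(window_lengths)
    if not window_lengths:
        raise ValueError("empty window set")
    years = triplet.cou.delta_cb.years
    n = len(years)
    rows = []
    for w in window_lengths:
        if w < 1 or w > n - 1:
            raise ValueError(f"window {w} exceeds record length {n - 1}")
        betas, gammas = [], []
        for i0 in range(0, n - w):
            i1 = i0 + w
            dca = triplet.bgc.delta_ca.values[i1] - triplet.bgc.delta_ca.values[i0]
            dcb = triplet.bgc.delta_cb.values[i1] - triplet.bgc.delta_cb.values[i0]
            if abs(dca) >= CO2_FLOOR_PPM:
                betas.append(dcb / dca)
            dta = triplet.rad.delta_ta.values[i1] - triplet.rad.delta_ta.values[i0]
            dcb_r = triplet.rad.delta_cb.values[i1] - triplet.rad.delta_cb.values[i0]
            if abs(dta) >= TEMP_FLOOR_K:
                gammas.append(dcb_r / dta)
        rows.append({
            "window_yr": w,
            "beta_bgc_mean": float(np.mean(betas)) if betas else np.nan,
            "beta_bgc_sd": float(np.std(betas, ddof=1)) if len(betas) > 1 else 0.0,
            "n_beta": len(betas),
            "gamma_rad_mean": float(np.mean(gammas)) if gammas else np.nan,
            "gamma_rad_sd": float(np.std(gammas, ddof=1)) if len(gammas) > 1 else 0.0,
            "n_gamma": len(gammas),
        })
    return pd.DataFrame(rows)
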