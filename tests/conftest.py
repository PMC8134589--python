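import numpy as np
import pytest

import carbonfeedback as cf

BETA_TRUE = 1.52  # GtC GtC^-1
GAMMA_STAR_TRUE = -10.9  # GtC K^-1

SIX_HARMONICS = (
    cf.Harmonic(3, 10.0, 0.10),
    cf.Harmonic(7, 6.0, 0.08),
    cf.Harmonic(15, 3.0, 0.05),
    cf.Harmonic(24, 2.0, 0.04),
    cf.Harmonic(40, 1.0, 0.03),
    cf.Harmonic(55, 0.5, 0.02),
)


@pytest.fixture(scope="session")
def harmonic_spec():
    """Six phase-locked harmonics with the feedback parameters of a
    weak-gain carbon cycle (beta = 1.52 GtC/GtC, gamma* = -10.9 GtC/K)."""
    return cf.HarmonicSpec(n_years=120, harmonics=SIX_HARMONICS,
                           beta_true=BETA_TRUE,
                           gamma_star_true=GAMMA_STAR_TRUE)


@pytest.fixture(scope="session")
def harmonic_system(harmonic_spec):
    return cf.gen_harmonic_system(harmonic_spec)


@pytest.fixture(scope="session")
def exp_cum_emissions():
    """Cumulative emissions from the exponential industrial-era flux,
    0.27 e^{0.018 t} ppm/yr over 168 years from 1850."""
    flux = cf.gen_exponential_emissions(168)
    zeros = flux.with_values(np.zeros(len(flux)))
    return cf.cumulative_emissions(cf.EmissionRecord(f_ff=flux, f_luc=zeros))


def co2_1pct(n_years=140, c0=285.0, start_year=1850):
    years = np.arange(start_year, start_year + n_years)
    vals = c0 * 1.01 ** np.arange(n_years)
    return cf.AnnualSeries(years, vals, units="ppm", kind="co2_concentration")


@pytest.fixture(scope="session")
def triplet_spec_nonlinear():
    """1pctCO2-style triplet with beta=1.5 GtC/GtC, gamma=-70 GtC/K and a
    nonlinear coefficient matching -11.22e-3 GtC/ppm/K."""
    return cf.TripletSpec(beta_true=1.5, gamma_true=-70.0,
                          f_true=-11.22e-3 / cf.M_GTC_PER_PPM,
                          s=3.0, co2_path=co2_1pct())


@pytest.fixture(scope="session")
def triplet_nonlinear(triplet_spec_nonlinear):
    return cf.gen_experiment_triplet(triplet_spec_nonlinear)


@pytest.fixture(scope="session")
def triplet_linear():
    """Triplet with f = 0: COU and BGC+RAD decompose additively."""
    spec = cf.TripletSpec(beta_true=1.5, gamma_true=-70.0, f_true=0.0,
                          s=3.0, co2_path=co2_1pct())
    return cf.gen_experiment_triplet(spec)
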