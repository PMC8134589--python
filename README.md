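# carbonfeedback

Estimation of climate-carbon cycle feedback parameters across timescales
from annual records of cumulative CO2 emissions, atmospheric CO2 and
global-mean temperature.

Land and ocean absorb more than half of anthropogenic CO2 emissions, and
how strongly that uptake responds to rising CO2 (the carbon-concentration
feedback, β, in GtC ppm⁻¹) and to warming itself (the carbon-climate
feedback, γ, in GtC K⁻¹) sets how much the carbon cycle amplifies
climate change.  This package implements a Fourier-analysis route to
those parameters for researchers working with observational records,
reconstructions or model output.

## The method in brief

Carbon-mass balance of the coupled system over any interval is

    ΔC_E = (1 + β) ΔC_A + γ* ΔT_A,        γ* = γ + f(β, γ) ΔC_A,

with ΔC_E cumulative emissions (GtC), ΔC_A atmospheric CO2, ΔT_A
temperature, and f a bilinear nonlinear coefficient.  Decomposing the
three series into harmonics, the per-harmonic amplitudes a_k, b_k, c_k
obey a_k = (1 + β) b_k + γ* c_k, so the ratios

    ζ_k = a_k / c_k  (= 1/TCRE at timescale N/k),
    η_k = b_k / c_k  (= 1/α at timescale N/k)

fall on the line ζ_k = (1 + β) η_k + γ* across timescales; OLS gives β
(slope − 1) and γ* (intercept).  From the airborne fraction
AF = ΔC_A/ΔC_E the feedback gain and amplification follow as

    g = 1 − 1/(AF (1 + β)),        G = 1/(1 − g) = AF (1 + β).

The package also provides: the quasi-equilibrium closed form
γ_k = −m(1 + β) η_k for preindustrial records (m = 2.12 GtC ppm⁻¹); a
three-parameter coupled CO2-temperature box model for self-consistency
checks; estimators for coupled/uncoupled (COU/BGC/RAD) experiment
triplets including the nonlinear term f(β, γ); and synthetic-data
generators with known ground truth for every stage.  See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Generate a phase-locked harmonic system with known feedbacks and
recover them through the full spectral pipeline:

```python
import carbonfeedback as cf

spec = cf.HarmonicSpec(
    n_years=120,
    harmonics=[cf.Harmonic(3, 10, 0.10), cf.Harmonic(7, 6, 0.08),
               cf.Harmonic(15, 3, 0.05), cf.Harmonic(24, 2, 0.04),
               cf.Harmonic(40, 1, 0.03), cf.Harmonic(55, 0.5, 0.02)],
    beta_true=1.52, gamma_star_true=-10.9)
c_e, c_a, t_a = cf.gen_harmonic_system(spec)

res = cf.SpectralFeedbackModel(c_e, c_a, t_a, band=(2, 90)).fit()
print(res.summary())
```

prints

```
================================================================
Spectral climate-carbon cycle feedback fit
================================================================
record: 1850-1969  (N = 120 yr)
Cross-timescale feedback fit  zeta_k = (1 + beta) eta_k + gamma*
  band: 2-90 yr   harmonics: 6   R^2 = 1.0000
  slope p     = 2.5200 +/- 0.0000
  beta        = 1.5200 +/- 0.0000 GtC GtC^-1  (3.2224 GtC ppm^-1)
  gamma*      = -10.9000 +/- 0.0000 GtC K^-1
  AF          = 0.415 +/- 0.010  (n = 6)
  gain g      = 0.0447   amplification G = 1.0468
================================================================
```

The slope of the ζ-η line is 1 + β (2.52 here, i.e. β = 1.52 GtC GtC⁻¹
or 3.22 GtC ppm⁻¹) and the intercept is γ* = −10.9 GtC K⁻¹ — the
generator's ground truth, recovered to eight decimals because the
phase-locked construction satisfies the amplitude identity exactly.  A
weak gain (g ≪ 1) means the carbon cycle barely amplifies warming at
these operating values.

The box-model round trip runs the loop the other way — simulate CO2 and
temperature from emissions with given (β, γ*), then re-estimate:

```python
import numpy as np
flux = cf.gen_exponential_emissions(168)          # 0.27 e^{0.018 t} from 1850
rec = cf.EmissionRecord(f_ff=flux, f_luc=flux.with_values(np.zeros(168)))
cum = cf.cumulative_emissions(rec)
params = cf.BoxModelParams(beta=1.52, gamma_star=-10.9, s=3.0, c0=285.0)
fit = cf.self_consistency_recovery(params, cum)
print(fit.beta, fit.gamma_star)   # 1.5169... -10.387...
```

The 168-year simulation ends near 404 ppm and +1.5 K, and the spectral
re-estimate lands within 0.3% (β) and 5% (γ*) of the inputs.

A `carbonfeedback` command-line tool drives the same stages from YAML
configs (`synth`, `estimate`, `pregamma`, `boxmodel`, `fea`); every run
writes a `report.json` plus a manifest with inputs, parameters and
tolerances.

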