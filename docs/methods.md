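# Methods

## The feedback framework

The coupled climate-carbon cycle is summarised by two response
parameters: the carbon-concentration feedback `beta` (change in combined
land+ocean carbon storage per unit change in atmospheric CO2; positive
for sinks) and the carbon-climate feedback `gamma` (storage change per
unit global-mean warming; negative when warming releases carbon).  With
a bilinear nonlinear term `f(beta, gamma)` coupling CO2 and temperature,
carbon-mass balance over an interval reads

    dC_E = (1 + beta) dC_A + gamma* dT_A,      gamma* = gamma + f dC_A,

where `dC_E` is cumulative anthropogenic emissions, `dC_A` the
atmospheric CO2 change and `dT_A` the temperature change (carbon in GtC
throughout; atmospheric CO2 in ppm converts through the fixed airborne
mass factor m = 2.12 GtC ppm^-1).

### Spectral estimation

Writing the three records as harmonic sums, the balance must hold
harmonic by harmonic, so the per-harmonic amplitudes satisfy
`a_k = (1 + beta) b_k + gamma* c_k`.  Dividing by the temperature
amplitude `c_k` gives, at each timescale `N/k`,

    zeta_k = (1 + beta) eta_k + gamma*,

with `zeta_k = a_k / c_k` the inverse transient climate response to
cumulative emissions (1/TCRE) and `eta_k = b_k / c_k` the inverse CO2
sensitivity of climate (1/alpha).  `beta` and `gamma*` follow from an
ordinary least-squares regression of `zeta_k` on `eta_k` across
timescales.  The regression is unweighted: no per-harmonic uncertainty
model is imposed.

Assumptions worth stating plainly:

- the balance is applied amplitude-wise, which is exact only when the
  three series are phase-locked harmonic by harmonic (equivalently, the
  phase-sum non-degeneracy of the derivation).  The synthetic generator
  exposes both a phase-locked mode (estimates recover the truth to
  round-off) and a random-phase mode (the identity holds for complex
  coefficients but not amplitudes) precisely so that this assumption can
  be stress-tested;
- the trend is treated as low-frequency wave content: spectra are
  computed with the mean removed but with **no detrending and no taper**
  (one-sided, 2/N amplitude convention);
- `beta` is assumed timescale-independent within the fit band.

For a quasi-equilibrium epoch with negligible emissions (`zeta_k ~ 0`)
the line collapses to the closed form `gamma_k = -m (1 + beta) eta_k`,
which converts reconstruction-based `eta_k` (ppm K^-1) into the
preindustrial carbon-climate feedback.

### Gain and amplification

The loop strength is the gain `g = -gamma* alpha / (1 + beta)`,
equivalently `g = 1 - 1/(AF (1 + beta))` with the cumulative airborne
fraction `AF = dC_A / dC_E`; amplification is `G = 1/(1 - g) =
AF (1 + beta)`.  Both routes are implemented and asserted equal on
consistent inputs (to 1e-10); `AF = 1/(1 + beta + alpha gamma*)` is a
further identity used in tests.  Error propagation follows the standard
rules: quadrature for flux sigmas (5% of fossil-fuel flux, 0.7 GtC yr^-1
for land-use change), `(1/n) sqrt(sum sigma_i^2)` for ensemble means of
per-member fits, plain sample sd for ensemble spread, and
relative-quadrature for the amplification ratio used to rescale an
allowable-emission budget.

### Box model

Validation uses a three-parameter closed loop solved year by year:

    C_A = C_0 + (dC_E - gamma* (T_A - T_0)) / ((1 + beta) m)
    T_A = T_0 + (s / ln 2) ln(C_A / C_0) + eps

with `s` the warming per CO2 doubling (K) and `eps` an optional
internal-variability residual.  The division by `(1 + beta) m` is the
only dimensionally consistent reading when `beta` is kept in its
GtC GtC^-1 form: the numerator is evaluated in GtC and the quotient
converted to ppm.  The two relations are simultaneous within a year and
are solved by damped fixed-point iteration (damping 0.5, tolerance
1e-10 ppm, at most 1000 sweeps, initialised from the previous year); the
logarithmic coupling is mild across the plausible parameter range, and
outputs vary continuously in `s` over 1.5-4.5 K.  On exit the per-year
conservation identity `dC_E = (1 + beta) m dC_A + gamma* dT_A` holds to
solver tolerance.

### Experiment-triplet (FEA) estimators

For COU/BGC/RAD experiment triplets the feedbacks are diagnosed by run
differences at a fixed horizon relative to an explicit reference year
(default: first record year; horizon default: last year):
`beta^BGC ~ dC_B^BGC/dC_A^BGC`, `gamma^RAD = dC_B^RAD/dT^RAD`,
`gamma^COU-BGC ~ (dC_B^COU - dC_B^BGC)/dT^COU` (this is `gamma*`), and
the nonlinear coefficient
`f = [dC_B^COU - (dC_B^BGC + dC_B^RAD)] / (dC_A^COU dT^COU)`.
Exact forms that retain the BGC run's small warming are provided
alongside the approximate ones; the exact COU-RAD beta is derived
directly from the bilinear response,
`(dC_B^COU dT^RAD - dC_B^RAD dT^COU)/(dC_A^COU dT^RAD)`, which is the
sign-consistent companion of the approximate form.  When land/ocean
splits are supplied the same formulas run per reservoir and the
components sum to the totals.  A sliding-window variant reports
`beta_k^BGC` and `gamma_k^RAD` as mean +/- sd over all windows of each
length, resolving timescale dependence.

## Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| m | 2.12 | GtC ppm^-1 | atmospheric carbon mass per ppm CO2; fixed |
| fit band | 2-90 | yr | inter-annual to multi-decadal band resolved by an industrial-length (~140-170 yr) record |
| "100-yr" band | 90-110 | yr | a discrete harmonic grid has no exact 100-yr line; the band mean over neighbouring harmonics stands in |
| sigma(F_FF) | 5% | of flux | conventional fossil-fuel inventory uncertainty (1 sigma) |
| sigma(F_LUC) | 0.7 | GtC yr^-1 | conventional land-use-change uncertainty (1 sigma) |
| emission growth | 0.27 e^{0.018 t} | ppm yr^-1 | exponential fit to industrial-era emissions from 1850; doubling time ~38.5 yr |
| s | 3.0 | K | mid-range warming per CO2 doubling (assessed range 1.5-4.5) |
| box damping / tol | 0.5 / 1e-10 | - / ppm | fixed-point stability and convergence |
| denominator floor | 1e-9 x max | - | harmonics with vanishing temperature amplitude have undefined ratios and are dropped with a warning |

## Synthetic data: what it emulates and what it does not

The generators reproduce the *structure* the estimators assume: harmonic
CO2/temperature covariation obeying the feedback identity with known
`(beta, gamma*)`; exponentially growing emissions; AR(1) internal
variability (marginal sd `sigma`, lag-1 correlation `phi`); firn-style
low-pass smoothing of ice-core-like records (implemented with the same
50%-cutoff smoother as the analysis); and bilinear COU/BGC/RAD triplets
with prescribed `(beta, gamma, f)` and a logarithmic temperature
response.  They do **not** emulate spatially resolved fields, ocean
circulation, volcanic or non-CO2 forcing, observational error structure,
or the red-noise spectrum of real internal variability beyond AR(1).
Passing tests therefore demonstrate that the estimators invert the model
class they are derived from (and are robust to the perturbations we
inject), not that real records satisfy that model class.

## Numerical choices

- **"N-year spline" smoothing** is implemented as an order-2 Butterworth
  filter run forward-backward (zero phase); the squared magnitude
  response is exactly 0.5 at the cutoff period, the defining property of
  the dendroclimatology convention.  The input mean is restored after
  filtering, so smoothing commutes with constant offsets.
- **Nearest-year resampling** assigns each irregular observation to its
  nearest calendar year (same-year collisions averaged, logged) and
  fills gaps by linear interpolation — the minimal gap rule.
- **Cumulative emissions** are a discrete running sum of annual fluxes
  (rectangle rule); the first value equals the first-year flux.
- **Estimation uses unsmoothed annual series**; smoothing exists for
  emulating published low-pass reconstruction products and for display.
- The **Nyquist harmonic** (k = N/2, even N) is phase-degenerate and is
  excluded from regressions.
- OLS is delegated to statsmodels; spectra to numpy's rfft; filtering to
  scipy.signal.

## Known limitations

- Amplitude-wise estimation degrades when CO2 and temperature harmonics
  decohere (random-phase regime); the fit is then biased in a
  phase-dependent way.  The random-phase generator mode exists to
  characterise this.
- `gamma*` from an emission-forced period conflates `gamma` with the
  nonlinear contribution `f dC_A`; the two are separable only with
  experiment triplets (or a quasi-equilibrium epoch where `dC_A ~ 0`).
- The box model has a single well-mixed atmosphere and no reservoir
  dynamics; it is a consistency device, not a projection tool.
- Hemispheric-mean temperature reconstructions are treated as given
  proxies for the global mean; no rescaling is applied.
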