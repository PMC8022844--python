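# mwdebye

Dielectric relaxation modelling of complex fluids (whole blood in the
1–100 MHz β-relaxation region being the motivating case) as a superposition
of Debye relaxators whose relaxation times follow a **Modified-Weibull**
distribution — a shape-2 Weibull (Rayleigh-type) density with a location
shift inside the exponential, renormalised by the constant

```
c(γ, η) = exp(−γ²/η²) + √π · (γ/η) · (1 + erf(γ/η))
```

The earlier spectroscopy literature used this density unnormalised under a
"Gaussian" label; `mwdebye` implements the corrected model, the exact
Gauss–Laguerre/erf series for the complex permittivity, a fast closed-form
approximation for the imaginary part, spectrum fitting, and synthetic
spectrum generation.

## What is in the box

| module | contents |
|---|---|
| `mwdebye.mwdist` | Modified-Weibull pdf/cdf/quantile/sampling, mixtures, normalising constant, the mislabelled-density mass |
| `mwdebye.kernels` | rational-kernel integrals `I_p(a, b)`: adaptive-quadrature oracle, Gauss–Laguerre node sums, segmented fallback; Gaussian power integral (erf and ₁F₁ routes); exponential-sum surrogate of `y²/(1+y²)` with validator and refitter |
| `mwdebye.permittivity` | `eps_real` / `eps_imag` / `eps_complex` / `eps_imag_ac` with `oracle`, `series` and (imaginary part) `approx` methods; Cole equation; legacy mis-normalised model and the amplitude-consistency conversion |
| `mwdebye.fitting` | nonlinear least squares in log-parameter space, multi-start, profile likelihood, identifiability/boundary diagnostics |
| `mwdebye.synthdata` | seeded synthetic spectra with relative-Gaussian or lognormal noise; the default whole-blood model (Δε = 8.993·10³, Ts = 1.139·10⁻⁷ s, τc = 2.434·10⁻⁸ s, σDC = 0.3204 S/m) |
| `mwdebye.io` / `mwdebye.cli` | CSV/JSON round trips and the `mwdebye` command |

## CLI

```bash
# evaluate a model on a frequency grid
mwdebye eval --config model.json --fmin 1e5 --fmax 1e9 --points 200 \
             --method series --out spectrum.csv

# simulate a noisy spectrum (reproducible per seed)
mwdebye simulate --config model.json --points 60 \
                 --noise relative_gaussian:0.01 --seed 7 --out synth.csv

# fit a measured spectrum
mwdebye fit --data synth.csv --template model.json --targets imag \
            --loss log10 --starts 8 --seed 17 --out fit.json

# check the published order-3 exponential-sum surrogate (~0.0185 @ y~0.546)
mwdebye validate-approx

# convert amplitudes between corrected and legacy normalisations
mwdebye convert --config model.json --delta-eps 8993
```

A model config is JSON:

```json
{
  "eps_inf": 10.0,
  "delta_eps": 8993.0,
  "sigma_dc": 0.3204,
  "eps0": 8.854e-12,
  "components": [
    {"label": "RBC", "r": 1.0, "ts_seconds": 1.139e-7, "tau_c_seconds": 2.434e-8}
  ]
}
```

Spectrum CSVs carry the header `frequency_hz,eps_real,eps_imag[,eps_imag_ac]`
('#' lines are comments).

## Numerical notes

* The `series` permittivity method escalates Gauss–Laguerre orders
  (16 → 256) until two successive orders agree; where `1 + a² + b²` is large
  the plain node sums cannot resolve the short time scale at any feasible
  order, and the same closed-form integrand is integrated over geometric
  segments instead. The quadrature `oracle` is available everywhere and
  shares no code with the series path.
* No approximate route exists for the real part: only the imaginary-part
  surrogate keeps its error within a usable range.
* `eps0` defaults to 8.854·10⁻¹² F/m for bit-compatibility with the published
  worked example; override it in the model config if desired.
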