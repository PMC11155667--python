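# Methods

## Lineshape conventions

All peak profiles are FWHM-parameterized and follow the **area
convention**: `amplitude` is the integrated area, not the height. This
makes intensities directly comparable across lineshape families (a
Gaussian and a Lorentzian with equal amplitude carry equal spectral
weight). The closed forms used:

* Gaussian: `σ = fwhmg / (2√(2 ln 2))`; height at center
  `A·2√(ln2/π)/fwhmg`.
* Lorentzian: half-width `γ = fwhml / 2`; height `2A/(π·fwhml)`.
* Voigt: `A·Re[w(z)]/(σ√(2π))` with `z = (x−c+iγ)/(σ√2)`, `σ` from
  `fwhmv`, and `γ = gamma`, defaulting to `fwhmv/2` when the attribute
  is absent.
* pseudo-Voigt: `A·[η·L + (1−η)·G]` with **one shared FWHM** (`fwhmv`)
  and explicit mixing fraction `η` (default 0.5). A two-width
  parameterization (separate `fwhmg`/`fwhml`) is a legitimate
  alternative convention; the single-width form was chosen because it
  keeps `fwhmv` interpretable as the profile's width and `η` as a pure
  shape parameter.

Steps rise monotonically from 0 to `amplitude` with inflection at
`center` and width scale `sigma`; the cumulative Gaussian
`A/2·(1+erf((x−c)/(σ√2)))` is the standard edge-jump model.

Defaults when a model document omits attributes: `amplitude = 1.0`,
`center = 0.0`, width `= 1.0`, bounds `(−∞, +∞)`, `vary = true`.

## Constraint expressions

Expressions are parsed with Python's `ast` into a strict whitelist:
numbers, parameter names, `+ − * / **`, unary minus, parentheses, and
one-argument calls to `sin, cos, exp, log, sqrt, abs`. Anything else
(attribute access, subscripts, arbitrary calls, strings, lambdas) is
rejected as a security error before evaluation — constraint strings
from input files can never execute code. Evaluation is topological over
the dependency graph with registry-order tie-breaks; cycles raise an
error naming the cycle. A parameter with an expression is never free:
its value is recomputed at every residual evaluation, so ties hold
exactly along the whole optimization path and at the optimum
(bitwise-equal tied centers in simultaneous fits).

## Optimization and uncertainties

χ² is the plain unweighted residual sum of squares (the package's
input format carries no per-point measurement errors). The default
optimizer is `scipy.optimize.least_squares` with the Trust Region
Reflective method and tolerances `ftol = xtol = gtol = 1e−12` (tight
enough that noiseless truth recovery is accurate to ≲1e−8 relative and
refitting from an optimum is a no-op). Levenberg–Marquardt is accepted
(`method="lm"`; it silently upgrades to TRF when finite bounds are
present, since LM cannot honor them). Any other method name is
forwarded to `scipy.optimize.minimize` on the χ² objective; for those
methods no covariance or standard errors are reported.

The covariance over free parameters is the SVD pseudo-inverse of
`JᵀJ` scaled by reduced χ²; standard errors are the square roots of
its diagonal. Singular directions (parameters the data do not
constrain) are truncated at the usual `eps·max(m,n)·s₁` threshold.

Profile confidence intervals step one parameter away from its best
value (geometric step schedule scaled by its standard error), refit all
others, and compare constrained to unconstrained χ² with the F
statistic `F = (χ²_fixed/χ²_best − 1)(N−k)`; the interval bound is the
Brent root of `P(F) = level` with levels 0.6827/0.9545/0.9973 for
1/2/3σ. A side that reaches a parameter bound before bracketing is
reported as not converged (`None`) rather than fabricated.

Non-convergence of the optimizer is data (`success = False`), not an
exception — the statistics tables are still produced and the CLI exits
nonzero after printing them.

## Fit statistics

`AIC = N·ln(χ²/N) + 2k` and `BIC = N·ln(χ²/N) + k·ln N` (least-squares
log-likelihood form, the convention of common fitting backends), so
`BIC − AIC = k(ln N − 2)` identically; χ² is floored at 1e−250 before
the logarithm so a numerically perfect fit yields a finite documented
sentinel. Regression metrics delegate to scikit-learn; R² uses raw
sums of squares while the explained variance score uses biased
variances, hence `EVS ≥ R²` always, with equality broken by a
systematic offset. Descriptive statistics and Pearson correlation use
pandas with linearly interpolated quantiles at 10% steps; correlation
entries involving a zero-variance series are flagged undefined rather
than reported as zero. The residual trend is an OLS line with a
pointwise t-distribution band at the requested level (default 95%).

In simultaneous mode AIC/BIC/χ² are computed on the stacked residual
with k = free parameters of the expanded model (they are global
quantities of the joint model), while regression metrics are computed
per spectrum against its own slice of the fit.

## Simultaneous fitting

Only `center` attributes are tied across spectra by default: peak
energies are physical properties of the system and should not drift
between replicate or related measurements, while intensities and
broadenings legitimately vary (concentration, temperature,
instrument). `tie_widths=True` additionally ties `fwhmg/fwhml/fwhmv/
sigma`. Spectra may live on different grids; residuals are evaluated
per native grid with no interpolation. Free-parameter count of the
expanded model is `n·P − (n−1)·C` (P parameters per spectrum, C tied
centers).

## Synthetic data

The generator is the package's test substrate: every spectrum is the
exact composite of declared components plus homoscedastic Gaussian
noise from a stated seed (normalized absorption data carry no error
bars, and the fit statistic is unweighted, so constant-variance noise
is the matching assumption).

`make_xas_pair` emulates a normalized transition-metal K-edge
measurement: 146 points on 7105–7130 eV; two weak pre-edge Gaussians
(areas 0.055/0.069, FWHM ≈ 1.2–1.3 eV) below three rising-edge
Gaussians (areas 0.30–0.45, FWHM 1.6–2.0 eV) and a unit cumulative-
Gaussian edge jump (σ = 1.2 eV at 7124 eV); the second spectrum scales
all amplitudes by 1.2 with identical energies. Default noise sd is
0.005 (≈0.5% of the edge jump). The truth constants are synthetic
package constants chosen so the model is locally identifiable — widths
below feature spacing and the edge inflection above the last peak —
which is what makes the generator usable as its own oracle: from a
truth-value initialization, fitted centers cover the truth within
±3·stderr in ≥90% of seeds, and noiseless recovery is exact to machine
precision. What the generator does *not* emulate: multiplet structure,
energy-dependent backgrounds, heteroscedastic counting noise,
monochromator glitches. Passing tests therefore demonstrate estimator
correctness and calibration under the stated noise model, not
robustness to every artifact of real beamline data.

The model-selection study uses a generic 6-Gaussian truth (evenly
spaced centers 3…18 on a 400-point 0–21 grid, FWHM 1.5, amplitudes
0.7–1.2, noise sd 0.02) and candidate models of 4–7 Gaussians
initialized with evenly spaced centers. BIC's `3·ln N ≈ 18` penalty
per extra peak dominates the ≈χ²₃ improvement available from fitting
noise, so the minimum lands at the true complexity.

## Lock reports

The lock payload (input echo, data columns, results) is canonicalized
as key-sorted JSON with floats rendered at 17 significant digits —
enough to round-trip IEEE doubles — and hashed with SHA-256. The
timestamp is excluded so re-exports of identical science share one ID.
Verification is independent of key order and whitespace because the
hash is computed over the canonical form, not the file bytes; a file
that fails to parse raises a parse error, which is deliberately
distinct from a failed hash comparison.

## Problem sizes

Test and acceptance runs use the scales above: 50-seed coverage on the
292-point pair (~15 s), 25-seed × 4-model BIC ladders on 400-point
spectra (~6 s). These sizes give binomial uncertainties of a few
percent on the reported rates, comfortably resolving the ≥90%/≥80%
claims.

## Known limitations

* Unweighted χ² only; no per-point errors or robust losses.
* Covariance-based errors are asymptotic; strongly correlated
  components (overlapping peaks on an edge) can undercover — profile
  intervals are provided for exactly that case.
* Profile confidence intervals assume a single-spectrum unconstrained
  model; simultaneous fits report covariance errors only.
* Expression grammar is arithmetic-only by design (no conditionals or
  inequality constraints).
* 1-D spectra only; no 2-D planes or instrument convolution beyond the
  Voigt kernel.
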