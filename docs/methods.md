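# Methods

This note records the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## 1. Proxy committees (module `riacarb.brnn`)

Each target variable (pH on the total scale; total alkalinity, TA, in
µmol kg⁻¹) gets its own committee of ten feed-forward networks with
tanh hidden layers and a linear output. The eleven inputs are latitude,
longitude, depth, temperature, salinity, phosphate, nitrate, silicate,
decimal year, and the week-of-year mapped to the unit circle,
(sin, cos)(2π·week/52). A period of 52 is used because the week index
is integer-valued; ISO week 53 is folded into 52 before encoding.
Dissolved oxygen is deliberately not an input (its reliability in
routine monitoring series is poor), and the chosen predictors are
expected to carry the biological signal instead.

Inputs and targets are standardized to zero mean and unit variance on
the training split; the scalers are stored with each member, which
makes the fit invariant to affine rescaling of any predictor column.

**Training** is Levenberg–Marquardt on the Bayesian-regularized
objective F = β·E_D + α·E_W (E_D the sum of squared residuals in
standardized units, E_W the sum of squared weights and biases). The
damping parameter μ starts at 5·10⁻³, is divided by 10 after an
accepted step and multiplied by 10 until F decreases; failure to find a
downhill step below μ = 10¹⁰ terminates training. After each accepted
step the hyperparameters are re-estimated by the evidence framework in
the Foresee–Hagan convention, starting from α = 0, β = 1:

    γ = N_w − 2α·tr(H⁻¹),   α ← γ / (2·E_W),   β ← (N − γ) / (2·E_D),

with H = 2β·JᵀJ + 2α·I the Gauss–Newton Hessian. tr(H⁻¹) is computed
from the eigenvalues of JᵀJ, i.e. tr(H⁻¹) = Σᵢ 1/(2βλᵢ + 2α), which is
robust to rank deficiency (λᵢ clipped at 0). Convergence is declared
when the relative changes of E_D and E_W and the change of γ all fall
below tolerance, or the gradient's max-norm does; note that F itself is
useless as a progress measure because at the evidence fixed point
β·E_D + α·E_W ≡ N/2 identically.

On a linear model (empty hidden-layer list, used for verification) the
fixed point of these updates reproduces the brute-force maximizer of
the log marginal likelihood over the ridge parameter λ = α/β to better
than 0.1% (tested against an independent grid/refine oracle).

**Members and splitting.** One random 90/10 split is shared by all ten
members, so a single held-out set scores both individual members and
the committee; members differ only in their initialization seeds
(Glorot-uniform weights, zero biases), fanned out deterministically
from the ensemble seed via `numpy.random.SeedSequence`. The test-set
size is round(0.10·N) with halves rounded away from zero. The committee
output is the arithmetic mean of the members' de-scaled outputs; by
convexity its MSE never exceeds the members' average MSE. Full-size
architectures default to [28, 10] hidden units for pH and [40] for TA;
all analysis drivers in this repository use scaled-down committees
([14, 5] and [20], with 1500/1000 labeled training rows) that keep the
complete chain under a minute per target while preserving behaviour —
the pH committee still tests at the observation-noise floor.

## 2. Carbonate transforms (module `riacarb.carbonate`)

* Hydrogen-ion concentration: \[H⁺\] = 10^(9−pH) nmol kg⁻¹, a strict
  monotone bijection; inputs outside (0, 14) raise, which catches unit
  mix-ups. Working in \[H⁺\] expresses acidification as an absolute
  concentration change rather than a logarithmic one.
* Ratio normalization NTA = TA·35/S, guarded by a configurable salinity
  floor (default S ≥ 5): toward fresh water the ratio method diverges
  and is known to over-correct. On data whose true TA-S slope α is
  below mean(TA)/mean(S) the ratio method provably flips the sign of
  the NTA-vs-S slope — the over-correction signature, reproduced as a
  test.
* Empirical normalization NTA = TA + α·(35 − S), with α the OLS slope
  of TA on S (orthogonal regression was considered and rejected: the
  definition of α is a predictive, not an errors-in-variables, slope).
  α is fitted per station × depth stratum and pooled ("global"); the
  pipeline default applies the global α because the per-stratum slopes
  vary little — on the synthetic world they span ≈ 42–44 against a
  planted 46.7 (the small attenuation comes from salinity observation
  noise and the committee's smoothing of TA).

## 3. Trend extraction (module `riacarb.trends`)

Per stratum × variable series (decimal-year axis, ≥ 8 points spanning
≥ 2 years):

1. **Outlier rule.** Points with |y − ȳ|/s > 3 (s the sample standard
   deviation, ddof = 1) are removed in a single pass, on the raw
   series, before any fitting. A residual-based variant would also be
   defensible; the raw-series reading is the implemented default and
   `z_max` is configurable. If s = 0 nothing is removed.
2. **Seasonal model.** y(t) = A·sin(ωt + φ) + B·t + C with ω *fixed*
   at 2π rad yr⁻¹. Freeing ω makes the fit non-convex and is not needed
   to remove an annual cycle; with ω fixed the model is linear in
   (a, b, B, C) via a·sin(ωt) + b·cos(ωt), and A = √(a²+b²),
   φ = atan2(b, a), normalized to [0, 2π). The design is built on a
   mean-centered time axis for conditioning and the phase mapped back.
3. **Second-stage regression.** The fitted seasonal component is
   subtracted and the deseasonalized series regressed on time; the
   reported B, its confidence interval (Student-t, n−2 df, 95% by
   default — whether report-style ± values are SEs or CIs is a genuine
   ambiguity, so the level is explicit and configurable), r² and
   two-sided p-value all come from this second stage. Trends with
   p > 0.01 are flagged non-significant (asterisked in the compact
   report layout).
4. **Degeneracies.** A rank-deficient design (all points at one phase)
   or a too-short span raises a per-series error, which `trend_table`
   records as a flagged row instead of aborting. A series whose total
   variation is below 10⁻⁵ relative to its mean magnitude is treated as
   constant and reported with p = 1: there is no noise against which to
   test a slope, and every physically measurable series (pH resolved to
   ~2·10⁻⁴ relative at best) sits far above this floor.

Noiseless data generated from the model are recovered to ≤ 10⁻⁹ in all
coefficients; with A = 0 the procedure reduces exactly to ordinary
linear regression. Monte-Carlo calibration (500 weekly 25-year
replicates, σ = 0.02) puts the 95% CI coverage at 93.6%.

## 4. Synthetic world (module `riacarb.world`)

The generator emulates the data situation of a long-running coastal
observing system, with every planted quantity exposed in
`SyntheticWorldSpec`:

* **Geometry.** Six stations spaced along the ría axis inside
  42–42.35° N, 9.11–8.6° W; depth bins 0–5, 5–10, 10–15 m represented
  by their midpoints; training samples scattered uniformly over the box
  and over 0–50 m.
* **Time bases.** Training: irregular times uniform over 1976.5–2018.7
  (an optional seasonal acceptance bias is available but defaults to
  off, since the real cruise distribution is unknown). Prediction:
  every 7th day from 1 Jan 1995 through end 2020 (1357 weeks), complete
  per station × bin unless a gap fraction is set.
* **Upwelling covariation.** A latent driver u(t) = sin(2πt + φ_u) +
  ε_u with weekly weather noise ε_u ~ N(0, 0.5), shared by all stations
  within a week. Nutrients load positively on u, temperature and pH
  negatively — high-nutrient, cold, low-pH upwelled water — so the
  carbonate signal is genuinely predictable from the hydrography, not
  just from the clock. pH loads −0.05 on the seasonal part and −0.08 on
  the weather part, giving weekly pH scatter ≈ 0.04, a realistic
  magnitude for an upwelling embayment.
* **Planted trends.** The pH trend is a smooth field,
  base − 0.0035 pH yr⁻¹ with a longitude gradient (inner stations more
  negative, down to ≈ −0.0040 at the surface) and a depth attenuation
  (+2.4·10⁻⁵ per m), keeping all station/depth values inside the
  −0.0042…−0.0025 pH yr⁻¹ band typical of such systems. TA is
  700 + 46.7·S + 1.0·(t − 1995) µmol kg⁻¹ with S carrying seasonality,
  a freshening gradient toward the inner ría, and river/rain weather
  (σ = 0.25).
* **Noise.** Additive, independent, zero-mean Gaussian per variable
  (pH 0.02, TA 5 µmol kg⁻¹, S 0.02, T 0.1 °C, nutrients 0.05–0.3
  µmol kg⁻¹ — instrument-grade magnitudes). Nutrients are clipped at 0;
  with the default means this is a rare-tail event only.

What the generator does **not** contain: physical circulation, river
discharge events, benthic fluxes, dissolved oxygen, autocorrelated
observation errors, or measurement drift. Tests passing on this world
therefore demonstrate correctness of the estimation machinery under
its stated assumptions, not skill on real coastal data.

## 5. Pipeline and reproducibility (module `riacarb.pipeline`)

Stages: data → train both committees → weekly projection → \[H⁺\] and
NTA (global-α empirical method by default) → outlier-filtered trend
fits, ordered station-major, depth-minor. A single master seed fans out
via `SeedSequence` to world generation, the split and all member
initializations; reruns with the same config reproduce every CSV byte
for byte. Artifacts (tables, serialized models as JSON, α table, trend
tables, manifest with SHA-256 checksums and wall times) land in the
configured output directory; any stage failure aborts with the stage
name and persists the partial manifest. Real-data mode accepts
training/prediction CSVs in the documented column layout instead of a
world spec.

## 6. Known limitations

* **End-to-end CI coverage.** The trend CI is computed from the
  projected series alone, so it captures weekly scatter but *not* the
  committee's own trend-estimation error, which shifts all strata of a
  given run coherently (the ten members share one split and one
  training table), nor the mild attenuation from extrapolating ~2 years
  past the training period's end with saturating activations. In
  repeated synthetic worlds the recovered per-stratum pH trends carry a
  seed-level error of ~1–3·10⁻⁴ pH yr⁻¹ against CI half-widths of
  ~2.5·10⁻⁴, so nominal 95% intervals cover the planted truth in only
  ≈ 75–80% of stratum × seed cases even though the sign and magnitude
  of every trend are recovered. Any study projecting trends through
  fitted proxy models inherits this: the honest uncertainty on B needs
  a model-level term (e.g., retraining replicates), which is outside
  the reported procedure.
* **ω fixed at the annual frequency.** Semi-annual or longer-period
  components are absorbed into the residuals; an optional grid
  refinement of ω exists as a config hook but is off by default.
* **No autocorrelation-robust errors.** Weekly residuals are treated as
  iid in the second-stage regression; Newey–West-type corrections are
  out of scope.
* **Committee diversity is initialization-only.** Members see identical
  data; bootstrap resampling per member would widen ensemble spread but
  contradicts the single-test-set reporting convention adopted here.
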