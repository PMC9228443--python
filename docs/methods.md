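# Methods

## Scope and model overview

The package covers the two quantitative layers of a tight-ultrafiltration
(1 kDa MWCO) fractionation of native agave fructans:

* an empirical layer — response-surface models of the separation factor
  (SF) and solute flux (Ji) over the operating box, and their
  desirability-based optimization;
* a mechanistic layer — a film-theory limiting-flux ODE model of the
  batch concentration mode, predicting per-solute retentate and permeate
  concentration profiles.

Out of scope by design: membrane cleaning and hydraulic-recovery
procedures, chromatographic (HPLC-SEC) peak processing (only its
summarized composition tables are consumed), fouling resistance and
osmotic-pressure corrections, and the plant hardware/PLC layer.

## Domain conventions

Compositions are mass fractions of Fc (DP > 10), FOS (DP 3–10) and MD
(DP 1–2) that must sum to 1; percentage input is accepted at the I/O
boundary (`Composition.from_percent`) but violations never renormalize
silently — rescaling is only available through the explicit
`Composition.normalized`.  SF uses only the FOS:Fc ratio; MD is carried
but never enters the metric.  Internally all fluxes are SI (m·s⁻¹,
m³·s⁻¹); the conventional kg·h⁻¹·m⁻² appears only at reporting
boundaries (factor 3600, and permeate density 1000 kg·m⁻³ where a mass
flux must become a velocity — a dilute-solution convention that is
logged when used).

## Response-surface layer

**Coding.** Factors are mapped onto the coded cube by
`x = (X − center)/half-range` with centers (45 °C, 3 bar, 100 kg·m⁻³)
and half-ranges (15, 2, 50).  The 3-factor Box-Behnken design is the
standard 12 edge midpoints plus replicated centers (4 by default).

**Fitting.** OLS in coded units on a linear (main effects) or full/
reduced quadratic basis, via `statsmodels`.  The reduced SF model drops
the `x1:x2` and `x2:x3` interactions and *refits* (coefficients are
re-estimated, not zeroed); for a Box-Behnken design the remaining
linear/interaction columns are orthogonal so those estimates are
unchanged anyway, which is exploited as a closed-form test oracle
(coefficient = half the +1/−1 response-mean gap).  An actual-unit
coefficient view is produced by exact polynomial re-expansion of the
coded fit — never by refitting — so predictions agree between unit
systems to rounding error.

One deliberate re-interpretation: the published linear flux model is
presented as an actual-unit equation, but its coefficients
(1.16, 0.3938, 0.5238, 0.3625) are dimensionally impossible in actual
units (0.3938 × 60 °C alone would exceed every measured flux ~10-fold)
and they match the coded-orthogonal closed form on the design data
exactly.  The package therefore treats that model as coded-unit, which
reproduces its reported R² (75.01%) precisely.

**ANOVA.** Partial (Type-III) sums of squares per 1-df term,
`SS_j = β_j² / [(XᵀX)⁻¹]_jj`; for the orthogonal linear and interaction
columns this coincides with sequential SS.  Pure error comes from the
center replicates, lack of fit is the residual remainder and is tested
against pure-error MS; term F-tests use residual MS.  p-values come from
the F distribution and are reported only — no automatic term selection
is performed (which terms to drop is taken as user input).

**Desirability.** Each response is rescaled by
`d = clip((Y − L)/(H − L), 0, 1)` with anchors defaulting to the
observed min/max of the response column (user-overridable), and the
overall score is the weighted geometric mean.  The study's narrative
describes "adding" individual desires, but its reported two-response
optimum (0.72) is reproduced only by the geometric mean
(√(0.781·0.665) = 0.721), which is also the standard convention; the
geometric mean is therefore implemented.  A consequence worth noting:
with the K-th-root normalization, a response saturated at d = 1 drops
out of the *argmax* but still lifts the overall value to the K-th root
of the remaining product — the optimizer's location, not its score,
reduces to the remaining responses.

The optimizer is deterministic: L-BFGS-B launched from every node of a
9³ coded lattice, best result kept, then a 0.01-step coded-grid descent
that also serves as a stationarity certificate.  The objective is
piecewise-smooth (clipping introduces flat regions), which the dense
multi-start handles; a brute-force lattice evaluation is kept as a test
oracle.

Reported optima differ from the published ones in the third significant
digit (e.g. SF-optimal temperature 46.63 °C vs 46.81 °C reported;
D = 0.947 vs 0.94).  The published values come from a commercial DOE
package whose internal coefficient precision is unknown; refitting the
printed design table at full precision is the assumed source, and the
package reports its own full-precision results.

## Limiting-flux batch simulator

**Model.**  Film theory with a limit (gel) concentration:
`J_lim = k·ln(C_lim/(Ro·C) − (1−Ro)/Ro)`, which is algebraically
`k·ln[(C_lim−C_P)/(C−C_P)]` under the apparent-rejection definition and
reduces to `k·ln(C_lim/C)` at total rejection.  The flux is clamped to
exactly 0 at and beyond `C = C_lim` (the log argument crosses 1 there
identically).  Assumptions: constant apparent rejection per run, one
shared boundary layer (a single J_lim for both solutes), negligible
osmotic pressure and fouling, solute concentration uniform across tank,
feed and retentate (batch concentration mode — only the permeate flow
enters the balances; feed/retentate flows are bookkeeping fields).

The driving concentration defaults to the long-chain (Fc) bulk
concentration with the Fc rejection, since Fc dominates the polarization
layer; a `total` option (C_Fc + C_FOS) is provided.  The per-solute
balance `dC_i/dt = (C_i/V)·J_lim·A·Ro_i` is the implemented form; a
dimensionally inconsistent intermediate form of the same balance
(`dC/dt = −J_lim·A·C_P`) appears in some write-ups and is treated as a
typographic step, not implemented.

**Numerics.**  `scipy.integrate.solve_ivp` (LSODA, rtol 1e-8,
atol 1e-10) on the state (V, C_Fc, C_FOS) augmented with cumulative
permeate masses (dM_i/dt = C_P,i·J_lim·A) so the solute mass audit
closes at solver accuracy rather than at the accuracy of a posteriori
quadrature.  Terminal events: V ≤ 5% of V₀ (default, configurable — no
canonical final volume exists for the pilot runs) and J_lim ≤ 0.  A feed
already at or above C_lim returns a single-point trajectory flagged
`flux_zero`.  Output is the dense solution evaluated on a uniform
601-point grid (the raw adaptive steps are too sparse to interpolate
well); profile queries use monotone cubic (PCHIP) interpolation, which
reproduces grid points exactly and cannot overshoot.

Useful analytic identities used as test oracles: `dC/C = −Ro·dV/V`
integrates to `C = C₀(V₀/V)^Ro` exactly; total retention gives
`C·V = C₀V₀`; an independent fixed-step RK4 integration at dt = 0.1 s
agrees with the adaptive solution to better than 1e-5 relative on a
1-hour reference run.

**Reference scenario sizes.**  Tests and examples use a 100 L charge
(V₀ = 0.1 m³) on the 0.5 m² module with the calibrated parameters —
a few simulated hours per run, integrating in well under a second.  The
initial volume of the original validation runs is not recorded, so their
absolute SSE values are not reproducible and are not targeted; the SSE
machinery itself is exercised on synthetic runs where truth is known.

## Calibration

`(k, C_lim)` come from the log-linear inversion `J = a + b·ln C`,
`k = −b`, `C_lim = exp(−a/b)`; a non-negative slope is a model violation
and raises.  The inversion is exact for total rejection, which is how
the calibration experiment is interpreted (the flux curve is measured on
the whole fructan mixture against total concentration).  The fitted
`C_lim` zeroes `limiting_flux` to machine precision — a deliberate
cross-module consistency invariant.

The rejection correlation over feed FOS:Fc ratio is linear for FOS
(endpoints: Ro 0.55 at ratio 0.23, 0.185 at 0.39) and constant for Fc
(mean 0.795 of the observed 0.76–0.83 band, whose orientation vs ratio
is not recorded); both forms are per-solute selectable.  Predictions are
clipped to [0, 1] with a logged warning, since clipping means the
correlation is being extrapolated.

## Synthetic data

Generators are pure functions of (parameters, seed) and every generator
composed with its estimator is the identity on truth at zero noise:

* **Batches:** Fc% ~ U(60, 75), MD% ~ N(10, 1) truncated to [7, 13] by
  redraw, FOS% the complement — reproducing the ~10% MD level and the
  linear FOS–Fc trade-off of commercial batches, and bracketing (not
  point-matching) the observed FOS:Fc range 0.23–0.44.
* **Design responses:** truth polynomial + additive N(0, σ); σ = 0.07 in
  tests, the scale of the measured surface's residual standard deviation.
* **Flux curves:** model flux × (1 + N(0, CV)); multiplicative because
  fluxes span an order of magnitude across 50–250 kg·m⁻³.
* **UF time series:** simulated trajectory + additive N(0, σ) per
  observation (σ = 2–3 kg·m⁻³ in tests, a plausible assay scatter).

No instrument-level structure (chromatogram shape, drift,
heteroscedastic assay error, fouling-induced flux decline) is emulated,
so green tests certify the estimators against their own model class —
they bound numerical and statistical error, not model misspecification
on real plant data.

## Known limitations

* Constant-rejection and shared-boundary-layer assumptions break down as
  the retentate concentrates toward C_lim; the simulator will happily
  integrate there, but predictions lose physical meaning before the
  volume event fires at aggressive v_min settings.
* Whether the FOS transport should carry its own rejection inside the
  flux law is ambiguous in the source formulation; the shared-J_lim
  choice is documented, not asserted as the only reading.
* The design-table machinery is specialized to 3 factors; no general
  k-factor BBD/CCD catalog is intended.
* One published validation prediction (SF 1.53 at 60 °C, 5 bar,
  50 kg·m⁻³) is inconsistent with the published polynomial itself
  (direct evaluation ≈ 2.03); it is flagged in the `reproduce` report as
  un-benchmarked rather than chased.
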