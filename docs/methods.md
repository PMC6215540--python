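# Methods

This note records the models the package implements, the assumptions
behind them, the parameter and design choices that were genuinely open,
and what the synthetic-data round trips do and do not demonstrate.

## Models

**Quadratic tight-binding isotherm.** ΔA(L₀) = (ΔA_max/2E₀)·{E₀+L₀+K_d −
√[(E₀+L₀+K_d)² − 4E₀L₀]}. Used for NADP⁺ binding followed as a flavin
absorbance change (467 nm in the reference experiment), where K_d
(~21 µM) is comparable to the enzyme concentration (50 µM) and ligand
depletion cannot be neglected. The total enzyme concentration is treated
as known and held fixed in the fit; co-fitting E₀ with ΔA_max and K_d on
a single titration is poorly identified. As E₀ → 0 the expression
reduces to the rectangular hyperbola ΔA_max·L₀/(K_d+L₀) (property-tested
at E₀ = K_d/10⁴).

**Michaelis–Menten and competitive inhibition.** v = k_cat·S/(K_m(1+I/K_i)+S),
with turnover (s⁻¹) as the internal velocity unit; raw µM/s rates are
converted using the enzyme concentration. Initial velocities from A340
progress curves use the NADPH difference extinction coefficient
Δε340 = 6.22 mM⁻¹cm⁻¹ and a linear-regression window over the first 10%
of the total absorbance change or the first 30 s, whichever is shorter
(the window is configurable; initial-rate linearity, not a standard, sets
it). Inhibition data are fit globally across all (S, I) records with
shared k_cat, K_m, K_i — never by per-level K_m,app regression — though
the Lineweaver–Burk signature K_m,app = K_m(1+I/K_i) is verified as an
invariant. Catalytic efficiency errors use first-order quadrature,
treating the k_cat and K_m errors as independent.

**pH bell.** Y = Y_H/(1 + H/K_a,low + K_a,high/H) with H = 10^(−pH),
maximal at the mean of the two pKas. The fit runs on the velocity scale
(the data are velocities); fitting log Y instead changes the implicit
weighting, not the model, and is not the default. The parameters are
named by limb (pKa_low/pKa_high) rather than by chemical assignment: the
fit localizes the two limb midpoints and takes no position on which
group must be protonated or deprotonated. A pKa outside the measured pH
range is flagged as extrapolated.

**Transients.** Reduction of the oxidized flavin at 443 nm under
pseudo-first-order conditions (coenzyme ≥ 7-fold over enzyme, checked
and flagged) is fit by a single exponential; the observed rate saturates
as k_obs = k_red[NADPH]/(K_d+[NADPH]). Reoxidation at 440 nm is fit with
1 or 2 exponential phases chosen by corrected AIC (ties to the simpler
model); a chosen two-phase fit with < 3× rate separation is flagged
poorly identifiable. The default trace windows are 1 s for reduction and
75 s for reoxidation. The k_obs-vs-[O₂] relation is an ordinary
least-squares line whose slope is the bimolecular rate constant.
If k_obs shows < 1% relative spread across the coenzyme grid the
hyperbola is unidentifiable (saturated, high-affinity regime) and only
a limiting rate is reported, flagged `concentration_independent`.
The kinetic isotope effect is the ratio of the protiated and deuterated
fitted rate constants with quadrature-propagated uncertainty.
Note: for the O₂ bimolecular constant the source characterization prints
two values in different places (49 vs 40.1 ± 5.1 mM⁻¹s⁻¹); the module
always reports the constant fitted from the supplied data and the
reference parameter set carries the tabulated 40.1.

**Redox potentiometry (dye equilibration).** Enzyme and reference dye
(indigo disulfonate, E°′ = −116 mV at pH 7.0, n = 2) are reduced
together quasi-statically; the enzyme couple is read at the dye's
isosbestic point (458 nm) and the dye at 610 nm where the flavin redox
states do not absorb, each by linear interpolation between fully
oxidized/reduced endpoint absorbances. At equilibrium both couples share
one potential, so log₁₀(E_red/E_ox) = n_e(E°_e−E°_d)/0.0592 +
(n_e/n_d)·log₁₀(D_red/D_ox). All logs are decadic (the 0.0592/n slope
form); the Nernst slope is fixed at its 25 °C value and overridable, not
recomputed from temperature. Points where either couple is < 10% or
> 90% reduced are excluded from the regression (retained and flagged):
the log-ratios diverge at the endpoints and would dominate an unweighted
OLS. The 10–90% window is a package choice, configurable.

**Extinction coefficient by SDS release.** The flavin is freed with SDS,
quantified against free FAD (ε450 = 11,300 M⁻¹cm⁻¹), corrected for the
dilution incurred by the SDS addition, and the intact-holoenzyme
absorbance divided by that concentration.

## Catalytic-cycle simulator

`synthetic_data.simulate_cycle` integrates mass-action ODEs for six
enzyme states — E_ox, E_ox·NADPH, FADH⁻·NADP⁺, C4a-peroxyflavin·NADP⁺,
Criegee adduct, C4a-hydroxyflavin·NADP⁺ — plus free NADPH/NADP⁺/O₂/
ketone/product pools, with LSODA at rtol 1e−9 / atol 1e−12. Enzyme and
nicotinamide totals are conserved to better than 1e−8 relative (tested).
Observables are Beer–Lambert projections with per-species extinction
coefficients.

Default parameters (the reference study conditions):

| parameter | default | basis |
|---|---|---|
| koff_NADPH | 1000 s⁻¹ | rapid-equilibrium binding assumption |
| kon_NADPH | koff/121 µM⁻¹s⁻¹ | K_d(NADPH) = 121 µM |
| k_red | 59 s⁻¹ | limiting flavin-reduction rate |
| k_O2 | 40.1 mM⁻¹s⁻¹ | tabulated bimolecular O₂ constant |
| k_uncouple | 0.47 s⁻¹ | peroxyflavin decay without substrate |
| k_sub | 0.05 µM⁻¹s⁻¹ | chosen so the ketone step is non-limiting at 200 µM |
| k_release | 6.8 s⁻¹ | rate-limiting product/NADP⁺ release, set so saturating turnover ≈ 2.1 s⁻¹ |
| k_collapse | 0 (lumped) | no resolvable Criegee signal; set > 0 to resolve it |

Spectral defaults: oxidized flavin ε443 = 12,200 M⁻¹cm⁻¹; reduced and
hydroxyflavin ≈ 0 at 443 nm; C4a-peroxyflavin ε366 = 8,000 M⁻¹cm⁻¹ (a
documented assumption — the intermediate's spectrum is not pinned down);
NADPH ε340 = 6,220 M⁻¹cm⁻¹. All configurable.

Two emergent behaviours matter for testing. First, with O₂ = 0 the
reduced state is absorbing and the 443 nm trace approaches a single
exponential at the hyperbolic rate; at a 20-fold coenzyme excess the RMS
deviation from the best single exponential is ~0.05% of the amplitude
(bounded at < 0.1% in the tests), dominated by the fast
binding-equilibration phase rather than substrate depletion. Second,
because binding is fast but not infinitely fast, the effective
saturation constant of the simulated k_obs is K_d·(1+k_red/koff) — about
6% above the binding K_d with the defaults — so simulator-derived rates
sit 2–3% below the ideal hyperbola; round-trip tests use a 5% tolerance
for this comparison, while the direct hyperbola round trips are exact to
1e−4 relative.

## Other generators

The Massey generator solves, for each value of delivered reducing
equivalents R, the conservation condition n_e·C_e·f_e(E) + n_d·C_d·f_d(E)
= R for the common potential E by bisection, where f is the n-electron
Nernst reduced fraction; its points lie on the analytic log-log line to
< 1e−10 (tested). With couples 50 mV apart only a minority of an evenly
spaced schedule falls in the joint 10–90% window, so the default
schedule is dense (150–200 points) — mirroring the minute-by-minute
spectral sampling of a 2 h equilibration.

Velocity, titration, pH and progress-curve generators evaluate the
closed-form models and add seeded Gaussian noise; titrations pin the
first (zero-ligand) point to ΔA = 0 since it defines the baseline. All
generators are bit-reproducible under a fixed seed.

What the synthetic data do **not** emulate: instrument dead time and
mixing artefacts, photobleaching, baseline drift, correlated noise,
inner-filter effects, and dilution during sequential titrant additions
(neglected by default, as in the reference workflow). Passing round
trips therefore demonstrate estimator correctness and identifiability
under the stated noise model, not robustness to instrument systematics.

## Fitting engine

Levenberg–Marquardt via lmfit, unweighted least squares (no weighting is
assumed for the source data), ftol/xtol 1e−12 with an iteration cap of
500 (configurable). Standard errors are asymptotic, from the inverse
curvature at the optimum — comparable to what commercial fitting
software reports — with bootstrap deliberately out of scope.
Initialization heuristics are scale-free and deterministic: Michaelis
k_cat ← 1.2·max(v), K_m ← S at half-max; isotherm ΔA_max ← max(ΔA), K_d ←
L₀ at half-max; bell Y_H ← max(v) with limb pKas from half-max
crossings; exponentials from log-linear regression on peeled residuals,
plus a second start derived by rate-splitting the one-phase optimum
(two-phase fits of rising traces otherwise risk a rate-collapse local
minimum); the lower-RSS start wins. Data are pre-sorted
deterministically so fits are invariant to row order. Noiseless
generator→fit round trips recover parameters to 1e−6 relative
(property-tested), and a dense grid-search oracle never finds a lower
RSS than the optimizer.

Replicate design in the noisy recovery tests: stopped-flow observed
rates are in practice averages of several traces per concentration, so
the noisy k_obs round trips use two determinations per concentration
with σ = 2% of k_red; under that design the recovered constants fall
within the reference ± bounds in ≥ 95% of 200 seeded replicates.

## Problem sizes

All analyses run on desk-scale inputs chosen to match the reference
experiments: 6–36-point steady-state grids, 500-point transients over
1 s, 150–200-point equilibration schedules, seven-concentration
saturation profiles. The full test suite and the acceptance script each
complete in well under a minute on one CPU.

## Known limitations

- One-electron (semiquinone) intermediates are not modelled; the Nernst
  analysis assumes clean n-electron couples.
- The midpoint potential is measured at pH 7.0 while kinetics run at
  pH 7.5; no pH adjustment of the potential is defined or applied.
- The bell fit does not assign protonation chemistry to its limbs.
- Uncertainties compare central estimates only; whether the reference ±
  values are asymptotic errors or replicate SDs is not resolved, so no
  statistical equivalence test against them is attempted.
- The cycle simulator treats O₂ and ketone as well-mixed pools and does
  not model the Criegee adduct spectrally.
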