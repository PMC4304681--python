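# Methods

## Mass-action equilibrium core

A model is a list of components and complex species; each species carries an
integer stoichiometry vector ν over components and a cumulative association
constant β (dimensionless against the 1 M standard state, stored and fitted
as log₁₀β). Free components are implicit species with log₁₀β = 0 and
ΔH = 0. Units throughout: molar concentrations, kcal·mol⁻¹ energies,
Svedberg sedimentation coefficients, R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹.

Given totals T, the solver finds free concentrations f with

    T_k = f_k + Σ_s ν_sk β_s Π_j f_j^ν_sj .

It iterates Newton steps on x = ln f — which keeps every concentration
positive by construction and handles affinities from picomolar to millimolar
— with the exact Jacobian ∂T_k/∂x_j = δ_kj f_j + Σ_s ν_sk ν_sj c_s, steps
clipped to 6 natural-log units, and per-point bisection backtracking when a
step fails to reduce the worst relative mass-balance error. Components with
zero total are eliminated (their species get zero concentration) before
iterating; points are solved in vectorized batches grouped by zero-pattern.
Convergence targets 1e-12 relative mass balance (the practical fixed point
of double precision); anything not below 1e-9 after 200 iterations raises
`ConvergenceError` rather than returning a degraded state.

Parameterization is always logarithmic: log₁₀β for constants and a log₁₀
cooperativity factor, never linear K, so the optimizer sees comparably
scaled, sign-free variables. Microscopic two-identical-site input (per-site
constant k, cooperativity α) is converted on construction to macroscopic
constants using the exact statistical factors K₁ = 2k and K₂ = αk/2; other
site symmetries must be supplied explicitly (per-species `stat_factor` or
pre-multiplied log₁₀β). Because no universal convention exists for quoting
cooperativity, ΔΔG is reported in both conventions side by side: the raw
stepwise difference ΔG₂ − ΔG₁, and −RT ln α with the statistical factor 4
removed, which is zero for independent identical sites.

## Technique forward models

All techniques share the same solved equilibrium state and the same
nuisance-parameter vocabulary: per-component concentration-error factors γ
(bounded, linkable across experiments) and incompetent fractions in [0, 1]
replace the traditional fractional "n" — the stoichiometry itself is fixed
by the model and never rescaled. Effective totals are
nominal · γ · (1 − incompetent).

**ITC.** Injections follow perfusion-cell bookkeeping: injection i of
volume v dilutes the pre-injection cell content by (1 − v/V₀) and adds
syringe material at v/V₀. With cell enthalpy content H = V₀ Σ_s ΔH_s[s],
the modeled raw heat is

    q_i = H(i) − H(i−1) + (v_i/V₀)(H(i) + H(i−1))/2 ,

the last term being the mean-value correction for reaction enthalpy carried
out with the displaced volume. Heats are normalized per mole of injectant;
a per-mole heat of dilution and a baseline are local parameters. Two- and
three-component cells (displacement/competition titrations) work unchanged
since the solver is general.

**SPR.** Steady-state surface binding is a 1:1 Langmuir response
R = R_max·f/(K_d,surf + f) + baseline in the *free* analyte concentration
of the injected mixture. The competition mode first calibrates
(R_max, K_d,surf, baseline) on a direct dilution series, then uses the
surface purely as a probe of free analyte in solution mixtures; responses
outside the calibrated free-concentration range warn about extrapolation.
Multivalent surface models are rejected outright — surface heterogeneity
makes them unreliable and they are out of scope.

**SV isotherms.** s_w is the signal-weighted average
Σ ε_s c_s s_s / Σ ε_s c_s over free and complex species, with complex
signal coefficients additive over components (ε_complex = Σ ε_k ν_k).
Boundary-shape quantities (amplitudes, s_fast of the reaction boundary) are
deliberately excluded: their formulas live at the boundary-model level,
below the isotherm abstraction this package works at.

**Fluorescence anisotropy.** Population-weighted mean over probe-containing
species; equal quantum yields are the default (making intensity weighting
equal population weighting), with optional per-species yield ratios as
locals.

**Generic linear signal.** baseline + Σ coeff_s·c_s covers quenching,
absorbance (Beer–Lambert), NMR chemical-shift isotherms and similar.

## Global fit

The objective is χ²_glob = Σ_e w_e Σ_i ((f_ei − y_ei)/σ_ei)². Default
weights are w_e = 1 (maximum-likelihood weighting for correct σ); an
"equal-experiment" preset w_e = mean(N)/N_e is available for very
dissimilar data-set sizes, and the weight-scan tool quantifies how much any
conclusion depends on this choice. The reduced form divides by
Σ w_e N_e − P with P the number of free parameters after link resolution
(each linked group counts once), so E[χ²_r] ≈ 1 under correct σ and unit
weights; the same N_eff and P conventions are reused by every F-statistics
computation so thresholds and χ²_r are mutually consistent.

Parameters are addressed by path (`species.AB.log10beta`,
`exp[3].gamma.A`); per-experiment locals are registered automatically with
technique defaults when a data set is added, and locals sharing a link
group are fitted as one value. Bounds are enforced by smooth transforms
(logit for two-sided, shifted log for one-sided), never by penalties, so
all optimizers work unconstrained. Marquardt–Levenberg runs on the residual
vector with forward-difference Jacobians (relative step 1e-6); simplex
restarts once from its converged point; simulated annealing is a seeded
exponential-cooling Metropolis walk (mandatory seed) polished by simplex.
The reported χ² is never above the starting value — a worse optimizer
outcome returns the start.

## Statistics

Covariance is χ²_r · (JᵀJ)⁻¹ with J the central-difference Jacobian of the
weighted residuals at the optimum; singular curvature falls back to the
pseudo-inverse with a warning. Profile projections fix one or two
parameters on a grid (log-spaced for K-type parameters, linear for ΔH and
s), re-optimize the remaining free parameters at each node (nodes whose
re-optimization fails are masked invalid, not interpolated), and threshold
with χ²_crit = χ²_min(1 + p/(N_eff−P)·F(p, N_eff−P; CL)). Monte-Carlo
intervals refit synthetic replicates (best-fit model + Gaussian noise at
each point's σ) from the best-fit start — a deliberate, mildly
anti-conservative choice that keeps 500 replicates at desk scale; >10%
replicate failures abort.

The consistency test partitions experiments by subgroup label and, for each
subgroup, compares the joint fit against split fits (subgroup alone +
remainder alone) through the extra-sum-of-squares ratio

    F = ((χ²_joint − χ²_own − χ²_rest)/p) / ((χ²_own + χ²_rest)/(N_tot − 2p)) ,

referred to F(p, N_tot − 2p). An earlier candidate — evaluating the
subgroup's χ² under parameters transferred from the leave-out fit — was
measurably anticonservative (~10% type-I at a nominal 5%) because the
transferred parameters carry their own estimation noise; the split-fit form
measures ~5% over simulated consistent suites (flags within one suite are
correlated, so calibration error bands are taken over suites, not
individual subgroup tests). The transfer χ² is still reported as a
diagnostic. Only global parameters cross-validate; per-experiment locals
stay at their provided values.

Information reports perturb one parameter by 1σ, hold all globals fixed,
re-optimize free locals, and rank experiments by their χ² increase — e.g.
only calorimetric data respond to an enthalpy perturbation.

## Design tools

Concentration maps evaluate a technique's signal, the fractional signal
contribution of each complex, the fractional population of a reference
component, or a differential sensitivity |∂signal/∂log p| (central
differences; log-type parameters stepped additively, others in ln) on a 2-D
log₁₀-total grid of two components over a fixed background. Feasibility
cropping keeps nodes where Σ c_k/stock_k ≤ 1 — mixtures made in one step
from stocks plus buffer; serial dilution planning is out of scope — and
optionally where the mapped signal lies within user bounds; the mask only
ever removes nodes, and larger stocks never remove feasible ones.
Trajectories are log-equidistant along the Euclidean segment in the map's
log₁₀ coordinates; recipes are v_k = c_k·V/stock_k with buffer filling to
V, exact by construction. In-silico data sets add i.i.d. Gaussian noise at
user-set per-point σ (the noise model is a choice — real ITC/SV errors are
heteroscedastic and the file format carries per-point σ for that reason)
and come back as first-class experiments; tags for boundary-level data (SE
profiles, SV boundaries) are recognized but rejected as unsupported.

## The bundled demonstration suite

`make_fixture_suite` generates a two-site hetero-association
A + B ⇌ AB ⇌ ABB with log₁₀β = 7 and 13 (Kd 100 nM and 1 µM — mild
negative cooperativity beyond statistics), stepwise enthalpies −10 and −6
kcal/mol, species s-values 3.5/2.0/4.6/5.4 S, observed in 11 data sets
across 4 techniques: one SPR competition isotherm (B over a calibrated
surface, A as competitor), four 20-injection ITC titrations of B into A at
2–20 µM cell concentrations (c-values ~20–200), five SV s_w series (three
dilution lines at ratios 1:1/1:2/2:1 across 50 nM–20 µM and two titration
lines at fixed 2 µM partner), and one anisotropy titration of A into 100 nM
probe-labeled B. Per-experiment σ is 1% of the signal magnitude (0.05 S
and 0.002 anisotropy as absolute floors of the same order), i.i.d.
Gaussian, deterministic under a seed — suites regenerate byte-identically.
The anisotropy member is a direct titration so the whole suite shares one
two-component model; a three-component competition anisotropy is exercised
separately in the tests.

What passing on this suite shows — and what it does not: the generator
draws from the fitted model family with exactly known, well-specified σ, so
χ²_r ≈ 1 and 3σ-recovery demonstrate the correctness of the forward models,
objective, optimizer and error propagation, not robustness to the model
misspecification, correlated baselines, or concentration errors of real
instruments (γ/incompetent-fraction locals exist for those, but the demo
truth sets them to their ideal values).

## Numerical choices and problem sizes

Profile grids for the correlation-breaking comparison span ±8σ (capped at
±3 log units) around each fit's own best values with 31×31 nodes, with the
enthalpies fixed at their fitted values so each node is a direct χ²
evaluation; areas count inside-nodes times cell area in (log₁₀K)² units and
are comparable across fits because the coordinates, not the grids, are
shared. The consistency-test calibration runs 200 three-subgroup 1:1
anisotropy suites (8 points each); Monte-Carlo validation uses 500
replicates of a 12-point linear-response isotherm against the closed-form
least-squares covariance. These sizes keep the full validation run in the
low minutes on one core while leaving every comparison statistically
meaningful.

## Known limitations

No kinetic (time-domain) modeling, no sedimentation-boundary or
sedimentation-equilibrium profile fitting, no thermogram peak integration,
no protonation/salt/temperature-linked models, no Bayesian posterior
sampling; plotting is limited to exporting plot-ready tables and matrices.
Monte-Carlo refits from the best-fit start can modestly understate
intervals for strongly nonlinear surfaces; use profile projections there.
The one-step mixing feasibility model ignores pipetting minimum volumes.
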