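# gmma — global multi-method analysis of protein interactions

Solution biophysicists routinely measure the same binding equilibrium with
several techniques — isothermal titration calorimetry (ITC), surface plasmon
resonance (SPR), sedimentation velocity (SV), fluorescence anisotropy — and
each technique alone often cannot resolve the parameters of a multi-site
system: single-method fits leave the binding constants of the individual
sites strongly correlated. `gmma` fits **one** thermodynamic interaction
model **simultaneously** to all of these data sets. Because the techniques
probe different projections of the same equilibrium (heats, free
concentrations, transport, rotational mobility), the joint fit breaks the
parameter correlations and pins down stoichiometry, affinity, cooperativity
and enthalpy far better than any single method.

## The model

An interaction model is a set of components (A, B, …) and complex species,
each with an integer stoichiometry vector, a cumulative association constant
β (stored as log₁₀β against a 1 M standard state), a molar enthalpy ΔH, a
sedimentation coefficient s, an anisotropy, and molar signal coefficients.
At any total composition the free concentrations solve the mass-action
balance

    c_tot,k = c_free,k + Σ_s ν_sk · β_s · Π_j c_free,j^ν_sj

(damped Newton iteration on log free concentrations, converged to < 1e-12
relative mass-balance error). Technique-specific forward models project the
solved state into each experiment's observable space, and the fit minimizes
the weighted global chi-square

    χ²_glob = Σ_e w_e Σ_i ( (f_ei − y_ei) / σ_ei )²

over global thermodynamic parameters {p_glob} and per-experiment nuisance
parameters {p_loc} (concentration-error factors, incompetent fractions,
baselines, surface calibrations …), which can be bounded and linked across
experiments. Optimizers: Marquardt–Levenberg, simplex, seeded simulated
annealing. Post-fit statistics include the covariance/cross-correlation
matrix, profile (error-surface) projections with F-statistics confidence
contours, Monte-Carlo intervals, scans over the experiment weights {w_e},
a cross-validation consistency test that flags mutually inconsistent data
sets, and per-experiment information reports. A design module maps signal,
species populations and parameter sensitivity over the two-dimensional
log-concentration plane, crops it to what your stocks can reach, samples
log-equidistant titration trajectories, emits pipetting recipes, and
simulates complete in-silico data sets for experiment planning.

Microscopic two-identical-site models are converted to macroscopic
constants with the exact statistical factors K₁ = 2k, K₂ = αk/2;
cooperativity free energies ΔΔG are reported both as the raw stepwise
difference and with the statistical factor removed (−RT ln α).

## Worked example

`examples/two_site_gmma.py` generates the bundled demonstration suite — a
two-site system A + B ⇌ AB ⇌ ABB (Kd1 = 100 nM, Kd2 = 1 µM, ΔH = −10 and
−6 kcal/mol stepwise) observed in 11 data sets across 4 techniques at 1%
noise — and fits the four global parameters:

```
global chi2 = 161.90, reduced chi2 = 1.079 (154 points, 4 free parameters)

parameter                 fitted      +-1sigma   truth
species.AB.log10beta         7.0212     0.0115     7.00
species.ABB.log10beta       12.9994     0.0161    13.00
species.AB.dH               -9.9463     0.0329   -10.00
species.ABB.dH             -16.0980     0.0507   -16.00

Kd1 = 9.524e-08 M, Kd2 = 1.051e-06 M
dG1 = -9.58 kcal/mol, dG2 = -8.15 kcal/mol
cooperativity ddG (macroscopic convention)      = 1.42 kcal/mol
cooperativity ddG (statistical factors removed) = 0.60 kcal/mol
```

Reduced χ² ≈ 1 means the single model describes all four methods jointly at
their stated noise; every parameter lands within a few σ of the generating
truth. `examples/error_analysis.py` shows the point of the exercise: the
95% joint (K₁, K₂) confidence region of the global fit is ~10× smaller in
area than that of a single ITC titration fitted alone. The other examples
cover titration planning (`plan_titration.py`) and outlier-data flagging
(`check_data_consistency.py`).

The same workflows are scriptable from the shell:

```bash
gmma simulate demo --seed 1          # write the bundled demo session
gmma fit demo/session.yaml --out demo/out
gmma stats demo/session.yaml --project species.AB.log10beta --montecarlo 200
gmma design map design.yaml --out map.tsv
```

All file formats are plain text (tab-separated data with `#` headers, YAML
model/session files, molar concentrations) and round-trip losslessly.

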