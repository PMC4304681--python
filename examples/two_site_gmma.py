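"""Global multi-method fit of the bundled two-site demo suite.

Generates the 11-dataset suite (1 SPR competition isotherm, 4 ITC
titrations, 5 sedimentation-velocity s_w series, 1 anisotropy titration)
for the system A + B <-> AB <-> ABB at 1% noise, fits the four global
thermodynamic parameters by Marquardt-Levenberg, and prints the recovered
binding constants, free energies, cooperativity and enthalpies with their
1-sigma uncertainties.
"""

import numpy as np

from gmma import (
    covariance_and_correlation,
    delta_g_from_log10beta,
    fit_global,
    make_fixture_suite,
    two_site_summary,
)

suite = make_fixture_suite(seed=1)
fit = fit_global(
    suite.experiments, suite.model, suite.start_parameters,
    method="marquardt-levenberg",
)
cov, corr, names = covariance_and_correlation(fit)
sigma = dict(zip(names, np.sqrt(np.diag(cov))))

print(f"global chi2 = {fit.chisq:.2f}, reduced chi2 = {fit.chisq_reduced:.3f} "
      f"({fit.n_eff:.0f} points, {fit.n_free} free parameters)")
print()
print("parameter                 fitted      +-1sigma   truth")
for name in names:
    val = fit.free_dict()[name]
    print(f"{name:25s} {val:9.4f}  {sigma[name]:9.4f}  {suite.truth[name]:7.2f}")

b1 = fit.free_dict()["species.AB.log10beta"]
b2 = fit.free_dict()["species.ABB.log10beta"]
summ = two_site_summary(b1, b2)
print()
print(f"Kd1 = {summ['Kd1']:.3e} M, Kd2 = {summ['Kd2']:.3e} M")
print(f"dG1 = {summ['dG1']:.2f} kcal/mol, dG2 = {summ['dG2']:.2f} kcal/mol")
print(f"cooperativity ddG (macroscopic convention)      = "
      f"{summ['ddG_macroscopic']:.2f} kcal/mol")
print(f"cooperativity ddG (statistical factors removed) = "
      f"{summ['ddG_corrected']:.2f} kcal/mol")
print()
print("per-experiment quality (rmsd in each technique's own signal units):")
for pe in fit.per_experiment:
    print(f"  {pe['name']:24s} {pe['technique']:16s} n={pe['n']:3d} "
          f"rmsd={pe['rmsd']:.4g}")
print()
print("The reduced chi2 near 1 says the model describes all four methods "
      "jointly at their stated noise; the fitted log10 constants and "
      "enthalpies land within a few sigma of the generating truth.")
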