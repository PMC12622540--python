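"""Decompose a multi-environment trait into mean, linear and nonlinear
plasticity by Finlay-Wilkinson regression, and check recovery against the
generator's truth.
"""

import numpy as np

from plastmap import plasticity, simulate

cfg = simulate.SimConfig(n_accessions=300, n_snps=300, n_envs=6, seed=42,
                         clip_percent_traits=False)
geno = simulate.simulate_genotypes(cfg)
env = simulate.simulate_environments(cfg)
pheno, truth = simulate.simulate_phenotypes(geno, env, cfg)

dec = plasticity.fit_fw_ls(pheno, "GCR")
print(dec.to_frame().head().to_string(index=False))
print(f"\nenvironment effects h_j: {np.round(dec.h, 2)} (sum "
      f"{dec.h.sum():.1e})")

r_slope = np.corrcoef(truth.b_true, dec.linear_plasticity - 1)[0, 1]
r_mean = np.corrcoef(truth.g_true, dec.g)[0, 1]
print(f"recovery: corr(true slope dev, estimated) = {r_slope:.3f}; "
      f"corr(true mean effect, estimated) = {r_mean:.3f}")

# the Bayesian fit agrees with least squares on well-identified data
gibbs = plasticity.fit_fw_gibbs(pheno, "GCR", n_iter=1500, burnin=500,
                                seed=1)
r = np.corrcoef(gibbs.linear_plasticity, dec.linear_plasticity)[0, 1]
print(f"Gibbs vs LS linear plasticity: corr = {r:.4f}")
print("\nA slope above 1 marks an accession that over-responds to good "
      "(hot) environments; the log residual variance is its departure "
      "from a straight-line response (nonlinear plasticity).")
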