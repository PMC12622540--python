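"""Generate a synthetic multi-environment panel and inspect its structure.

The generator emulates a rice diversity panel scored for a chalkiness-like
percent trait over five site-years: LD-blocked SNPs, temperature
covariates, and phenotypes from the reaction-norm model
y_ij = mu + g_i + (1 + b_i) h_j + eps_ij.
"""

import numpy as np

from plastmap import simulate

cfg = simulate.SimConfig(n_accessions=200, n_snps=500, seed=7)
geno = simulate.simulate_genotypes(cfg)
env = simulate.simulate_environments(cfg)
pheno, truth = simulate.simulate_phenotypes(geno, env, cfg)

print(f"panel: {geno.n_accessions} accessions x {geno.n_snps} SNPs, "
      f"{cfg.n_envs} environments")
print(f"MAF range: {geno.maf.min():.3f} - {geno.maf.max():.3f}")
print("\nenvironments (grain-filling temperatures, degC):")
print(env.to_string(index=False))
print("\ntrue environment effects h_j (trait units, sum to zero):")
print(np.round(truth.h_true, 2))
print("\ngenerating variance components:",
      {k: round(v, 2) for k, v in truth.vc_true.items()})
print(f"clipped to [0,100]: {100 * truth.clipped_fraction:.1f}% of values")
print("\nHotter environments push the trait up (h_j tracks tmean); the "
      "variance components set broad-sense heritability near 0.7.")
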