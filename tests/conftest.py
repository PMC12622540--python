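import numpy as np
import pandas as pd
import pytest

from plastmap import simulate


@pytest.fixture(scope="session")
def small_panel():
    """200 accessions x 300 SNPs x 5 environments, default trait model."""
    cfg = simulate.SimConfig(n_accessions=200, n_snps=300, seed=3)
    geno = simulate.simulate_genotypes(cfg)
    env = simulate.simulate_environments(cfg)
    pheno, truth = simulate.simulate_phenotypes(geno, env, cfg)
    return {"cfg": cfg, "geno": geno, "env": env, "pheno": pheno,
            "truth": truth}


@pytest.fixture(scope="session")
def recovery_panel():
    """The packaged parameter-recovery fixture: 300 x 6, unclipped."""
    cfg = simulate.SimConfig(
        n_accessions=300, n_snps=500, n_envs=6, seed=42,
        clip_percent_traits=False,
    )
    geno = simulate.simulate_genotypes(cfg)
    env = simulate.simulate_environments(cfg)
    pheno, truth = simulate.simulate_phenotypes(geno, env, cfg)
    return {"cfg": cfg, "geno": geno, "env": env, "pheno": pheno,
            "truth": truth}


@pytest.fixture()
def toy_2x2():
    """Noiseless 2x2 FWR table: mu=10, g=(-1,1), h=(-2,2), b=(-0.5,0.5)."""
    mu, g, h, b = 10.0, (-1.0, 1.0), (-2.0, 2.0), (-0.5, 0.5)
    rows = []
    for i, acc in enumerate(["a1", "a2"]):
        for j, env in enumerate(["e1", "e2"]):
            y = mu + g[i] + (1.0 + b[i]) * h[j]
            rows.append((acc, env, "GCR", y))
    return pd.DataFrame(rows, columns=["accession", "environment", "trait",
                                       "value"])


def balanced_gxe(n_lines, n_envs, reps, vg, ve_env, vge, ve, seed,
                 trait="T", mu=10.0):
    """Balanced crossed-design phenotypes with known variance components."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0, np.sqrt(vg), n_lines)
    b = rng.normal(0, np.sqrt(ve_env), n_envs)
    ab = rng.normal(0, np.sqrt(vge), (n_lines, n_envs))
    eps = rng.normal(0, np.sqrt(ve), (n_lines, n_envs, reps))
    rows = []
    for i in range(n_lines):
        for j in range(n_envs):
            for k in range(reps):
                rows.append(
                    (f"L{i:03d}", f"E{j}", trait,
                     mu + a[i] + b[j] + ab[i, j] + eps[i, j, k])
                )
    pheno = pd.DataFrame(rows, columns=["accession", "environment", "trait",
                                        "value"])
    # realised (sample) variances of the drawn effects: the estimable
    # targets for a variance-component fit given these finite level sets
    abc = ab - ab.mean(axis=1, keepdims=True) - ab.mean(axis=0, keepdims=True) \
        + ab.mean()
    realized = {
        "Vg": a.var(ddof=1),
        "VE": b.var(ddof=1),
        "VGE": (abc**2).sum() / ((n_lines - 1) * (n_envs - 1)),
        "Ve": eps.var(ddof=1),
    }
    return pheno, {"g": a, "e": b, "ge": ab, "realized": realized}
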