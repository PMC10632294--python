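import pytest

from clonepart import grm as grm_mod, simdata, varcomp

# segregation-class mix matching the default generator (k near 0.7)
SEG_PROBS = {"AaxAa": 0.1, "AaxAA": 0.225, "AAxAa": 0.225, "Aaxaa": 0.225, "aaxAa": 0.225}


@pytest.fixture(scope="session")
def small_map():
    return simdata.default_linkage_map(120)


@pytest.fixture(scope="session")
def family200(small_map):
    """One pure full-sib family of 200 offspring, all genotyped, with truth."""
    parents = simdata.simulate_parent_genotypes(small_map, SEG_PROBS, seed=101)
    fam = simdata.simulate_family(
        simdata.FamilyConfig(n_offspring=200, n_genotyped=200, seed=102), small_map, parents
    )
    gv = simdata.assign_genetic_values(
        fam.genotypes,
        simdata.ArchitectureConfig(sigma_u2=1.0, r_a=0.75, n_causal_add=80, n_causal_dom=80),
        seed=103,
    )
    return fam, gv


@pytest.fixture(scope="session")
def small_fitted_trial(small_map):
    """A 60-offspring trial plus its model-2 REML fit (shared to keep tests fast)."""
    parents = simdata.simulate_parent_genotypes(small_map, SEG_PROBS, seed=201)
    fam = simdata.simulate_family(
        simdata.FamilyConfig(n_offspring=60, n_genotyped=60, seed=202), small_map, parents
    )
    gv = simdata.assign_genetic_values(
        fam.genotypes, simdata.ArchitectureConfig(sigma_u2=1.0, r_a=0.75, n_causal_add=60, n_causal_dom=60), seed=203
    )
    p = grm_mod.parental_allele_frequencies([parents["mother"].dosage, parents["fatherA"].dosage])
    g = grm_mod.vanraden_g(fam.genotypes.calls.astype(float), p, ids=fam.genotypes.ids)
    site = simdata.SiteSpec(name="t", n_blocks=4, master_blocks=((1, 2), (3, 4)), block_grid=(8, 10))
    noise = simdata.NoiseConfig(sigma_v2=0.05, sigma_r2=0.5, sigma_s2=0.25, rho_c=0.7, rho_r=0.7)
    trial = simdata.simulate_trial(site, gv.u, noise, seed=204, genotype_ids=fam.genotypes.ids)
    data = varcomp.TrialData.from_trial_frame(trial.frame, grm=g)
    fit = varcomp.fit(data, model=2, n_starts=1, compute_se=True)
    return {"trial": trial, "data": data, "fit": fit, "grm": g, "noise": noise, "gv": gv}
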