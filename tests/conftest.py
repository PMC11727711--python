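"""Shared fixtures: simulated cohorts reused across test modules.

All simulations are seeded; session scope keeps the heavier cohorts built
once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from plumagemap import assoc, cross_sim, variant_io


@pytest.fixture(scope="session")
def gwas_cohort() -> cross_sim.SimulatedCohort:
    """Default-conditions intercross panel (8 chromosomes, 400 F2)."""
    cfg = cross_sim.default_config(seed=11, missing_rate=0.02)
    return cross_sim.breed_cross(cfg)


@pytest.fixture(scope="session")
def f2_subset(gwas_cohort):
    """F2-only view of the GWAS cohort: (dataset, phenotype labels, sex)."""
    meta = gwas_cohort.metadata
    mask = (meta["generation"] == "F2").to_numpy()
    idx = np.flatnonzero(mask)
    ds = variant_io.VariantDataset(
        gwas_cohort.dataset.variants,
        gwas_cohort.dataset.genotypes[idx],
        [gwas_cohort.samples[i] for i in idx],
    )
    return ds, meta.loc[mask, "phenotype"].to_numpy(), meta.loc[mask, "sex"].to_numpy()


@pytest.fixture(scope="session")
def gwas_scan(f2_subset):
    """Null LMM fit and per-variant scan on the F2 subset."""
    ds, phen, sex = f2_subset
    y = assoc.encode_phenotype(phen)
    G = assoc.grm(ds.genotypes)
    pcs = assoc.pca_covariates(G, 3)
    X = assoc.build_covariates(len(y), sex=sex, pcs=pcs)
    fit = assoc.fit_null_lmm(y, X, G)
    res = assoc.scan(ds, y, X, fit)
    return {"dataset": ds, "y": y, "X": X, "G": G, "fit": fit, "result": res}


def make_region_cohort(seed: int, n_f2: int = 300, noise_free: bool = True):
    """Small two-chromosome cohort focused on a 0.4-Mb candidate region.

    The region carries ~50 ancestry-informative SNPs; an exaggerated
    recombination rate supplies recombinants in the short interval.
    """
    positions = np.sort(
        np.unique(np.r_[np.linspace(400_000, 800_000, 50).astype(int), 600_001])
    )
    layout = cross_sim.GenomeLayout(
        chromosomes=(("chr13", 2_000_000), ("chr33", 1_000_000)),
        snp_positions={"chr13": np.array([1_000_000]), "chr33": positions},
        recomb_rate=20.0,
    )
    panel = cross_sim.default_panel(
        layout,
        seed=seed + 1,
        aim_fraction=1.0,
        aim_freqs=(0.0, 1.0) if noise_free else (0.02, 0.98),
        causal_B=("chr13", 1_000_000),
        causal_R=("chr33", 600_001),
    )
    cfg = cross_sim.CrossConfig(
        layout=layout,
        founders=panel,
        n_per_founder=(25, 25),
        n_f1=40,
        n_f2=n_f2,
        seed=seed,
    )
    return cross_sim.breed_cross(cfg)


@pytest.fixture(scope="session")
def region_cohort():
    return make_region_cohort(seed=7)
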