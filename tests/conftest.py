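"""Shared fixtures: small simulated datasets built at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import aimpanel as ap
from aimpanel.io_formats import GenotypeDataset, SnpRecord, make_snp_table


@pytest.fixture(scope="session")
def small_cohort():
    """50 x 100 admixed cohort with missing data plus parental panels."""
    cfg = ap.SimConfig(n_individuals=50, n_snps=100, seed=3,
                       missing_rate=0.05, n_ref=60)
    pop1, pop2, freqs = ap.simulate_parental(cfg)
    admixed, truth = ap.simulate_admixed(cfg, freqs)
    return {"config": cfg, "pop1": pop1, "pop2": pop2, "freqs": freqs,
            "admixed": admixed, "truth": truth}


@pytest.fixture(scope="session")
def tiny_hmm_problem():
    """Hand-written 2-individual, 5-marker chromosome for oracle checks."""
    cm = [0.0, 3.0, 7.0, 15.0, 30.0]
    recs = [SnpRecord(f"s{i}", "1", int(c * 1e6) + 1, "A", "C", c)
            for i, c in enumerate(cm)]
    snps = make_snp_table(recs)
    calls = np.array([[0, 1, 2, 1, 0], [2, 2, -1, 0, 1]], dtype=np.int8)
    dataset = GenotypeDataset(["i1", "i2"], snps, calls)
    freqs = pd.DataFrame({"snp_id": snps["snp_id"],
                          "p_ceu": [0.9, 0.8, 0.85, 0.7, 0.95],
                          "p_yri": [0.1, 0.2, 0.3, 0.15, 0.2]})
    return {"dataset": dataset, "freqs": freqs, "cm": np.array(cm),
            "m": np.array([0.2, 0.6]), "lambda_gen": 7.0}


@pytest.fixture(scope="session")
def ld_fixture():
    """200-SNP parental datasets with planted duplicate columns (exact ties,
    r^2 = 1 in both parents), partial-LD pairs (high r^2 in one parent
    only), and otherwise independent AIM-grade SNPs."""
    cfg = ap.SimConfig(n_individuals=50, n_snps=200,
                       chromosome_lengths_cm=(40.0, 40.0, 40.0),
                       delta_preset="aims", seed=11, n_ref=100)
    pop1, pop2, _ = ap.simulate_parental(cfg)
    calls1 = pop1.calls.copy()
    calls2 = pop2.calls.copy()
    rng = np.random.default_rng(77)
    # exact duplicates (tie + conflict in both parents)
    for j in (10, 40, 90, 150):
        calls1[:, j + 1] = calls1[:, j]
        calls2[:, j + 1] = calls2[:, j]
    # partial LD in parent1 only: copy then perturb a few entries
    for j in (25, 70, 120, 170):
        calls1[:, j + 1] = calls1[:, j]
        touch = rng.choice(calls1.shape[0], size=6, replace=False)
        calls1[touch, j + 1] = rng.integers(0, 3, size=6)
    p1 = GenotypeDataset(pop1.samples, pop1.snps.copy(), calls1, "CEU-like")
    p2 = GenotypeDataset(pop2.samples, pop2.snps.copy(), calls2, "YRI-like")
    return p1, p2
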