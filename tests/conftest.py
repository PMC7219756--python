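"""Shared fixtures: small simulated datasets and relationship matrices.

Everything is generated at test time from seeded configs; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

import gblup_field as gf


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete breeding program: 4 sets, forward-CV capable."""
    cfg = gf.SimConfig(
        n_founders=16,
        n_markers=300,
        n_sets=4,
        lines_per_set=24,
        trial_lines=12,
        n_checks=2,
        replicates=(2,),
        locations=1,
        missing_rate=0.005,
        seed=7,
    )
    genotypes, pedigree, plots, truth = gf.simulate(cfg)
    return cfg, genotypes, pedigree, plots, truth


@pytest.fixture(scope="session")
def small_G(small_sim):
    _, genotypes, _, _, _ = small_sim
    qcd = gf.qc_filter(genotypes, maf_min=0.01, line_missing_max=0.05)
    return gf.condition_pd(gf.build_G(gf.mean_impute(qcd)))


@pytest.fixture(scope="session")
def small_A(small_sim, small_G):
    _, _, pedigree, _, _ = small_sim
    return gf.condition_pd(gf.build_A_selfed(pedigree).subset(small_G.labels))


@pytest.fixture(scope="session")
def small_plots(small_sim, small_G):
    """Plot table restricted to lines that survived genotype QC."""
    _, _, _, plots, _ = small_sim
    return plots[plots["line_id"].isin(small_G.labels)].reset_index(drop=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
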