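import numpy as np
import pytest

import wgblup
from wgblup.data import UNKNOWN_PARENT, Pedigree


@pytest.fixture(scope="session")
def small_cohort():
    """A 140-individual, 300-marker simulated cohort shared by tests that
    only need realistic structure, not a specific architecture."""
    ped = wgblup.sim_pedigree(40, 5, 10, 2, seed=7)
    g = wgblup.sim_genotypes(ped, 300, ld_rho=0.5, map_length_mb=60,
                             seed=8, n_chromosomes=3)
    spec = wgblup.ArchitectureSpec(n_qtl=4, h2=0.5, major_fraction=0.5)
    trait, truth = wgblup.sim_trait(g, spec, seed=9)
    return ped, g, trait, truth


def random_pedigree(rng, n):
    """Random pedigree of n individuals; parents drawn among earlier
    individuals with unknown parents allowed."""
    ids = [f"I{k}" for k in range(n)]
    sires, dams = [], []
    for k in range(n):
        if k >= 2 and rng.random() < 0.7:
            s, d = rng.choice(k, size=2, replace=False)
            sires.append(ids[s])
            dams.append(ids[d])
        else:
            sires.append(UNKNOWN_PARENT)
            dams.append(UNKNOWN_PARENT)
    return Pedigree(np.array(ids, object), np.array(sires, object),
                    np.array(dams, object))
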