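import numpy as np
import pandas as pd
import pytest

from xgrr import pedrel, simdata
from xgrr.pedigree import Pedigree


@pytest.fixture(scope="session")
def nuclear_family():
    """Sire x dam with two sons and two daughters."""
    return Pedigree(
        pd.DataFrame(
            [
                ("sire", "0", "0", "M"),
                ("dam", "0", "0", "F"),
                ("son1", "sire", "dam", "M"),
                ("son2", "sire", "dam", "M"),
                ("dau1", "sire", "dam", "F"),
                ("dau2", "sire", "dam", "F"),
            ],
            columns=["id", "sire", "dam", "sex"],
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A ~120-sire breeding cohort with LD haplotypes and QTL-free records.

    Shared by the variance-component and association tests; phenotype
    draws with other truths re-simulate on top of the same structures.
    """
    ped = simdata.simulate_pedigree(
        n_founders=240,
        n_generations=4,
        mean_offspring_per_sire=15,
        mean_gametes_per_parent=2.5,
        seed=101,
    )
    sires = sorted(set(ped.table["sire"]) - {"0"})
    parents = sorted((set(ped.table["sire"]) | set(ped.table["dam"])) - {"0"})
    breeding = ped.ancestor_closure(parents)
    mm = simdata.default_marker_map(n_x=80, n_par=8)
    rng = np.random.default_rng(102)
    pool = simdata.mosaic_founder_haps(
        mm, 400, n_ancestral=25, founder_freqs=rng.uniform(0.1, 0.9, mm.n_markers), seed=103
    )
    panel = simdata.drop_genomes(breeding, mm, founder_haps=pool, seed=104)
    A = pedrel.autosomal_A(breeding)
    S = pedrel.xlinked_S(breeding)
    gametes = [(s, f"g{i}") for s in sires for i in range(12)]
    return {
        "ped": breeding,
        "sires": sires,
        "map": mm,
        "panel": panel,
        "A": A,
        "S": S,
        "gametes": gametes,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
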