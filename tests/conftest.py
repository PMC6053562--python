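import numpy as np
import pandas as pd
import pytest

from sealdrift import abc_demography as abcd
from sealdrift.genotype_io import GenotypeMatrix

# study-scale ABC configuration shared by the validation tests: 1,000
# single-SNP loci in 32 diploids, reference table of 5,000 simulations per
# scenario under the standard priors
ABC_N_DIPLOIDS = 32
ABC_N_LOCI = 1000
ABC_SIMS_PER_SCENARIO = 5000


@pytest.fixture(scope="session")
def reference_nomaf() -> abcd.ReferenceTable:
    return abcd.build_reference_table(
        abcd.PriorSet(), (1, 2, 3, 4), ABC_SIMS_PER_SCENARIO,
        ABC_N_DIPLOIDS, ABC_N_LOCI, 0.0, seed=20240101)


@pytest.fixture(scope="session")
def reference_maf() -> abcd.ReferenceTable:
    return abcd.build_reference_table(
        abcd.PriorSet(), (1, 2, 3, 4), ABC_SIMS_PER_SCENARIO,
        ABC_N_DIPLOIDS, ABC_N_LOCI, 0.05, seed=20240102)


def make_gm(calls, colonies=None, cohorts=None, years=None, radlocus_ids=None,
            pos=None) -> GenotypeMatrix:
    """Small literal genotype matrix with minimal metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n_loci, n_samp = calls.shape
    colonies = colonies or ["C1"] * n_samp
    cohorts = cohorts or ["k1"] * n_samp
    years = years if years is not None else [2000.0] * n_samp
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n_samp)],
        "colony": colonies, "cohort": cohorts, "year": years})
    locus_ids = np.array([f"L{i}" for i in range(n_loci)], dtype=object)
    rad = np.asarray(radlocus_ids, dtype=object) if radlocus_ids is not None \
        else locus_ids.copy()
    return GenotypeMatrix(locus_ids=locus_ids, radlocus_ids=rad, calls=calls,
                          samples=samples,
                          pos=None if pos is None else np.asarray(pos))
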