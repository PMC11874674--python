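import numpy as np
import pytest

import clutchkin as ck
from clutchkin.genodata import make_genotype_table


def small_table(genos_per_embryo, loci=("L1",), clutch="C1"):
    """Build a one-clutch embryo table from per-embryo genotype lists."""
    recs = []
    for i, g in enumerate(genos_per_embryo):
        calls = {loci[j]: g[j] for j in range(len(loci))}
        recs.append((f"E{i + 1}", clutch, 2019, "embryo", calls))
    return make_genotype_table(recs, loci)


@pytest.fixture(scope="session")
def population_model():
    return ck.default_population()


@pytest.fixture(scope="session")
def study_dataset(population_model):
    """One study-shaped simulated dataset (13 clutches + 81 adults)."""
    return ck.generate_dataset(population_model, ck.study_like_design(), seed=7)


@pytest.fixture(scope="session")
def adult_freqs(study_dataset):
    gt, _, _ = study_dataset
    return ck.allele_frequencies(gt, subset=gt.adult_ids)
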