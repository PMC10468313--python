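import numpy as np
import pytest

import clonemarker as cm


@pytest.fixture(scope="session")
def toy_reference() -> dict[str, str]:
    """Two short handcrafted contigs; chr1 carries a homopolymer and a
    dinucleotide repeat so left-alignment has real work to do."""
    chr1 = "ACGTACGTTTTTTACGCATATATATGCGACGTACGTACGGCCTAGGCTA"
    chr2 = "TTGACCAGTTGACCAGGTCAACTGGTCAAC"
    return {"chr1": chr1, "chr2": chr2}


@pytest.fixture()
def small_design() -> cm.CohortDesign:
    return cm.make_design(
        n_clones=2,
        replicates=2,
        clone_specific=5,
        genome_length=20_000,
        background_het_rate=0.002,
        dropout_rate=0.0,
        false_positive_rate=0.0,
        seed=11,
    )


@pytest.fixture()
def small_cohort(small_design):
    """Noiseless 2-clone cohort: (design, reference, truth, samples, records)."""
    ref = cm.generate_reference(
        small_design.genome_length, small_design.n_contigs,
        small_design.gc_fraction, seed=small_design.seed,
    )
    truth = cm.plant_cohort(small_design, ref)
    samples, records = cm.simulate_calls(truth, small_design)
    return small_design, ref, truth, samples, records


def random_matrix(rng: np.random.Generator, n_clones=2, max_reps=3, n_sites=30):
    """Random genotype matrix with missing cells, for oracle comparisons."""
    clones = [f"c{i}" for i in range(n_clones)]
    s2c = {}
    for c in clones:
        for r in range(1, int(rng.integers(1, max_reps + 1)) + 1):
            s2c[f"{c}_r{r}"] = c
    samples = list(s2c)
    import pandas as pd

    keys = [("chr1", i + 1, "A", "G") for i in range(n_sites)]
    vals = rng.choice(
        [0.0, 1.0, 2.0, np.nan], size=(n_sites, len(samples)), p=[0.45, 0.3, 0.15, 0.1]
    )
    data = pd.DataFrame(
        vals, index=pd.Index(keys, tupleize_cols=False), columns=samples
    )
    return cm.GenotypeMatrix(data, s2c)
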