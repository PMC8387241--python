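import numpy as np
import pandas as pd
import pytest

import syncomstats as scs


@pytest.fixture(scope="session")
def panel32():
    """The study-scale paired panel: 32 strains, 16 families, 16 per host."""
    return scs.make_strain_panel(16, 16, seq_len=360, family_divergence=0.10,
                                 seed=7)


@pytest.fixture(scope="session")
def panel4():
    """A small paired panel for fast unit tests."""
    return scs.make_strain_panel(2, 2, seq_len=120, family_divergence=0.15,
                                 seed=3)


@pytest.fixture()
def toy_abundance():
    """Hand-built abundance table: 4 root samples (2 per host), 2 strains."""
    panel = scs.StrainPanel(pd.DataFrame({
        "strain_id": ["Lj_f01", "At_f01"],
        "host_of_origin": ["Lj", "At"],
        "family": ["f01", "f01"],
        "species": ["f01_sp1", "f01_sp2"],
        "ref_seq": ["ACGT" * 30, "ACGA" * 30],
    }))
    values = pd.DataFrame(
        [[0.02, 0.98], [0.02, 0.98], [0.01, 0.99], [0.01, 0.99]],
        index=["s1", "s2", "s3", "s4"],
        columns=["Lj_f01", "At_f01"],
    )
    meta = pd.DataFrame(
        {
            "compartment": ["root"] * 4,
            "host_species": ["Lj", "Lj", "At", "At"],
            "host_genotype": ["wt"] * 4,
            "treatment": ["competition"] * 4,
            "first_syncom": ["mixed"] * 4,
            "second_syncom": ["mock"] * 4,
            "experiment": ["e1"] * 4,
            "replicate": [1, 2, 1, 2],
        },
        index=values.index,
    )
    ab = scs.AbundanceTable(values, "strain")
    return ab, meta, panel
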