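import numpy as np
import pandas as pd
import pytest

from meadownet import FeatureTable, SampleMetadata, TaxonomyTable


def make_table(values, sample_ids=None, taxon_ids=None, mode="count"):
    values = np.asarray(values)
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(values.shape[0])]
    taxon_ids = taxon_ids or [f"t{j + 1}" for j in range(values.shape[1])]
    return FeatureTable(
        pd.DataFrame(values, index=sample_ids, columns=taxon_ids), mode=mode
    )


def make_metadata(sample_ids, compartments, months=None):
    months = months or ["Dec"] * len(sample_ids)
    return SampleMetadata(
        pd.DataFrame(
            {
                "compartment": compartments,
                "month": months,
                "pH": 8.0,
                "temperature": 20.0,
                "salinity": 30.0,
            },
            index=pd.Index(sample_ids),
        )
    )


@pytest.fixture
def random_count_table():
    rng = np.random.default_rng(42)
    return make_table(rng.integers(0, 50, size=(6, 10)))


@pytest.fixture
def small_taxonomy():
    return TaxonomyTable(
        {
            "t1": "k__Fungi;p__Ascomycota;g__GenA",
            "t2": "k__Fungi;p__Ascomycota;g__GenA",
            "t3": "k__Fungi;p__Basidiomycota;g__GenB",
            "t4": "k__Fungi",  # classified only to kingdom
            "t5": "d__Bacteria;p__Proteobacteria;f__FamX;g__GenC",
            "t6": "d__Archaea;p__Crenarchaeota",
        }
    )
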