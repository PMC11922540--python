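import numpy as np
import pandas as pd
import pytest

from phytoquant.asv import AsvTable
from phytoquant.synthetic import ClassSpec, GeneratorConfig


@pytest.fixture
def small_config():
    """A fast two-year, three-station design with three classes."""
    classes = (
        ClassSpec("Bacillariophyceae", 3, np.log(10000), 1.0, np.log(2000), 0.5, 1.0),
        ClassSpec("Chrysophyceae", 4, np.log(5000), 1.0, np.log(600), 0.5, 1.3),
        ClassSpec("Cryptophyceae", 3, np.log(3000), 1.0, np.log(1000), 0.5, 0.8),
    )
    return GeneratorConfig(
        classes=classes, n_stations=3, n_years=2, read_depth=5000,
        heterotroph_asv_count=3, seed=11,
    )


@pytest.fixture
def species_table():
    """Two samples, two classes, hand-checkable totals."""
    return pd.DataFrame(
        {
            "sample_id": ["1_20", "1_20", "1_20", "2_20", "2_20"],
            "species": ["d1", "d2", "c1", "d1", "c1"],
            "class_name": ["Diatom", "Diatom", "Crypto", "Diatom", "Crypto"],
            "abundance": [10.0, 20.0, 30.0, 5.0, 15.0],
            "biomass": [1.0, 2.0, 3.0, 0.5, 1.5],
        }
    )


def make_asv_table(counts: dict, lineages: dict, trophic: dict | None = None,
                   samples=("s1", "s2", "s3")) -> AsvTable:
    """Build a small AsvTable from {asv: [counts per sample]} dicts."""
    counts_df = pd.DataFrame(counts, index=list(samples))
    counts_df.index.name = "sample_id"
    tax = pd.DataFrame({"lineage": pd.Series(lineages)})
    tax.index.name = "asv_id"
    if trophic is not None:
        tax["trophic"] = pd.Series(trophic)
    table = AsvTable(counts_df, tax)
    return table.with_derived_fields()


@pytest.fixture
def asv_factory():
    return make_asv_table
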