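import numpy as np
import pandas as pd
import pytest

from rbpome.interactome import ProteinQuantTable, WholeProteomeTable
from rbpome.localization import aggregate_entries


def make_quant_table(rows, method="cCL"):
    """rows: (protein_id, cl, noncl, peptides, ibaq) with None for absent."""
    df = pd.DataFrame(
        rows,
        columns=["protein_id", "intensity_cl", "intensity_noncl", "unique_peptides_cl", "ibaq_pulldown"],
    ).astype({"intensity_cl": float, "intensity_noncl": float, "ibaq_pulldown": float})
    return ProteinQuantTable(method=method, data=df)


@pytest.fixture
def small_quant():
    return make_quant_table(
        [
            ("A", 1000.0, 50.0, 3, 20.0),   # ratio 20 -> enriched
            ("B", 500.0, 50.0, 3, 5.0),     # ratio exactly 10 -> not
            ("C", 1000.0, np.nan, 2, 8.0),  # CL-only detection -> enriched
            ("D", 1000.0, 10.0, 1, 2.0),    # too few peptides
            ("E", 90.0, 100.0, 5, 1.0),     # depleted
        ]
    )


@pytest.fixture
def toy_loc_db():
    """8 genes; 'posterior' carried by g0-g3 in stages 4-5."""
    rows = []
    for i in range(8):
        rows.append((f"g{i}", "stages_1-3", "ubiquitous"))
        term = "posterior" if i < 4 else "ubiquitous"
        rows.append((f"g{i}", "stages_4-5", term))
    return aggregate_entries(pd.DataFrame(rows, columns=["gene_id", "stage_window", "terms"]))


@pytest.fixture
def whole_table():
    return WholeProteomeTable(
        pd.DataFrame({"protein_id": ["A", "B", "C", "E"], "ibaq_whole": [1.0, 1.0, 2.0, 2.0]})
    )
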