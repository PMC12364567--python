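import numpy as np
import pandas as pd
import pytest

from lipidtraffic.dataio import AbundanceTable, CompartmentNetwork, StudyDesign


@pytest.fixture
def path_network() -> CompartmentNetwork:
    """Path graph A - B - C - D."""
    return CompartmentNetwork.from_lists(
        ["A", "B", "C", "D"], [("A", "B"), ("B", "C"), ("C", "D")]
    )


@pytest.fixture
def toy_study():
    """Two phenotypes x two compartments, 4 samples per group, 3 variables.

    PC(34:2): detected everywhere; TG(48:1): only in F/liver (all samples);
    PE(36:2): detected in 2 of 4 samples of every group (occupancy 0.5).
    """
    rows = []
    ids = []
    rng = np.random.default_rng(42)
    design_rows = []
    for phen in ("F", "M"):
        for comp in ("liver", "serum"):
            for i in range(4):
                sid = f"{phen}_{comp}_{i}"
                ids.append(sid)
                design_rows.append({"phenotype": phen, "compartment": comp})
                pc = rng.lognormal(3, 0.5)
                tg = rng.lognormal(3, 0.5) if (phen, comp) == ("F", "liver") else 0.0
                pe = rng.lognormal(3, 0.5) if i < 2 else 0.0
                rows.append([pc, tg, pe])
    data = pd.DataFrame(
        rows, index=ids, columns=["PC(34:2)", "TG(48:1)", "PE(36:2)"]
    )
    data.index.name = "sample_id"
    table = AbundanceTable(data)
    design = StudyDesign(pd.DataFrame(design_rows, index=pd.Index(ids, name="sample_id")))
    network = CompartmentNetwork.from_lists(["liver", "serum"], [("liver", "serum")])
    return table, design, network
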