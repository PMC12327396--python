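import numpy as np
import pandas as pd
import pytest

from milkwdi.data import AssayLimits, DosingRegimen, StudyDataset, RECORD_COLUMNS
from milkwdi.simulate import PopulationPK, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated 10-goat study at the default calibration."""
    return generate_dataset(PopulationPK(seed=1))


@pytest.fixture(scope="session")
def noiseless_population():
    return PopulationPK(
        analytical_cv=0.0,
        iiv_gsd={"ka": 1.0, "ke": 1.0, "v_over_f": 1.0, "mp_ratio": 1.0},
        n_animals=2,
        seed=0,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_population):
    return generate_dataset(noiseless_population)


def make_dataset(rows, regimen=None, limits=None, **kwargs):
    """Build a StudyDataset from (animal, matrix, time, rep, conc, censor[, prov]) tuples."""
    full = []
    for r in rows:
        r = tuple(r)
        if len(r) == 6:
            r = r + ("measured",)
        full.append(r)
    frame = pd.DataFrame(full, columns=RECORD_COLUMNS)
    frame["conc"] = frame["conc"].astype(float)
    return StudyDataset(
        regimen=regimen or DosingRegimen(),
        limits=limits or AssayLimits(),
        frame=frame,
        **kwargs,
    )
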