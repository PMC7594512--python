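import numpy as np
import pandas as pd
import pytest

from triomics.io_preprocess import ClinicalTable, OmicsMatrix


def make_matrix(values, kind="mRNA", genes=None, samples=None) -> OmicsMatrix:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{i}" for i in range(arr.shape[1])]
    return OmicsMatrix(kind, pd.DataFrame(arr, index=genes, columns=samples))


def make_clinical(os_time, os_event, age=None, gender=None, pam50=None, samples=None) -> ClinicalTable:
    n = len(os_time)
    samples = samples or [f"S{i}" for i in range(n)]
    data = pd.DataFrame(
        {
            "os_time": np.asarray(os_time, dtype=float),
            "os_event": np.asarray(os_event, dtype=bool),
            "age": np.asarray(age if age is not None else [60.0] * n, dtype=float),
            "gender": gender if gender is not None else ["female"] * n,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    if pam50 is not None:
        data["pam50"] = pd.array(pam50, dtype="string")
    return ClinicalTable(data)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A small generated cohort with planted structure, shared across tests."""
    from triomics.synthetic import SimulationParams, generate_cohort

    params = SimulationParams(
        n_samples=120,
        n_genes=80,
        n_cnacor=15,
        n_metcor=15,
        n_prognostic=8,
        missing_frac=0.0,
        male_frac=0.0,
        seed=42,
    )
    return generate_cohort(params)
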