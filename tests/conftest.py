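import warnings

import numpy as np
import pandas as pd
import pytest

import leptomet as lm

# correlation-stage warnings about censored-then-imputed constant metabolites
# are expected on synthetic studies and only noise in test output
warnings.filterwarnings("ignore", message=".*constant metabolite.*")


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by read-only tests."""
    config = lm.SimulationConfig.scaled_down(80, seed=11)
    return lm.simulate_study(config)


@pytest.fixture(scope="session")
def study_files(tmp_path_factory, small_study):
    """The same study exported as the three on-disk tables."""
    matrix, annotations, metadata, truth = small_study
    outdir = tmp_path_factory.mktemp("study")
    lm.write_study(outdir, matrix, annotations, metadata, truth)
    return outdir


@pytest.fixture()
def toy_metadata():
    rows = []
    for k, ind in enumerate(["A", "B", "C", "D"]):
        for cond in ("pre", "post"):
            rows.append(
                {
                    "sample_id": f"{ind}_{cond}",
                    "individual_id": ind,
                    "condition": cond,
                    "sex": "M" if k % 2 else "F",
                    "age": 10.0 + k,
                    "ethnicity": "x",
                    "run_day": f"d{k % 2}",
                }
            )
    return lm.dataio.validate_metadata(pd.DataFrame(rows))


def make_matrix(values, sample_ids, metabolite_ids, log_scale=True):
    return lm.AbundanceMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=sample_ids, columns=metabolite_ids),
        log_scale=log_scale,
    )
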