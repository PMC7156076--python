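import numpy as np
import pandas as pd
import pytest

import detectome as dt
from detectome.model import annotations_frame


@pytest.fixture(scope="session")
def default_study() -> dt.SimulatedStudy:
    """The default study-shaped synthetic scenario (zero call noise)."""
    return dt.generate(dt.ScenarioConfig())


@pytest.fixture(scope="session")
def default_calls(default_study) -> dt.DetectionCallMatrix:
    return default_study.calls()


@pytest.fixture(scope="session")
def scopes(default_study):
    """Sample-id lists per group x compartment cell of the default study."""
    ann = annotations_frame(default_study.annotations)

    def sel(**kw):
        return [
            s for s in ann.index if all(ann.loc[s, k] == v for k, v in kw.items())
        ]

    return {
        "plasma_cases": sel(group="case", compartment="plasma"),
        "plasma_controls": sel(group="control", compartment="plasma"),
        "ev_cases": sel(group="case", compartment="EV"),
        "ev_controls": sel(group="control", compartment="EV"),
        "females": sel(sex="F"),
        "males": sel(sex="M"),
    }


def random_call_matrix(rng, n_mirnas, n_samples, p=0.5) -> dt.DetectionCallMatrix:
    calls = pd.DataFrame(
        rng.random((n_mirnas, n_samples)) < p,
        index=[f"m{i:03d}" for i in range(n_mirnas)],
        columns=[f"s{j:02d}" for j in range(n_samples)],
    )
    return dt.DetectionCallMatrix(calls=calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
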