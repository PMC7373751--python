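import numpy as np
import pandas as pd
import pytest

from megade import ExpressionStudy, StudyMeta


def make_study(
    values: dict[str, list[float]],
    groups: list[str],
    study_id: str = "S1",
    country: str = "USA",
    year: int = 2010,
) -> ExpressionStudy:
    """Build a small in-memory study from {gene: row} and group labels."""
    frame = pd.DataFrame.from_dict(values, orient="index")
    samples = [f"{study_id}_smp{i}" for i in range(frame.shape[1])]
    frame.columns = samples
    n_case = groups.count("case")
    n_control = groups.count("control")
    meta = StudyMeta(
        study_id=study_id,
        n_control=max(n_control, 1),
        n_case=max(n_case, 1),
        country=country,
        year=year,
    )
    return ExpressionStudy(
        values=frame,
        groups=pd.Series(groups, index=samples, name="group"),
        meta=meta,
    )


@pytest.fixture
def four_sample_study():
    """2 control + 2 case samples, 3 genes, already log2/centred."""
    return make_study(
        {
            "GUP": [0.0, 0.0, 2.0, 2.0],
            "GFLAT": [1.0, 1.0, 1.0, 1.0],
            "GDOWN": [3.0, 2.0, 1.0, 0.0],
        },
        ["control", "control", "case", "case"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
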