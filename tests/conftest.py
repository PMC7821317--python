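import numpy as np
import pytest

from opsel.pipeline import AssayRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_assay_csv(tmp_path):
    """Six well-formed assay rows spanning both sexes and two treatments."""
    path = tmp_path / "assays.csv"
    path.write_text(
        "focal_sex,treatment,assay_date,offspring_count,total_offspring_weight\n"
        "F,CT,d01,40,160.0\n"
        "F,CT,d01,35,140.0\n"
        "M,CT,d02,50,200.0\n"
        "M,CT,d02,30,120.0\n"
        "F,HT,d01,20,90.0\n"
        "M,HT,d02,25,100.0\n"
    )
    return path


def make_records(sex, treatment, counts, dates=None, weights=None):
    """Build a list of AssayRecord from parallel arrays."""
    n = len(counts)
    dates = dates if dates is not None else ["d01"] * n
    weights = weights if weights is not None else [None] * n
    return [
        AssayRecord(
            focal_sex=sex,
            treatment=treatment,
            assay_date=str(dates[i]),
            offspring_count=int(counts[i]),
            total_offspring_weight=weights[i],
        )
        for i in range(n)
    ]
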