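import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import methclocks as mc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

MRSCORE_PROBES = [
    "cg01612140",
    "cg05575921",
    "cg06126421",
    "cg08362785",
    "cg10321156",
    "cg14975410",
    "cg19572487",
    "cg23665802",
    "cg24704287",
    "cg25983901",
]


@pytest.fixture
def mrscore_set():
    return mc.load_bundled_coefficients("mrscore")


@pytest.fixture
def small_beta():
    """Deterministic 8-probe x 6-sample matrix without missing values."""
    rng = np.random.default_rng(42)
    probes = [f"cg{i:08d}" for i in range(8)]
    samples = [f"s{i}" for i in range(6)]
    vals = pd.DataFrame(rng.uniform(0.05, 0.95, (8, 6)), index=probes, columns=samples)
    return mc.BetaMatrix(vals)


@pytest.fixture
def paired_sheet():
    """Five subjects with complete tumor/normal pairs plus one tumor-only."""
    rows = []
    for i in range(5):
        subj = f"p{i}"
        rows.append(dict(sample_id=f"{subj}_T", subject_id=subj, tissue_role="tumor",
                         group="none", stage="II", age=60.0 + i, sex="M"))
        rows.append(dict(sample_id=f"{subj}_N", subject_id=subj, tissue_role="normal",
                         group="none", stage="II", age=60.0 + i, sex="M"))
    rows.append(dict(sample_id="p9_T", subject_id="p9", tissue_role="tumor",
                     group="none", stage="I", age=70.0, sex="F"))
    return mc.SampleSheet(pd.DataFrame(rows))


def indicator_matrix(probes, hot_probe=None, value=1.0, fill=0.0):
    """Single-sample beta matrix with one probe set to ``value``."""
    vals = pd.DataFrame(fill, index=list(probes), columns=["s1"], dtype=float)
    if hot_probe is not None:
        vals.loc[hot_probe, "s1"] = value
    return mc.BetaMatrix(vals)
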