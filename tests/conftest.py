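import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from lipofx import (  # noqa: E402
    CohortDataset,
    SamplerSettings,
    apply_missingness,
    generate_cohort,
    make_paper_like_config,
)


@pytest.fixture(scope="session")
def paper_like_cohort() -> CohortDataset:
    """A trial-sized (16/14) synthetic cohort with censoring and QC dropout."""
    cfg = make_paper_like_config(seed=20200511)
    return apply_missingness(generate_cohort(cfg), cfg)


@pytest.fixture(scope="session")
def paper_like_config():
    return make_paper_like_config(seed=20200511)


@pytest.fixture
def quick_sampler() -> SamplerSettings:
    """Short chains for unit tests; defaults stay at 4 × 2000 for users."""
    return SamplerSettings(chains=2, iterations_per_chain=1000, seed=7)


@pytest.fixture
def tiny_cohort() -> CohortDataset:
    """Hand-built 4-subject, 1-metabolite dataset with every status kind."""
    subjects = pd.DataFrame(
        {
            "subject_id": ["a", "b", "c", "d"],
            "arm": [1, 1, 0, 0],
            "statin": [1, 0, 1, 0],
            "ezetimibe": [0, 0, 1, 0],
        }
    )
    rows = []
    conc = {"a": (2.0, 1.0), "b": (3.0, np.nan), "c": (2.5, 2.4), "d": (3.5, np.nan)}
    status = {"b": "below_lod", "d": "qc_rejected"}
    for sid, (b, w) in conc.items():
        rows.append((sid, "baseline", "M", b, "observed"))
        rows.append((sid, "week16", "M", w, status.get(sid, "observed")))
    measurements = pd.DataFrame(
        rows, columns=["subject_id", "visit", "metabolite_id", "concentration", "status"]
    )
    return CohortDataset(subjects, measurements)
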