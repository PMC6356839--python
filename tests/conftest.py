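import numpy as np
import pandas as pd
import pytest

from deepcoxsig import synthcohort as sc


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort reused by several suites (kept small for speed)."""
    cfg = sc.SyntheticConfig(n_tumor=250, n_genes=100, n_informative=10,
                             seed=11)
    expr, surv, clinical, truth = sc.generate_cohort(cfg)
    return cfg, expr, surv, clinical, truth


def make_surv(times, events, prefix="S"):
    idx = [f"{prefix}{i:03d}" for i in range(len(times))]
    return pd.DataFrame({"time": np.asarray(times, float),
                         "event": np.asarray(events, int)},
                        index=pd.Index(idx, name="sample_id"))
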