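import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import methylcascade as mc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort() -> mc.SimulatedCohort:
    """Small 3-positive + 2-mimicker cohort shared by read-only tests."""
    cfg = mc.CohortConfig(
        n_probes=1500,
        classes=[("PAAD", 30), ("iCCA", 30), ("NormalBile", 25), ("MimA", 20), ("MimB", 20)],
        delta=0.3,
        noise_sd=0.05,
        seed=101,
    )
    return mc.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def manifest() -> pd.DataFrame:
    return mc.make_manifest(1000, seed=7)


@pytest.fixture(scope="session")
def trained_cascade(small_cohort):
    """A small trained cascade plus its train/holdout split."""
    from methylcascade.cascade import MlpSpec
    from methylcascade.pipeline import train_eval_split

    co = small_cohort
    train_mask, hold_mask = train_eval_split(co.sample_sheet, 0.3, seed=5)
    X = co.beta.T
    y = co.sample_sheet["label"].to_numpy()
    material = co.sample_sheet["material"].to_numpy()
    model = mc.CascadeClassifier(
        k=96,
        anomaly_spec=MlpSpec(output="sigmoid", hidden_widths=[64, 64],
                             learning_rate=0.0088, dropout=0.2, l1=0.00067, epochs=40),
        classifier_spec=MlpSpec(output="softmax", hidden_widths=[64, 32, 16],
                                learning_rate=0.00895, l1=0.00441, epochs=60),
        seed=5,
    )
    model.fit(X.loc[train_mask], y[train_mask], batch=material[train_mask])
    return model, co, train_mask, hold_mask
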