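import numpy as np
import pandas as pd
import pytest

import methpanel as mp


@pytest.fixture(scope="session")
def small_cohort():
    """4-class cohort with 5 planted probes per class, no missingness."""
    cfg = mp.SimConfig(n_classes=4, samples_per_class=20, n_probes=300,
                       informative_per_class=5, effect_delta=0.35,
                       precision=30.0, seed=11)
    bm, labels, truth, manifest = mp.generate_beta_dataset(cfg)
    return {"cfg": cfg, "bm": bm, "labels": labels, "truth": truth,
            "manifest": manifest}


@pytest.fixture
def tiny_bm():
    return mp.BetaMatrix(pd.DataFrame(
        [[0.1, 0.9, np.nan], [0.5, 0.2, 0.8]],
        index=["s1", "s2"], columns=["p1", "p2", "p3"]))


@pytest.fixture
def two_class_labels():
    return mp.SampleLabels(pd.Series(
        {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}))


def make_groups_bm(groups, probe="p1"):
    """BetaMatrix + labels from {class: [values]} for one probe."""
    values, index, classes = [], [], []
    for cls, vals in groups.items():
        for i, v in enumerate(vals):
            values.append(v)
            index.append(f"{cls}{i}")
            classes.append(cls)
    bm = mp.BetaMatrix(pd.DataFrame({probe: values}, index=index))
    labels = mp.SampleLabels(pd.Series(classes, index=index))
    return bm, labels
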