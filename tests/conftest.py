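import numpy as np
import pandas as pd
import pytest

import winterflux as wf


@pytest.fixture(scope="session")
def regions():
    return wf.simulate_regions(0)


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated winter shared by fast unit tests."""
    cfg = wf.SimConfig(n_individuals=12, n_weeks=8, seed=3)
    y, truth = wf.simulate_capture_histories(cfg)
    return cfg, y, truth


@pytest.fixture(scope="session")
def desk_fit():
    """Desk-scale multistate recovery fit: truth diagonal at the reported
    regional fidelities, 100 individuals x 19 weeks, detection 0.9."""
    cfg = wf.SimConfig(n_individuals=100, n_weeks=19, seed=42)
    y, truth = wf.simulate_capture_histories(cfg)
    res = wf.MultistateModel(y).fit(
        chains=3, iterations=20_000, burn_in=5_000, thin=5, seed=42
    )
    return cfg, truth, res


def make_labeled_bursts(n_per_class: int, seed: int, signal_params=None):
    """Calibrated bursts + labels from the generator's known classes."""
    sched = pd.DataFrame(
        {
            "individual_id": "TRAIN",
            "timestamp": pd.Timestamp("2016-12-01", tz="UTC"),
            "behavior": np.repeat(list(wf.simulate.BEHAVIORS), n_per_class),
            "device": "unbounded",
        }
    )
    cfg = wf.SimConfig(seed=seed)
    bursts = wf.simulate_bursts(
        cfg, sched, signal_params=signal_params, rng=np.random.default_rng(seed)
    )
    cal = wf.calibrate_units(bursts)
    feats = wf.extract_features(cal)
    return feats, sched["behavior"].to_numpy()


@pytest.fixture(scope="session")
def trained_classifier():
    """Classifier trained on 500 bursts per class with default signatures."""
    feats, labels = make_labeled_bursts(500, seed=7)
    clf = wf.train_classifier(feats, labels, n_trees=500, seed=7)
    return clf, feats, labels
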