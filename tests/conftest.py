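import numpy as np
import pytest
from hypothesis import settings

from multiexit import BackboneConfig, SynthParams, generate_synthetic_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_backbone():
    """Smallest legal backbone: 2 blocks, 8x8 input."""
    return BackboneConfig(
        block_channels=(4, 6), convs_per_block=(1, 1), input_size=(8, 8), num_classes=3
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small synthetic dataset shared by data-pipeline tests."""
    params = SynthParams(n_patients=10, images_per_patient=6, image_size=16, seed=7)
    return generate_synthetic_dataset(params)


def random_prediction_table(rng, n):
    """Random confidences/predictions/labels for oracle-equivalence tests."""
    from multiexit import PredictionTable

    conf = rng.random(n)
    pred = rng.integers(0, 3, n)
    true = np.where(rng.random(n) < conf, pred, rng.integers(0, 3, n))
    return PredictionTable(conf, pred, true)


def brute_force_bins_and_ece(confidence, predicted, true, M):
    """Independent double-loop implementation of binning and ECE.

    Sample i belongs to bin m iff (m-1)/M < p_i <= m/M, with p_i = 0 in bin 1.
    """
    n = len(confidence)
    counts, accs, confs = [], [], []
    for m in range(1, M + 1):
        lo, hi = (m - 1) / M, m / M
        members = []
        for i in range(n):
            p = confidence[i]
            if (lo < p <= hi) or (m == 1 and p == 0.0):
                members.append(i)
        counts.append(len(members))
        if members:
            accs.append(sum(1.0 for i in members if predicted[i] == true[i]) / len(members))
            confs.append(sum(confidence[i] for i in members) / len(members))
        else:
            accs.append(float("nan"))
            confs.append(float("nan"))
    ece = 0.0
    for m in range(M):
        if counts[m]:
            ece += counts[m] / n * abs(accs[m] - confs[m])
    return counts, accs, confs, ece
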