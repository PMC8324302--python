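import numpy as np
import pytest

import hydramech as hm


@pytest.fixture()
def short_spec():
    """A small, fast synthetic recording specification."""
    return hm.SyntheticSpec(duration_s=300.0, fps=16.0, seed=11, noise_sd=0.05)


@pytest.fixture()
def clean_spec():
    """Noise-free variant for exact-value checks."""
    return hm.SyntheticSpec(duration_s=60.0, fps=16.0, seed=3, noise_sd=0.0)


@pytest.fixture()
def stim_protocol():
    """1 s on / 30 s off over five minutes, rendered at 16 fps."""
    return hm.generate_stimulus_protocol(1.0, 30.0, 300.0, 25.0, fps=16.0)


def greedy_match_f1(planted, detected, tol_s=0.3):
    """Greedy one-to-one matching F1 between two sorted time lists."""
    planted = np.asarray(planted, dtype=float)
    detected = np.asarray(detected, dtype=float)
    used = np.zeros(detected.size, dtype=bool)
    tp = 0
    for p in planted:
        if not detected.size:
            break
        d = np.abs(detected - p)
        d[used] = np.inf
        if d.min() <= tol_s:
            used[np.argmin(d)] = True
            tp += 1
    fp = int((~used).sum())
    fn = planted.size - tp
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)
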