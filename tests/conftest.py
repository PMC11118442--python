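import numpy as np
import pytest

import microdyn as md


@pytest.fixture(scope="session")
def synth_ground_truth():
    """60 s synthetic recording at snr 3 with known templates and labels."""
    spec = md.SyntheticSpec(duration_s=60.0, snr=3.0, seed=42)
    templates = md.make_templates(spec)
    labels = md.make_label_sequence(spec)
    rec = md.synthesize_eeg(templates, labels, spec)
    return spec, templates, labels, rec


@pytest.fixture(scope="session")
def two_tone():
    """1 Hz + 10 Hz unit sines, 10 s at 250 Hz, with the pure components."""
    fs = 250.0
    t = np.arange(int(10 * fs)) / fs
    low = np.sin(2 * np.pi * 1.0 * t)
    high = np.sin(2 * np.pi * 10.0 * t)
    return low + high, low, high, fs


def random_transition_string(rng, alphabet_size: int, length: int) -> str:
    """Uniform random no-consecutive-repeat symbol string."""
    letters = "ABCD"[:alphabet_size]
    out = [letters[rng.integers(alphabet_size)]]
    while len(out) < length:
        c = letters[rng.integers(alphabet_size)]
        if c != out[-1]:
            out.append(c)
    return "".join(out)
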