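import numpy as np
import pytest

from loopscape.core import PWM, GenomicInterval, Loop
from loopscape import balance, synthgen


@pytest.fixture(scope="session")
def sharp_pwm() -> PWM:
    """A sharp, non-palindromic 10-bp motif (97:1 counts per column)."""
    counts = np.full((4, 10), 1.0)
    for k, b in enumerate("CCAGCAGGGG"):
        counts["ACGT".index(b), k] = 97
    return PWM.from_counts(counts)


@pytest.fixture(scope="session")
def toy_pwm() -> PWM:
    """A soft 4-bp motif used for exhaustive brute-force comparisons."""
    probs = np.array(
        [
            [0.4, 0.1, 0.25, 0.3],
            [0.2, 0.6, 0.25, 0.1],
            [0.3, 0.2, 0.25, 0.2],
            [0.1, 0.1, 0.25, 0.4],
        ]
    )
    return PWM(probabilities=probs)


@pytest.fixture(scope="session")
def featureless_balanced():
    """Balanced featureless decaying matrix (400 bins, depth 2e6)."""
    params = synthgen.SimParams(n_bins=400, depth=2e6, seed=22)
    matrix, _ = synthgen.simulate_contact_map(params)
    return balance.ipf_balance(matrix)


def random_loops(n, n_bins, rng, min_sep=20, max_sep=100, resolution=10_000):
    """Random off-diagonal loop positions at architectural-loop distances."""
    loops = []
    while len(loops) < n:
        i = int(rng.integers(12, n_bins - 12 - min_sep))
        j = i + int(rng.integers(min_sep, max_sep))
        if j < n_bins - 12:
            loops.append(
                Loop.from_anchors(
                    GenomicInterval("chrS", i * resolution, (i + 1) * resolution),
                    GenomicInterval("chrS", j * resolution, (j + 1) * resolution),
                    resolution,
                )
            )
    return loops
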