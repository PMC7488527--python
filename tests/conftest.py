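import numpy as np
import pytest

from thermodev.records import TransitionSample


def make_samples(points, transition="hatching", regime="20", temp_c=19.7):
    """Build TransitionSamples from (age_h, n_past, n_total) triples."""
    return [
        TransitionSample(
            regime=regime,
            temp_c=temp_c,
            age_h=float(a),
            transition=transition,
            n_total=int(n),
            n_past=int(y),
        )
        for a, y, n in points
    ]


@pytest.fixture
def symmetric_overlap():
    """Symmetric 3-point dataset with an intermediate count at the center."""
    return make_samples([(4.0, 0, 10), (5.0, 5, 10), (6.0, 10, 10)])


@pytest.fixture
def separated_pair():
    """Completely separated two-point dataset (no intermediate counts)."""
    return make_samples([(4.0, 0, 10), (6.0, 10, 10)])


def grid_maximize(objective, half=(12.0, 12.0), iters=9, npts=41):
    """Coarse-to-fine 2-D grid search maximizing ``objective(b0, b1)``.

    Independent of the IRLS path: evaluates the objective on a shrinking
    lattice around the running argmax.
    """
    c0, c1 = 0.0, 0.0
    h0, h1 = half
    for _ in range(iters):
        g0 = np.linspace(c0 - h0, c0 + h0, npts)
        g1 = np.linspace(c1 - h1, c1 + h1, npts)
        best = (-np.inf, c0, c1)
        for b0 in g0:
            for b1 in g1:
                v = objective(b0, b1)
                if v > best[0]:
                    best = (v, b0, b1)
        _, c0, c1 = best
        h0 *= 2.5 / (npts - 1) * 2
        h1 *= 2.5 / (npts - 1) * 2
    return c0, c1
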