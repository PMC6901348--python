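import numpy as np
import pytest

from fjwnn.rules import FuzzyRule, FuzzyRuleSystem
from fjwnn.wavelets import Wavelet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_two_rule_system(m=2):
    """A hand-built two-rule system used as ground truth in several tests.

    Rule 1 (scale 0) covers the lower half of the input square, rule 2
    (scale 1) the upper half; both carry one wavelet and a linear part.
    """
    r1 = FuzzyRule(
        a=0,
        wavelets=[Wavelet(a=0, b=(0.3, 0.3))],
        w=np.array([1.5, 0.8, -0.4]),
        ca=np.array([1, 0]),
        v=0.9,
    )
    r2 = FuzzyRule(
        a=1,
        wavelets=[Wavelet(a=1, b=(2 * 0.7, 2 * 0.6))],
        w=np.array([-1.0, 0.2, 1.1]),
        ca=np.array([2, 2]),
        v=0.8,
    )
    return FuzzyRuleSystem(
        rules=[r1, r2],
        mf_mu=np.array([[0.25, 0.75], [0.3, 0.7]]),
        mf_su=np.array([[0.25, 0.2], [0.3, 0.25]]),
        prune_threshold=0.05,
        ph=0,
        norm_lo=np.zeros(m),
        norm_hi=np.ones(m),
        n_a=2,
    )


@pytest.fixture
def two_rule_system():
    return make_two_rule_system()
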