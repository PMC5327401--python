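import numpy as np
import pytest

from irisquant.quantification import train_pigment_classifier
from irisquant.synthetic import (
    SyntheticEyeSpec,
    render_synthetic_eye,
    synthetic_training_pixels,
)


@pytest.fixture(scope="session")
def classifier():
    """Quadratic-kernel SVM trained on synthetic class-colour pixels."""
    return train_pigment_classifier(synthetic_training_pixels(n_per_class=300, seed=11))


@pytest.fixture(scope="session")
def mixed_eye():
    """A rendered eye with proportions (0.2, 0.3, 0.5) and its ground truth."""
    spec = SyntheticEyeSpec(proportions=(0.2, 0.3, 0.5), seed=42, sample_id="mixed")
    return render_synthetic_eye(spec)


@pytest.fixture(scope="session")
def blue_eye():
    spec = SyntheticEyeSpec(proportions=(0.9, 0.07, 0.03), seed=7, sample_id="blue")
    return render_synthetic_eye(spec)


def hwe_enumeration_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p by integer enumeration over heterozygote counts.

    Conditional on the observed allele counts, the number of genotype
    configurations with h heterozygotes is n! / (a! h! b!) * 2^h; the p-value
    sums the normalised weights of all configurations no more probable than
    the observed one. Pure integer arithmetic, independent of the package's
    log-gamma implementation.
    """
    from math import factorial

    n = n_AA + n_Aa + n_aa
    nr = 2 * min(n_AA, n_aa) + n_Aa
    if nr == 0:
        return 1.0
    weights = {}
    for h in range(nr % 2, nr + 1, 2):
        a = (nr - h) // 2
        b = n - h - a
        weights[h] = factorial(n) * 2**h // (factorial(a) * factorial(h) * factorial(b))
    total = sum(weights.values())
    w_obs = weights[n_Aa]
    return sum(w for w in weights.values() if w <= w_obs) / total
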