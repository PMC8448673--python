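import numpy as np
import pytest

from vasoionics import CoupledMarkovParams


@pytest.fixture
def uncoupled_n2() -> CoupledMarkovParams:
    return CoupledMarkovParams(2, 0.0, 0.6, 0.8)


@pytest.fixture
def coupled_n3() -> CoupledMarkovParams:
    return CoupledMarkovParams(3, 1.0, 0.9, 0.8)


def enumerate_uncoupled_row(n: int, k: int, rho: float, sigma_c: float) -> np.ndarray:
    """Brute-force oracle: next-level distribution from k open of n independent
    channels, by exhaustive enumeration of all 2^n next configurations."""
    from itertools import product

    row = np.zeros(n + 1)
    current = [1] * k + [0] * (n - k)
    for nxt in product((0, 1), repeat=n):
        p = 1.0
        for cur_s, nxt_s in zip(current, nxt):
            if cur_s == 1:
                p *= rho if nxt_s == 1 else (1.0 - rho)
            else:
                p *= sigma_c if nxt_s == 0 else (1.0 - sigma_c)
        row[sum(nxt)] += p
    return row
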