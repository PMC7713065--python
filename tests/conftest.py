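"""Shared fixtures: small synthetic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from fnrscan.motifs import PWM
from fnrscan.simulate import SimConfig, default_box_matrix, sample_box_sites, simulate

GC65 = np.array([0.175, 0.325, 0.325, 0.175])


def random_seq(rng: np.random.Generator, length: int, p=GC65) -> str:
    return "".join(rng.choice(list("ACGT"), p=p, size=length))


class NamedSeq:
    """Minimal promoter-like object: ref_id + sequence."""

    def __init__(self, ref_id: str, sequence: str):
        self.ref_id = ref_id
        self.sequence = sequence


def planted_promoter_set(n: int, seed: int, length: int = 450,
                         matrix: np.ndarray | None = None,
                         n_planted: int | None = None):
    """n background promoters, the first ``n_planted`` carrying one box each.

    Returns (promoters, offsets, sites); offsets[i] is None when no box.
    """
    rng = np.random.default_rng(seed)
    if matrix is None:
        matrix = default_box_matrix()
    k = n if n_planted is None else n_planted
    sites = sample_box_sites(k, matrix, rng)
    W = matrix.shape[0]
    proms, offsets = [], []
    for i in range(n):
        s = random_seq(rng, length)
        if i < k:
            o = int(rng.integers(0, length - W))
            s = s[:o] + sites[i] + s[o + W:]
            offsets.append(o)
        else:
            offsets.append(None)
        proms.append(NamedSeq(f"P{i:03d}", s))
    return proms, offsets, sites


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition synthetic dataset, shared across tests."""
    return simulate(SimConfig(seed=2024))


@pytest.fixture(scope="session")
def sim_noiseless():
    return simulate(SimConfig(seed=77, noise_sigma=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_pwm():
    """Width-2 PWM with well-separated column scores."""
    mat = np.array([[0.4, 0.3, 0.2, 0.1],
                    [0.1, 0.2, 0.3, 0.4]])
    return PWM(mat, np.full(4, 0.25))
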