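"""Shared fixtures and the independent alignment oracle.

``sw_oracle`` is a deliberately naive quadratic affine-gap Smith-Waterman
(three-matrix recurrence, pure Python) kept independent of the package's
aligner so the two can cross-check each other on small inputs.
"""

from __future__ import annotations

import random

import pytest

from xorfeome.pipeline import classify_collection
from xorfeome.simulate import MODES, SimConfig, simulate_collection


def sw_oracle(q, s, match=2.0, mismatch=-3.0, gap_open=-5.0, gap_extend=-2.0):
    """Brute-force local alignment score; a gap of length L scores open + L*extend."""
    n, m = len(q), len(s)
    NEG = float("-inf")
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open + gap_extend, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open + gap_extend, F[i][j - 1] + gap_extend)
            sub = match if (q[i - 1] == s[j - 1] and q[i - 1] != "N") else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


@pytest.fixture(scope="session")
def oracle():
    return sw_oracle


def random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def small_bundle():
    """30-clone synthetic collection (5 clones per error mode), fixed seed."""
    cfg = SimConfig(seed=7, class_counts={m: 5 for m in MODES})
    return simulate_collection(cfg)


@pytest.fixture(scope="session")
def small_evidence(small_bundle):
    """Evidence table for the 30-clone collection (computed once)."""
    return classify_collection(small_bundle)
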