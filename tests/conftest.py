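"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import random

import pytest

from peptidemine.search import ScoringScheme


@pytest.fixture
def write_text(tmp_path):
    """Write literal text to a temp file and return its path."""

    def _write(name: str, text: str):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture(scope="session")
def default_scheme() -> ScoringScheme:
    return ScoringScheme()


def sw_oracle(a: str, b: str, scheme: ScoringScheme) -> int:
    """Exhaustive local-alignment oracle, independent of any DP recurrence.

    A local alignment that is score-optimal starts and ends with an aligned
    pair and, under affine penalties, never benefits from splitting a gap, so
    the optimum is the max over all equal-size increasing subsets of positions
    of ``a`` and ``b`` (the matched pairs), charging one contiguous gap per
    sequence between consecutive pairs.
    """
    sub = scheme.matrix
    go, ge = scheme.gap_open, scheme.gap_extend
    best = 0
    la, lb = len(a), len(b)
    for k in range(1, min(la, lb) + 1):
        for ia in itertools.combinations(range(la), k):
            for ib in itertools.combinations(range(lb), k):
                s = sub[(a[ia[0]], b[ib[0]])]
                for t in range(1, k):
                    gap_a = ia[t] - ia[t - 1] - 1
                    gap_b = ib[t] - ib[t - 1] - 1
                    if gap_a:
                        s += go + (gap_a - 1) * ge
                    if gap_b:
                        s += go + (gap_b - 1) * ge
                    s += sub[(a[ia[t]], b[ib[t]])]
                if s > best:
                    best = s
    return best


def random_protein(rng: random.Random, length: int, alphabet: str = "ACDEFGHILMNPQSTVWY") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))
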