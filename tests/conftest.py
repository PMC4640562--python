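"""Shared fixtures and independent oracles for the test suite."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from clstest.variant_io import LocusEvidence, LocusKey, SampleEvidence


def exact_binomial_upper_tail(X: int, n: int, p: Fraction) -> Fraction:
    """Independent oracle: P(B >= X), B ~ Binomial(n, p), exact rational arithmetic."""
    return sum(Fraction(comb(n, k)) * p**k * (1 - p) ** (n - k) for k in range(X, n + 1))


def random_evidence_rows(rng: np.random.Generator, n_rows: int) -> list[LocusEvidence]:
    """Random per-locus evidence spanning passing and failing configurations."""
    rows = []
    for i in range(n_rows):
        g_depth = int(rng.integers(0, 60))
        g_alt = int(rng.integers(0, min(g_depth, 4) + 1))
        g_hq = int(rng.integers(0, g_depth + 1))
        rows.append(
            LocusEvidence(
                key=LocusKey("chr1", i + 1, "A", "T"),
                germline=SampleEvidence(g_depth, g_alt, g_hq, called=False),
                tumor_a=SampleEvidence(
                    (da := int(rng.integers(0, 120))), min(int(rng.integers(0, 60)), da),
                    da, called=bool(rng.integers(0, 2)),
                ),
                tumor_b=SampleEvidence(
                    (db := int(rng.integers(0, 120))), min(int(rng.integers(0, 60)), db),
                    db, called=bool(rng.integers(0, 2)),
                ),
                in_dbsnp=bool(rng.random() < 0.2),
            )
        )
    return rows


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231109)
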