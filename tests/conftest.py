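import random

import pytest

from tagquant import FeatureBarcode, FeatureWhitelist


def make_whitelist(seqs: dict[str, str]) -> FeatureWhitelist:
    return FeatureWhitelist([FeatureBarcode(fid, seq) for fid, seq in seqs.items()])


def random_whitelist(rng: random.Random, n: int, L: int, min_dist: int = 1) -> FeatureWhitelist:
    """Random whitelist of n distinct length-L barcodes at pairwise distance >= min_dist."""
    seqs: list[str] = []
    for _ in range(100_000):
        cand = "".join(rng.choice("ACGT") for _ in range(L))
        if all(sum(a != b for a, b in zip(cand, s)) >= min_dist for s in seqs):
            seqs.append(cand)
            if len(seqs) == n:
                break
    assert len(seqs) == n, "rejection sampling failed; loosen parameters"
    return make_whitelist({f"F{i+1}": s for i, s in enumerate(seqs)})


@pytest.fixture
def well_separated_whitelist() -> FeatureWhitelist:
    """Four 8-bp barcodes at pairwise Hamming distance >= 3 (hand-checked)."""
    return make_whitelist({
        "TAG1": "AAAACCCC",
        "TAG2": "GGGGTTTT",
        "TAG3": "ACGTACGT",
        "TAG4": "CTCTGAGA",
    })


@pytest.fixture
def clashing_whitelist() -> FeatureWhitelist:
    """Two barcodes at Hamming distance 1 (variant collisions guaranteed)."""
    return make_whitelist({"F1": "AAAA", "F2": "AAAT"})
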