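"""Synthetic barcode sets emulating published assay designs.

These are NOT the real assay barcode sequences: they are synthetic stand-ins,
generated deterministically, engineered to reproduce the documented clash
structure of two real designs so the QC metrics have realistic inputs:

* a Multiseq-style set: 96 sample barcodes of 8 bp, two of which (labelled
  BC49 and BC74, after the real pair they emulate) share a 7-bp substring —
  the longest clash an 8-bp pair can have short of identity;
* a CRISPR-screen-style set: 90 20-bp sgRNA sequences targeting 45 genes,
  where EZR-1/EZR-2 and PPIB-2/PPIB-1 each share a 16-bp substring, and
  EZR-2 and PPIB-1 begin with GCG and GGA respectively.

Every other pair in each set is verified at construction time to share
nothing as long as the engineered clash, so the clashing pairs are exactly
the ones a QC sweep should flag.
"""

from __future__ import annotations

import random

from .core import FeatureBarcode, FeatureWhitelist

_MULTISEQ_SHARED_7MER = "GGTTAGC"
_EZR_SHARED_16MER = "ATCGGACCTTGATCAC"
_PPIB_SHARED_16MER = "TTGCCAAGTCGTAGGA"


def _shares_kmer(seq: str, k: int, pool: set[str]) -> bool:
    return any(seq[i : i + k] in pool for i in range(len(seq) - k + 1))


def _add_kmers(seq: str, k: int, pool: set[str]) -> None:
    for i in range(len(seq) - k + 1):
        pool.add(seq[i : i + k])


def _fill_random(
    rng: random.Random, n: int, length: int, k: int, kmer_pool: set[str],
    taken: set[str],
) -> list[str]:
    """Random sequences sharing no length-k substring with anything so far."""
    out: list[str] = []
    while len(out) < n:
        cand = "".join(rng.choice("ACGT") for _ in range(length))
        if cand in taken or _shares_kmer(cand, k, kmer_pool):
            continue
        _add_kmers(cand, k, kmer_pool)
        taken.add(cand)
        out.append(cand)
    return out


def multiseq_like_whitelist(n: int = 96) -> FeatureWhitelist:
    """Synthetic 8-bp sample-barcode set with one engineered 7-bp clash."""
    if n < 2:
        raise ValueError("need at least the two clashing barcodes")
    bc49 = _MULTISEQ_SHARED_7MER + "A"   # shared 7-mer as prefix
    bc74 = "T" + _MULTISEQ_SHARED_7MER   # shared 7-mer as suffix
    kmer_pool: set[str] = set()
    _add_kmers(bc49, 7, kmer_pool)
    _add_kmers(bc74, 7, kmer_pool)
    taken = {bc49, bc74}
    rng = random.Random(4949)
    others = _fill_random(rng, n - 2, 8, 7, kmer_pool, taken)
    # the clashing pair sits at positions 49 and 74 when the set is big
    # enough, else in the last two slots (labels are kept either way)
    pos49 = 48 if n >= 74 else n - 2
    pos74 = 73 if n >= 74 else n - 1
    barcodes = []
    j = 0
    for i in range(n):
        if i == pos49:
            barcodes.append(FeatureBarcode("BC49", bc49))
        elif i == pos74:
            barcodes.append(FeatureBarcode("BC74", bc74))
        else:
            barcodes.append(FeatureBarcode(f"BC{i + 1}", others[j]))
            j += 1
    return FeatureWhitelist(barcodes)


def sgrna_like_whitelist(n_genes: int = 45) -> FeatureWhitelist:
    """Synthetic 20-bp sgRNA set (2 guides/gene) with two 16-bp clashes.

    EZR-1/EZR-2 share a 16-mer, as do PPIB-2/PPIB-1; EZR-2 begins with GCG
    and PPIB-1 with GGA.
    """
    ezr1 = _EZR_SHARED_16MER + "TGCA"          # shared 16-mer as prefix
    ezr2 = "GCG" + "T" + _EZR_SHARED_16MER     # ... as suffix, leading GCG
    ppib2 = _PPIB_SHARED_16MER + "CAGT"
    ppib1 = "GGA" + "C" + _PPIB_SHARED_16MER
    engineered = {"EZR-1": ezr1, "EZR-2": ezr2, "PPIB-1": ppib1, "PPIB-2": ppib2}

    kmer_pool: set[str] = set()
    for seq in engineered.values():
        _add_kmers(seq, 16, kmer_pool)
    # the two engineered clashes must not collide with each other
    assert len({ezr1, ezr2, ppib1, ppib2}) == 4
    taken = set(engineered.values())
    rng = random.Random(1620)
    gene_names = ["EZR", "PPIB"] + [f"GENE{i}" for i in range(1, n_genes - 1)]
    barcodes = []
    for gene in gene_names:
        for guide in (1, 2):
            name = f"{gene}-{guide}"
            if name in engineered:
                barcodes.append(FeatureBarcode(name, engineered[name]))
            else:
                seq = _fill_random(rng, 1, 20, 16, kmer_pool, taken)[0]
                barcodes.append(FeatureBarcode(name, seq))
    return FeatureWhitelist(barcodes)
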