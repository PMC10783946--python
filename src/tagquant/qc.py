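"""Barcode-design quality control metrics.

Badly designed barcode sets clash: short barcodes sharing long substrings,
pairs at small Hamming distance, long homopolymer runs and skewed per-position
nucleotide content all degrade assignment once sequencing errors are in play.
This module computes the full metric bundle on a whitelist:

* theoretical code diversity for length L under a minimum pairwise Hamming
  distance d, via two classical coding-theory upper bounds (Singleton:
  ``4^(L-d+1)``; sphere-packing/Hamming: ``floor(4^L / sum_{i<=t} C(L,i) 3^i)``
  with ``t = floor((d-1)/2)``) — the bounds bracket achievable code sizes;
* barcodes sharing a contiguous length-k substring with another barcode;
* pairwise Hamming distance histogram (and vs reverse complements);
* maximal homopolymer runs;
* per-position nucleotide content.

All pairwise metrics are restricted to equal-length pairs (Hamming distance
is undefined otherwise); skipped pairs are counted explicitly.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Optional

from .core import FeatureWhitelist, ValidationError, hamming, revcomp


def diversity_bound(L: int, d: int, bound: Literal["singleton", "sphere_packing"] = "singleton") -> int:
    """Upper bound on the number of length-L DNA codewords at min distance d.

    Exact integer arithmetic throughout.
    """
    if d < 1 or d > L:
        raise ValidationError(f"minimum distance d={d} must satisfy 1 <= d <= L={L}")
    if bound == "singleton":
        return 4 ** (L - d + 1)
    if bound == "sphere_packing":
        t = (d - 1) // 2
        sphere = sum(math.comb(L, i) * 3**i for i in range(t + 1))
        return 4**L // sphere
    raise ValidationError(f"unknown bound {bound!r}")


def shared_subsequence_groups(
    whitelist: FeatureWhitelist, k: int
) -> tuple[dict[str, set[str]], int]:
    """Length-k substrings shared by >= 2 distinct barcodes.

    Returns (groups, ambiguous_count): ``groups`` maps each clashing
    substring to the set of feature_ids containing it; ``ambiguous_count``
    is the number of barcodes appearing in at least one group.
    """
    if k < 1:
        raise ValidationError(f"substring length k={k} must be >= 1")
    owners: dict[str, set[str]] = {}
    for bc in whitelist:
        for i in range(len(bc.sequence) - k + 1):
            owners.setdefault(bc.sequence[i : i + k], set()).add(bc.feature_id)
    groups = {sub: ids for sub, ids in owners.items() if len(ids) >= 2}
    ambiguous = set().union(*groups.values()) if groups else set()
    return groups, len(ambiguous)


def ambiguous_by_sublen(whitelist: FeatureWhitelist, ks: Optional[list[int]] = None) -> dict[int, int]:
    """Ambiguous-barcode count for each substring length k (non-increasing in k)."""
    if ks is None:
        ks = list(range(1, max(len(bc) for bc in whitelist) + 1))
    return {k: shared_subsequence_groups(whitelist, k)[1] for k in ks}


def longest_shared_substring_length(whitelist: FeatureWhitelist) -> int:
    """Largest k at which any two barcodes still share a length-k substring (0 if none)."""
    for k in range(max(len(bc) for bc in whitelist), 0, -1):
        if shared_subsequence_groups(whitelist, k)[1] > 0:
            return k
    return 0


@dataclass
class HammingHistograms:
    pairwise: dict[int, int]
    min_distance: Optional[int]
    revcomp_pairwise: dict[int, int]
    revcomp_min_distance: Optional[int]
    self_revcomp_distance: dict[str, int]
    skipped_pairs: int


def hamming_histograms(whitelist: FeatureWhitelist) -> HammingHistograms:
    """Pairwise Hamming histogram, and the same against reverse complements.

    The reverse-complement histogram covers unordered pairs of DISTINCT
    barcodes (each barcode vs the other's reverse complement, taking the
    minimum of the two orientations is not needed since
    d(a, rc(b)) == d(b, rc(a))); a barcode against its own reverse complement
    is reported separately per barcode.  Unequal-length pairs are skipped and
    counted.
    """
    pairwise: Counter[int] = Counter()
    rc_pairwise: Counter[int] = Counter()
    skipped = 0
    for a, b in combinations(whitelist.barcodes, 2):
        if len(a.sequence) != len(b.sequence):
            skipped += 1
            continue
        pairwise[hamming(a.sequence, b.sequence)] += 1
        rc_pairwise[hamming(a.sequence, revcomp(b.sequence))] += 1
    self_rc = {bc.feature_id: hamming(bc.sequence, revcomp(bc.sequence)) for bc in whitelist}
    return HammingHistograms(
        pairwise=dict(sorted(pairwise.items())),
        min_distance=min(pairwise) if pairwise else None,
        revcomp_pairwise=dict(sorted(rc_pairwise.items())),
        revcomp_min_distance=min(rc_pairwise) if rc_pairwise else None,
        self_revcomp_distance=self_rc,
        skipped_pairs=skipped,
    )


def homopolymer_runs(
    whitelist: FeatureWhitelist, min_len: int = 2
) -> tuple[dict[str, list[tuple[str, int]]], dict[int, int]]:
    """Maximal homopolymer runs of length >= min_len, per barcode.

    A run of length 5 is reported once, as length 5 (maximality).  Returns
    (per_barcode, distribution) where distribution counts runs by length
    across the whole whitelist.
    """
    if min_len < 2:
        raise ValidationError(f"min_len={min_len} must be >= 2")
    per_barcode: dict[str, list[tuple[str, int]]] = {}
    dist: Counter[int] = Counter()
    for bc in whitelist:
        runs: list[tuple[str, int]] = []
        seq = bc.sequence
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            if j - i >= min_len:
                runs.append((seq[i], j - i))
                dist[j - i] += 1
            i = j
        per_barcode[bc.feature_id] = runs
    return per_barcode, dict(sorted(dist.items()))


def position_content(whitelist: FeatureWhitelist) -> list[dict[str, float]]:
    """Per-position base fractions among barcodes long enough to cover it."""
    max_len = max(len(bc) for bc in whitelist)
    out: list[dict[str, float]] = []
    for pos in range(max_len):
        covering = [bc.sequence[pos] for bc in whitelist if len(bc.sequence) > pos]
        counts = Counter(covering)
        out.append({base: counts.get(base, 0) / len(covering) for base in "ACGT"})
    return out


def qc_report(
    whitelist: FeatureWhitelist,
    homopolymer_min: int = 2,
    sub_lens: Optional[list[int]] = None,
) -> dict:
    """Bundle every metric into a JSON-serializable report.

    Warnings flag a minimum pairwise distance <= 2 (guaranteed mismatch-map
    variant loss) and shared substrings of length >= L-1.
    """
    lengths = sorted({len(bc) for bc in whitelist})
    hist = hamming_histograms(whitelist)
    amb = ambiguous_by_sublen(whitelist, sub_lens)
    per_bc_runs, run_dist = homopolymer_runs(whitelist, homopolymer_min)

    warnings: list[str] = []
    if hist.min_distance is not None and hist.min_distance <= 2:
        warnings.append(
            f"minimum pairwise Hamming distance is {hist.min_distance} (<= 2): "
            "single-substitution errors can clash between barcodes"
        )
    L_max = max(lengths)
    long_shared = [k for k, n in amb.items() if k >= L_max - 1 and n > 0]
    if long_shared:
        warnings.append(
            f"barcodes share substrings of length >= L-1 (k={sorted(long_shared)}): "
            "near-duplicate barcodes present"
        )

    diversity = {}
    for L in lengths:
        diversity[str(L)] = {
            str(d): {
                "singleton": diversity_bound(L, d, "singleton"),
                "sphere_packing": diversity_bound(L, d, "sphere_packing"),
            }
            for d in range(1, L + 1)
        }

    # integer histogram keys are stringified so the report is a fixed point
    # of a JSON round trip
    return {
        "n_barcodes": len(whitelist),
        "lengths": lengths,
        "min_pairwise_hamming": hist.min_distance,
        "hamming_histogram": {str(k): v for k, v in hist.pairwise.items()},
        "revcomp_hamming_histogram": {str(k): v for k, v in hist.revcomp_pairwise.items()},
        "revcomp_min_distance": hist.revcomp_min_distance,
        "self_revcomp_distance": hist.self_revcomp_distance,
        "skipped_pairs": hist.skipped_pairs,
        "ambiguous_by_sublen": {str(k): v for k, v in amb.items()},
        "homopolymer_runs": {
            fid: [{"base": b, "length": n} for b, n in runs]
            for fid, runs in per_bc_runs.items()
        },
        "homopolymer_distribution": {str(k): v for k, v in run_dist.items()},
        "position_content": position_content(whitelist),
        "diversity": diversity,
        "warnings": warnings,
    }


def write_qc_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
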