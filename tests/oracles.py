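"""Brute-force reference implementations used only to check the package.

Everything here is deliberately naive — exhaustive enumeration and direct
Hamming computation — and stays independent of the code paths it validates.
"""

from __future__ import annotations

from itertools import product

BASES = "ACGT"


def brute_hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def brute_lookup(sequence: str, parents: dict[str, str]) -> str | None:
    """Mismatch-map membership by direct distance computation.

    Exact-sequence priority, then unique distance-<=1 parent, else None.
    """
    for pid, pseq in parents.items():
        if sequence == pseq:
            return pid
    near = [pid for pid, pseq in parents.items()
            if len(pseq) == len(sequence) and brute_hamming(sequence, pseq) <= 1]
    return near[0] if len(near) == 1 else None


def brute_scan(read: str, parents: dict[str, str], revcomp_flag: bool = False):
    """Window scan by brute force: every window vs every parent.

    Returns ("assigned", parent, offset, n_mismatches) or ("ambiguous",) or
    ("unassigned",), mirroring the documented tie-break rules.
    """
    comp = str.maketrans("ACGT", "TGCA")
    L = len(next(iter(parents.values())))
    seqs = [(read, "forward")]
    if revcomp_flag and not set(read) - set(BASES):
        seqs.append((read.translate(comp)[::-1], "reverse"))
    hits = []  # (parent, offset, exact, strand)
    for seq, strand in seqs:
        for off in range(len(seq) - L + 1):
            window = seq[off : off + L]
            if set(window) - set(BASES):
                continue
            pid = brute_lookup(window, parents)
            if pid is not None:
                hits.append((pid, off, window == parents[pid], strand))
    hit_parents = {h[0] for h in hits}
    if not hit_parents:
        return ("unassigned",)
    if len(hit_parents) > 1:
        return ("ambiguous",)
    exact = [h for h in hits if h[2]]
    chosen = exact[0] if exact else hits[0]
    return ("assigned", chosen[0], chosen[1], 0 if exact else 1)


def lcs_length(a: str, b: str) -> int:
    """Longest common (contiguous) substring length, classic DP."""
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def greedy_code(L: int, d: int) -> list[str]:
    """Greedy lexicographic code over {A,C,G,T}^L with min distance d."""
    code: list[str] = []
    for tup in product(BASES, repeat=L):
        cand = "".join(tup)
        if all(brute_hamming(cand, c) >= d for c in code):
            code.append(cand)
    return code
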