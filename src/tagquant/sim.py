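"""Substitution-error simulation and synthetic FASTQ fixture generation.

The simulation answers a design question: given a barcode set and a per-base
substitution error rate p, what fraction of tag reads survive single-mismatch
error correction?  Each simulated read draws a parent barcode, substitutes
every base independently with probability p (uniformly over the three other
bases), and looks the mutated sequence up in the mismatch map.  Outcomes:

* correct      — the lookup returns the true parent;
* misassigned  — the lookup returns a different parent (only possible when
  barcodes sit close together in Hamming space);
* lost         — the lookup fails (the mutated read is unassigned, or fell on
  a variant dropped as ambiguous).

For a single isolated barcode of length L the closed form is
``P(correct) = (1-p)^L + L p (1-p)^(L-1)`` (zero or exactly one
substitution), which anchors the simulation's correctness tests.

The fixture generator emits paired FASTQ files with the layout real
feature-barcode libraries have — R1 = cell barcode + UMI (+ filler), R2 =
filler + (mutated) tag + filler at a fixed or variable offset — plus a truth
table, so the quantifier can be validated against known ground truth.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import FeatureWhitelist, ValidationError, hamming
from .mismatch import MismatchMap, build_mismatch_map

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.uint8)


def _decode_rows(codes: np.ndarray) -> list[str]:
    raw = _BASES[codes].tobytes()
    L = codes.shape[1]
    return [raw[i : i + L].decode("ascii") for i in range(0, len(raw), L)]


@dataclass
class SimulationResult:
    error_rate: float
    n_reads: int
    seed: int
    fraction_correct: float
    fraction_lost: float
    fraction_misassigned: float
    per_parent: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_assignment(
    whitelist: FeatureWhitelist,
    p: float,
    n_reads: int,
    seed: int,
    weights: Optional[Sequence[float]] = None,
    mmap: Optional[MismatchMap] = None,
) -> SimulationResult:
    """Simulate n_reads mutated tag reads and classify their assignment.

    Parents are drawn uniformly unless ``weights`` is given.  Whole-sequence
    lookup (no windowing): this isolates the error-correction behaviour of
    the mismatch map itself from read-structure effects.  Deterministic for
    a given seed.
    """
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"error rate p={p} must be in [0, 1]")
    if n_reads < 1:
        raise ValidationError("n_reads must be >= 1")
    if mmap is None:
        mmap = build_mismatch_map(whitelist)
    L = mmap.L
    ids = whitelist.feature_ids
    parent_codes = np.stack([_encode(s) for s in whitelist.sequences])

    rng = np.random.default_rng(seed)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(ids) or (w < 0).any() or w.sum() == 0:
            raise ValidationError("weights must be non-negative, one per barcode, not all zero")
        parent_idx = rng.choice(len(ids), size=n_reads, p=w / w.sum())
    else:
        parent_idx = rng.integers(len(ids), size=n_reads)

    reads = parent_codes[parent_idx].copy()
    err = rng.random((n_reads, L)) < p
    # shift by 1..3 mod 4 guarantees a substitution to a *different* base
    shift = rng.integers(1, 4, size=(n_reads, L), dtype=np.uint8)
    reads[err] = (reads[err] + shift[err]) % 4

    n_correct = np.zeros(len(ids), dtype=np.int64)
    n_lost = np.zeros(len(ids), dtype=np.int64)
    n_mis = np.zeros(len(ids), dtype=np.int64)
    entries = mmap.entries
    for seq, true_idx in zip(_decode_rows(reads), parent_idx):
        assigned = entries.get(seq)
        if assigned is None:
            n_lost[true_idx] += 1
        elif assigned == ids[true_idx]:
            n_correct[true_idx] += 1
        else:
            n_mis[true_idx] += 1

    n_per = n_correct + n_lost + n_mis
    per_parent = {
        ids[i]: {
            "n_reads": int(n_per[i]),
            "fraction_correct": n_correct[i] / n_per[i] if n_per[i] else 0.0,
            "fraction_lost": n_lost[i] / n_per[i] if n_per[i] else 0.0,
            "fraction_misassigned": n_mis[i] / n_per[i] if n_per[i] else 0.0,
        }
        for i in range(len(ids))
    }
    return SimulationResult(
        error_rate=p,
        n_reads=n_reads,
        seed=seed,
        fraction_correct=int(n_correct.sum()) / n_reads,
        fraction_lost=int(n_lost.sum()) / n_reads,
        fraction_misassigned=int(n_mis.sum()) / n_reads,
        per_parent=per_parent,
    )


def expected_fraction_correct_single(L: int, p: float) -> float:
    """Closed form for an isolated barcode: P(0 or 1 substitutions)."""
    return (1 - p) ** L + L * p * (1 - p) ** (L - 1)


def sweep(
    whitelist: FeatureWhitelist,
    p_values: Sequence[float],
    n_reads: int,
    seed: int,
) -> list[SimulationResult]:
    """One simulation per error rate; seed for rate i is (seed + i) mod 2^31."""
    if not p_values:
        raise ValidationError("p_values must be non-empty")
    mmap = build_mismatch_map(whitelist)
    return [
        simulate_assignment(
            whitelist, p, n_reads, seed=(seed + i) % 2**31, mmap=mmap
        )
        for i, p in enumerate(p_values)
    ]


@dataclass
class FixtureSpec:
    """Recipe for a synthetic paired-FASTQ fixture with known ground truth.

    Defaults describe a small droplet-style library: 16-bp cell barcodes,
    12-bp UMIs (the common 10x v3 geometry), tag embedded in R2 at a
    variable offset inside random filler, no sequencing errors and no PCR
    duplication unless asked for.
    """

    whitelist: FeatureWhitelist
    n_cells: int = 4
    cb_len: int = 16
    umi_len: int = 12
    reads_per_cell_feature: int = 10
    r1_len: Optional[int] = None      # defaults to cb_len + umi_len
    r2_len: Optional[int] = None      # defaults to tag length + 12
    tag_offset: Optional[int] = None  # None: uniform over feasible offsets
    filler_base: Optional[str] = None  # None: random bases; e.g. "A" for poly-A flanks
    error_rate: float = 0.0
    reads_per_molecule: int = 1       # >1 emits PCR duplicates (identical triples)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cells, self.cb_len, self.umi_len,
               self.reads_per_cell_feature, self.reads_per_molecule) < 1:
            raise ValidationError("all fixture counts must be positive")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValidationError("error_rate must be in [0, 1]")
        if self.filler_base is not None and self.filler_base not in "ACGT":
            raise ValidationError("filler_base must be one of A/C/G/T")


def _random_cells(spec: FixtureSpec, rng: np.random.Generator) -> list[str]:
    """Distinct cell barcodes at pairwise Hamming distance >= 2, by rejection."""
    cells: list[str] = []
    for _ in range(10_000):
        cand = "".join("ACGT"[i] for i in rng.integers(4, size=spec.cb_len))
        if all(hamming(cand, c) >= 2 for c in cells):
            cells.append(cand)
            if len(cells) == spec.n_cells:
                return cells
    raise ValidationError(
        f"could not draw {spec.n_cells} cell barcodes of length {spec.cb_len} "
        "at pairwise distance >= 2 within the rejection budget"
    )


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate == 0.0:
        return seq, 0
    out = list(seq)
    n_sub = 0
    for i, orig in enumerate(out):
        if rng.random() < rate:
            out[i] = "ACGT"[(_CODE[orig] + rng.integers(1, 4)) % 4]
            n_sub += 1
    return "".join(out), n_sub


def _filler(n: int, spec: FixtureSpec, rng: np.random.Generator) -> str:
    if n <= 0:
        return ""
    if spec.filler_base is not None:
        return spec.filler_base * n
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def generate_fixture(spec: FixtureSpec, out_dir: str | os.PathLike,
                     gzipped: bool = False) -> dict[str, str]:
    """Write R1/R2 FASTQ files plus a truth table; byte-deterministic per seed.

    The truth table (TSV) lists every emitted read pair's id, cell, UMI, true
    parent, injected substitution count and tag offset.  Returns the three
    output paths.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.whitelist.length
    r1_len = spec.r1_len if spec.r1_len is not None else spec.cb_len + spec.umi_len
    r2_len = spec.r2_len if spec.r2_len is not None else L + 12
    if r1_len < spec.cb_len + spec.umi_len:
        raise ValidationError("r1_len shorter than cell barcode + UMI")
    if r2_len < L:
        raise ValidationError("r2_len shorter than the tag length")
    max_offset = r2_len - L
    if spec.tag_offset is not None and not 0 <= spec.tag_offset <= max_offset:
        raise ValidationError(f"tag_offset must be in [0, {max_offset}]")

    cells = _random_cells(spec, rng)
    r1_records: list[str] = []
    r2_records: list[str] = []
    truth_rows: list[dict] = []
    read_no = 0
    for cell in cells:
        for bc in spec.whitelist:
            for _ in range(spec.reads_per_cell_feature):
                umi = "".join("ACGT"[i] for i in rng.integers(4, size=spec.umi_len))
                tag, n_sub = _mutate(bc.sequence, spec.error_rate, rng)
                offset = (spec.tag_offset if spec.tag_offset is not None
                          else int(rng.integers(0, max_offset + 1)))
                r1 = cell + umi + _filler(r1_len - spec.cb_len - spec.umi_len, spec, rng)
                r2 = (_filler(offset, spec, rng) + tag
                      + _filler(r2_len - offset - L, spec, rng))
                for _dup in range(spec.reads_per_molecule):
                    read_no += 1
                    name = f"read{read_no}"
                    r1_records.append(f"@{name}\n{r1}\n+\n{'I' * len(r1)}\n")
                    r2_records.append(f"@{name}\n{r2}\n+\n{'I' * len(r2)}\n")
                    truth_rows.append({
                        "read_id": name, "cell": cell, "umi": umi,
                        "parent_id": bc.feature_id, "n_substitutions": n_sub,
                        "tag_offset": offset,
                    })

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    suffix = ".fastq.gz" if gzipped else ".fastq"
    paths = {
        "r1": os.path.join(out_dir, "R1" + suffix),
        "r2": os.path.join(out_dir, "R2" + suffix),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    for key, records in (("r1", r1_records), ("r2", r2_records)):
        if gzipped:
            # mtime=0 keeps gzip output byte-identical across runs
            with gzip.GzipFile(paths[key], "wb", mtime=0) as fh:
                fh.write("".join(records).encode("ascii"))
        else:
            with open(paths[key], "w") as fh:
                fh.write("".join(records))
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def truth_matrix(truth_path: str, whitelist: FeatureWhitelist) -> pd.DataFrame:
    """Cells x features UMI counts implied by a fixture truth table.

    Counts distinct (cell, umi) per feature among reads whose tag survived
    with <= 1 substitution — the ground truth the quantifier should recover
    when the whitelist is well separated.
    """
    truth = pd.read_csv(truth_path, sep="\t")
    ok = truth[truth["n_substitutions"] <= 1]
    counts = (
        ok.drop_duplicates(["cell", "umi", "parent_id"])
        .groupby(["cell", "parent_id"]).size().unstack(fill_value=0)
    )
    cells = sorted(truth["cell"].unique())
    return counts.reindex(index=cells, columns=whitelist.feature_ids, fill_value=0)
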