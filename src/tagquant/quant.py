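"""Read scanning and UMI counting: FASTQ pairs -> cells x features matrix.

Per read pair: the cell barcode and UMI are sliced out of read 1, the cell
barcode is optionally corrected against an on-list (exact, else unique
Hamming-distance-1 neighbour), the tag read is trimmed (anchor first, then
fixed 5'/3' trimming) and every length-L window of the result is looked up in
the mismatch map.  A read hitting exactly one parent becomes a count record;
records are UMI-deduplicated per (cell, feature) and written as a sparse
MatrixMarket matrix.

Scanning every window reproduces what a k-mer index with k equal to the tag
length does: the tag is found wherever it sits in the read, tolerating
variable barcode position, with one substitution of error tolerance supplied
by the mismatch map itself.  Quality strings are ignored throughout.
"""

from __future__ import annotations

import enum
import json
import os
from dataclasses import dataclass, asdict
from typing import Iterable, Iterator, Optional

import numpy as np
import pysam
import scipy.io
import scipy.sparse

from .core import (
    DNA_ALPHABET,
    FeatureWhitelist,
    ReadLayout,
    ValidationError,
    revcomp,
)
from .mismatch import MismatchMap, build_mismatch_map


class ScanStatus(enum.Enum):
    ASSIGNED = "assigned"
    AMBIGUOUS = "ambiguous"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class TagHit:
    """A uniquely assigned tag: parent feature, window offset, error count."""

    parent_id: str
    offset: int
    n_mismatches: int
    strand: str = "forward"


@dataclass(frozen=True)
class CountRecord:
    cell: str
    umi: str
    parent_id: str


@dataclass
class RunStats:
    """Per-run read accounting; conserved: the four disposition counters
    (discarded_by_layout + discarded_by_onlist + unassigned + ambiguous +
    assigned) sum to pairs_read."""

    pairs_read: int = 0
    discarded_by_layout: int = 0
    discarded_by_onlist: int = 0
    unassigned: int = 0
    ambiguous: int = 0
    assigned: int = 0
    umis_after_dedup: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CountMatrix:
    """Sparse cells x features UMI count matrix with label vectors.

    Rows follow ``cells`` (lexicographically sorted unique cell barcodes, so
    the matrix is invariant to input read order); columns follow ``features``
    (whitelist order).
    """

    cells: list[str]
    features: list[str]
    counts: scipy.sparse.csr_matrix

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.cells == other.cells
            and self.features == other.features
            and (self.counts != other.counts).nnz == 0
        )


def trim_tag_read(seq: str, layout: ReadLayout) -> Optional[str]:
    """Apply anchor then fixed trimming; None signals a discarded read.

    Anchor trimming locates the FIRST exact occurrence of the anchor and
    keeps the flank named by ``anchor_keep``; a read without the anchor is
    discarded.  Fixed trimming then removes ``trim5``/``trim3`` bases; if
    nothing would remain the read is discarded.
    """
    if layout.anchor is not None:
        idx = seq.find(layout.anchor)
        if idx < 0:
            return None
        seq = seq[:idx] if layout.anchor_keep == "before" else seq[idx + len(layout.anchor):]
    if layout.trim5 + layout.trim3 >= len(seq):
        return None
    return seq[layout.trim5 : len(seq) - layout.trim3]


def _scan_windows(seq: str, mmap: MismatchMap, offsets: Iterable[int], strand: str):
    """Yield (parent, offset, exact, strand) for every matching window."""
    L = mmap.L
    for off in offsets:
        window = seq[off : off + L]
        if set(window) - DNA_ALPHABET:
            continue  # windows containing N etc. never match
        parent = mmap.entries.get(window)
        if parent is not None:
            yield parent, off, window in mmap.exact, strand


def scan_read(
    trimmed_seq: str,
    mmap: MismatchMap,
    revcomp_flag: bool = False,
    scan_offset: Optional[int] = None,
) -> tuple[ScanStatus, Optional[TagHit]]:
    """Look up every length-L window of the read in the mismatch map.

    Exactly one distinct parent across all matching windows (both strands if
    ``revcomp_flag``) yields an ASSIGNED TagHit; two or more parents yield
    AMBIGUOUS; none, UNASSIGNED.  Within the assigned parent, an exact-match
    window is preferred over a variant window (n_mismatches 0 vs 1) and the
    leftmost qualifying window wins.
    """
    L = mmap.L
    if scan_offset is not None:
        offsets: Iterable[int] = (
            [scan_offset] if scan_offset + L <= len(trimmed_seq) else []
        )
    else:
        offsets = range(len(trimmed_seq) - L + 1)

    hits = list(_scan_windows(trimmed_seq, mmap, offsets, "forward"))
    if revcomp_flag:
        rc = revcomp(trimmed_seq) if not (set(trimmed_seq) - DNA_ALPHABET) else None
        if rc is not None:
            if scan_offset is not None:
                rc_offsets: Iterable[int] = [scan_offset] if scan_offset + L <= len(rc) else []
            else:
                rc_offsets = range(len(rc) - L + 1)
            hits.extend(_scan_windows(rc, mmap, rc_offsets, "reverse"))

    parents = {h[0] for h in hits}
    if not parents:
        return ScanStatus.UNASSIGNED, None
    if len(parents) > 1:
        return ScanStatus.AMBIGUOUS, None

    parent = parents.pop()
    exact_hits = [h for h in hits if h[2]]
    chosen = exact_hits[0] if exact_hits else hits[0]
    return ScanStatus.ASSIGNED, TagHit(
        parent_id=parent,
        offset=chosen[1],
        n_mismatches=0 if exact_hits else 1,
        strand=chosen[3],
    )


def extract_cell_umi(read1_seq: str, layout: ReadLayout) -> Optional[tuple[str, str]]:
    """Slice cell barcode and UMI out of read 1; None signals discard.

    Reads shorter than the layout requires are discarded, as are cell
    barcodes containing any non-ACGT character (an N in the cell barcode
    cannot be corrected).  UMIs may contain N — they still deduplicate as
    literal strings.
    """
    if len(read1_seq) < layout.min_read1_length:
        return None
    cell = read1_seq[layout.cb_span[0] : layout.cb_span[1]]
    umi = read1_seq[layout.umi_span[0] : layout.umi_span[1]]
    if set(cell) - DNA_ALPHABET:
        return None
    return cell, umi


def correct_cell_barcode(cell: str, onlist: Optional[frozenset[str]]) -> Optional[str]:
    """On-list correction: exact, else the unique distance-1 member, else None.

    With no on-list supplied this is the identity.
    """
    if onlist is None:
        return cell
    if cell in onlist:
        return cell
    candidates = set()
    for pos, orig in enumerate(cell):
        for base in "ACGT":
            if base != orig:
                neighbor = cell[:pos] + base + cell[pos + 1 :]
                if neighbor in onlist:
                    candidates.add(neighbor)
                    if len(candidates) > 1:
                        return None
    if len(candidates) == 1:
        return candidates.pop()
    return None


def deduplicate(records: list[CountRecord]) -> list[CountRecord]:
    """Collapse duplicate (cell, umi, parent) triples; drop UMI conflicts.

    A (cell, umi) pair observed with two or more distinct parents is removed
    entirely — conservative and order-independent.  Output is sorted by
    (cell, umi, parent) for determinism.
    """
    by_pair: dict[tuple[str, str], set[str]] = {}
    for rec in records:
        by_pair.setdefault((rec.cell, rec.umi), set()).add(rec.parent_id)
    kept = [
        CountRecord(cell, umi, parents.pop())
        for (cell, umi), parents in by_pair.items()
        if len(parents) == 1
    ]
    kept.sort(key=lambda r: (r.cell, r.umi, r.parent_id))
    return kept


def _fastq_pairs(path1: str, path2: str) -> Iterator[tuple[str, str]]:
    """Yield (r1_sequence, r2_sequence) from record-synchronized FASTQ files."""
    with pysam.FastxFile(path1) as fq1, pysam.FastxFile(path2) as fq2:
        it1, it2 = iter(fq1), iter(fq2)
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise ValidationError(
                    f"paired FASTQ files {path1} and {path2} have different record counts"
                )
            yield rec1.sequence.upper(), rec2.sequence.upper()


def records_to_matrix(
    records: list[CountRecord], whitelist: FeatureWhitelist
) -> CountMatrix:
    """Build the sparse matrix from deduplicated records."""
    features = whitelist.feature_ids
    feat_index = {f: j for j, f in enumerate(features)}
    cells = sorted({rec.cell for rec in records})
    cell_index = {c: i for i, c in enumerate(cells)}
    rows = [cell_index[r.cell] for r in records]
    cols = [feat_index[r.parent_id] for r in records]
    counts = scipy.sparse.coo_matrix(
        (np.ones(len(records), dtype=np.int64), (rows, cols)),
        shape=(len(cells), len(features)),
    ).tocsr()
    return CountMatrix(cells=cells, features=features, counts=counts)


def quantify(
    fastq_r1: str | os.PathLike,
    fastq_r2: str | os.PathLike,
    whitelist: FeatureWhitelist,
    layout: ReadLayout,
    onlist: Optional[frozenset[str]] = None,
    mmap: Optional[MismatchMap] = None,
) -> tuple[CountMatrix, RunStats]:
    """Run the full pipeline on paired FASTQ files.

    Per pair: extract_cell_umi -> correct_cell_barcode -> trim_tag_read ->
    scan_read; assigned reads become CountRecords, which are deduplicated and
    tabulated.  Raises on mismatched R1/R2 record counts.
    """
    if mmap is None:
        mmap = build_mismatch_map(whitelist)
    stats = RunStats()
    records: list[CountRecord] = []
    for r1_seq, r2_seq in _fastq_pairs(os.fspath(fastq_r1), os.fspath(fastq_r2)):
        stats.pairs_read += 1
        extracted = extract_cell_umi(r1_seq, layout)
        if extracted is None:
            stats.discarded_by_layout += 1
            continue
        cell, umi = extracted
        cell_corr = correct_cell_barcode(cell, onlist)
        if cell_corr is None:
            stats.discarded_by_onlist += 1
            continue
        tag_seq = r1_seq if layout.tag_read == 1 else r2_seq
        trimmed = trim_tag_read(tag_seq, layout)
        if trimmed is None:
            stats.discarded_by_layout += 1
            continue
        status, hit = scan_read(
            trimmed, mmap, revcomp_flag=layout.revcomp, scan_offset=layout.scan_offset
        )
        if status is ScanStatus.UNASSIGNED:
            stats.unassigned += 1
        elif status is ScanStatus.AMBIGUOUS:
            stats.ambiguous += 1
        else:
            stats.assigned += 1
            records.append(CountRecord(cell_corr, umi, hit.parent_id))

    deduped = deduplicate(records)
    stats.umis_after_dedup = len(deduped)
    return records_to_matrix(deduped, whitelist), stats


def write_matrix(matrix: CountMatrix, out_dir: str | os.PathLike) -> None:
    """Write matrix.mtx (MatrixMarket coordinate integer, 1-based indices),
    barcodes.txt (row order) and features.txt (column order)."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(out_dir, "matrix.mtx"),
        matrix.counts.tocoo().astype(np.int64),
        field="integer",
        symmetry="general",
    )
    with open(os.path.join(out_dir, "barcodes.txt"), "w") as fh:
        fh.writelines(f"{c}\n" for c in matrix.cells)
    with open(os.path.join(out_dir, "features.txt"), "w") as fh:
        fh.writelines(f"{f}\n" for f in matrix.features)


def read_matrix(out_dir: str | os.PathLike) -> CountMatrix:
    """Read back what :func:`write_matrix` wrote; exact round-trip."""
    out_dir = os.fspath(out_dir)
    counts = scipy.io.mmread(os.path.join(out_dir, "matrix.mtx")).tocsr().astype(np.int64)
    with open(os.path.join(out_dir, "barcodes.txt")) as fh:
        cells = [line.strip() for line in fh if line.strip()]
    with open(os.path.join(out_dir, "features.txt")) as fh:
        features = [line.strip() for line in fh if line.strip()]
    if counts.shape != (len(cells), len(features)):
        raise ValidationError(
            f"matrix shape {counts.shape} does not match label files "
            f"({len(cells)} cells, {len(features)} features)"
        )
    return CountMatrix(cells=cells, features=features, counts=counts)


def write_run_info(stats: RunStats, config: dict, out_dir: str | os.PathLike) -> None:
    """Write run_info.json: the seven counters plus the resolved config."""
    payload = {"stats": stats.to_dict(), "config": config}
    with open(os.path.join(os.fspath(out_dir), "run_info.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
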