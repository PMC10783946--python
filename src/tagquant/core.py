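"""Domain types and sequence utilities shared by the whole pipeline.

A *feature barcode* (tag) is a short designed DNA sequence identifying an
orthogonal feature — an antibody, a sample hashtag, an sgRNA — rather than a
transcript.  Everything downstream (mismatch-map construction, read scanning,
QC, simulation) operates on a validated :class:`FeatureWhitelist` of such
barcodes.

Conventions used throughout the package:

* sequences are uppercase strings over the 4-letter alphabet ``A/C/G/T``;
  ``N`` and IUPAC ambiguity codes are rejected at parse time, never fixed up
  silently, because single-base mismatch enumeration is only defined over the
  4-letter alphabet;
* all intervals are 0-based, half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Literal, Optional

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class TagQuantError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(TagQuantError):
    """Invalid user input: malformed whitelist, bad layout, bad parameters."""


def _check_dna(seq: str, context: str = "sequence") -> None:
    if not seq:
        raise ValidationError(f"{context} is empty")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValidationError(
            f"{context} {seq!r} contains invalid character(s) "
            f"{sorted(bad)}; only uppercase A/C/G/T are allowed"
        )


def hamming(seq_a: str, seq_b: str) -> int:
    """Number of mismatching positions between two equal-length strings.

    Raises :class:`ValidationError` on unequal lengths (Hamming distance is
    undefined there; callers that need to compare ragged sets must skip and
    count those pairs explicitly).
    """
    if len(seq_a) != len(seq_b):
        raise ValidationError(
            f"hamming distance requires equal lengths, got {len(seq_a)} and {len(seq_b)}"
        )
    return sum(a != b for a, b in zip(seq_a, seq_b))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (an involution)."""
    _check_dna(seq, "revcomp input")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FeatureBarcode:
    """One designed feature barcode: a label and its DNA sequence."""

    feature_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.feature_id or any(c.isspace() for c in self.feature_id):
            raise ValidationError(
                f"feature_id {self.feature_id!r} must be non-empty and contain no whitespace"
            )
        _check_dna(self.sequence, f"barcode {self.feature_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FeatureWhitelist:
    """Ordered collection of feature barcodes with uniqueness guarantees.

    ``uniform_length`` is true iff every sequence has the same length;
    quantification and mismatch-map construction require it, the QC metrics
    do not.
    """

    barcodes: list[FeatureBarcode]

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValidationError("whitelist is empty")
        seen_ids: dict[str, int] = {}
        seen_seqs: dict[str, str] = {}
        for bc in self.barcodes:
            if bc.feature_id in seen_ids:
                raise ValidationError(f"duplicate feature_id {bc.feature_id!r} in whitelist")
            if bc.sequence in seen_seqs:
                raise ValidationError(
                    f"duplicate sequence {bc.sequence!r} shared by "
                    f"{seen_seqs[bc.sequence]!r} and {bc.feature_id!r}"
                )
            seen_ids[bc.feature_id] = 1
            seen_seqs[bc.sequence] = bc.feature_id

    @property
    def uniform_length(self) -> bool:
        lengths = {len(bc) for bc in self.barcodes}
        return len(lengths) == 1

    @property
    def length(self) -> int:
        """Common barcode length L; errors if the whitelist is ragged."""
        lengths = {len(bc) for bc in self.barcodes}
        if len(lengths) != 1:
            raise ValidationError(
                f"whitelist has mixed barcode lengths {sorted(lengths)}; "
                "a uniform length is required here"
            )
        return lengths.pop()

    @property
    def feature_ids(self) -> list[str]:
        return [bc.feature_id for bc in self.barcodes]

    @property
    def sequences(self) -> list[str]:
        return [bc.sequence for bc in self.barcodes]

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self):
        return iter(self.barcodes)


@dataclass
class ReadLayout:
    """Where the cell barcode, UMI and tag live in a read pair.

    ``cb_span`` and ``umi_span`` are 0-based half-open intervals in read 1.
    The tag read (mate ``tag_read``) is optionally trimmed before scanning:
    anchor trimming first (keep the flank on the ``anchor_keep`` side of the
    first exact occurrence of ``anchor``; reads without the anchor are
    discarded), then ``trim5``/``trim3`` fixed trimming.  ``scan_offset``
    restricts matching to a single window start instead of scanning all
    offsets; ``revcomp`` additionally scans the reverse complement.
    """

    cb_span: tuple[int, int]
    umi_span: tuple[int, int]
    tag_read: int = 2
    trim5: int = 0
    trim3: int = 0
    anchor: Optional[str] = None
    anchor_keep: Literal["before", "after"] = "after"
    scan_offset: Optional[int] = None
    revcomp: bool = False

    def __post_init__(self) -> None:
        for name, (start, end) in (("cb_span", self.cb_span), ("umi_span", self.umi_span)):
            if start < 0 or end <= start:
                raise ValidationError(f"{name} {start}:{end} is not a valid half-open interval")
        a0, a1 = self.cb_span
        b0, b1 = self.umi_span
        if max(a0, b0) < min(a1, b1):
            raise ValidationError("cb_span and umi_span overlap")
        if self.tag_read not in (1, 2):
            raise ValidationError("tag_read must be 1 or 2")
        if self.trim5 < 0 or self.trim3 < 0:
            raise ValidationError("trim5/trim3 must be non-negative")
        if self.anchor is not None:
            _check_dna(self.anchor, "anchor")
            if self.anchor_keep not in ("before", "after"):
                raise ValidationError("anchor_keep must be 'before' or 'after'")

    @property
    def min_read1_length(self) -> int:
        return max(self.cb_span[1], self.umi_span[1])


def read_whitelist(
    path: str | os.PathLike,
    format: Literal["tsv", "fasta"] = "tsv",
    header: bool = False,
) -> FeatureWhitelist:
    """Read a feature-barcode whitelist from TSV or FASTA.

    TSV dialect: tab-separated, ``feature_id<TAB>sequence``, extra columns
    ignored, no header unless ``header=True`` skips line 1.  FASTA uses the
    record id as feature_id.  File order is preserved.  Duplicate ids or
    sequences and non-ACGT characters are hard errors naming the offender.
    """
    path = os.fspath(path)
    barcodes: list[FeatureBarcode] = []
    if format == "tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if header and lineno == 1:
                    continue
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValidationError(
                        f"{path}:{lineno}: expected at least 2 tab-separated columns "
                        f"(feature_id, sequence), got {len(fields)}"
                    )
                try:
                    barcodes.append(FeatureBarcode(fields[0], fields[1]))
                except ValidationError as exc:
                    raise ValidationError(f"{path}:{lineno}: {exc}") from None
    elif format == "fasta":
        for record in SeqIO.parse(path, "fasta"):
            barcodes.append(FeatureBarcode(record.id, str(record.seq)))
    else:
        raise ValidationError(f"unknown whitelist format {format!r}")
    return FeatureWhitelist(barcodes)


def read_onlist(path: str | os.PathLike) -> frozenset[str]:
    """Read a cell-barcode on-list: plain text, one barcode per line."""
    cells: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            cell = line.strip()
            if not cell:
                continue
            _check_dna(cell, f"{os.fspath(path)}:{lineno}: cell barcode")
            cells.add(cell)
    if not cells:
        raise ValidationError(f"on-list {os.fspath(path)} contains no barcodes")
    return frozenset(cells)
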