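"""Single-base mismatch map: the in-memory form of the "mismatched FASTA".

Each feature barcode of length L is expanded into itself plus its 3L
single-substitution variants, every variant labelled with its parent.  A read
window that matches any entry is thereby assigned to the parent directly, so
summing counts over entries realizes 1-substitution error correction
("error collapse").

Collision policy (whitelists whose barcodes are closer than Hamming
distance 3 generate colliding variants):

* a parent's exact sequence always maps to that parent, taking priority over
  any variant claim on the same string;
* a variant equal to another parent's exact sequence is removed from the
  generating parent's variant set (recorded in ``exact_collisions``);
* a variant generated by two or more parents is dropped entirely (recorded in
  ``ambiguous_variants``) — conservative, mirroring a multi-mapping read
  being discarded.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from itertools import combinations

from .core import FeatureWhitelist, ValidationError, _check_dna, hamming

logger = logging.getLogger(__name__)

_BASES = "ACGT"


def generate_mismatches(sequence: str) -> list[str]:
    """All 3L single-substitution variants of ``sequence``, excluding itself.

    Deterministic order: position-major, then alphabetical substitute base,
    so downstream FASTA serialization is byte-reproducible.
    """
    _check_dna(sequence, "sequence")
    variants = []
    for pos, orig in enumerate(sequence):
        for base in _BASES:
            if base != orig:
                variants.append(sequence[:pos] + base + sequence[pos + 1 :])
    return variants


@dataclass
class MismatchMap:
    """Lookup from variant sequence to parent feature_id, with bookkeeping.

    ``entries`` maps every retained sequence (exact parents and surviving
    variants) to exactly one parent id.  ``ambiguous_variants`` holds variants
    dropped because two or more parents generated them; ``exact_collisions``
    holds (variant, generating parent) pairs suppressed because the variant
    equals some other parent's exact sequence.  The two removal records are
    disjoint from ``entries`` keys except that an exact-collision string is
    itself present in ``entries`` under its own parent.
    """

    entries: dict[str, str]
    exact: dict[str, str]
    ambiguous_variants: set[str]
    exact_collisions: set[tuple[str, str]]
    retained_variants: dict[str, int]
    L: int
    n_parents: int

    def lookup(self, sequence: str) -> str | None:
        """Parent id for ``sequence``, or None if absent/ambiguous."""
        return self.entries.get(sequence)

    def is_exact(self, sequence: str) -> bool:
        return sequence in self.exact


def build_mismatch_map(whitelist: FeatureWhitelist) -> MismatchMap:
    """Expand a uniform-length whitelist into its single-mismatch map.

    Emits a warning (not an error) when any parent pair sits at Hamming
    distance <= 2, since such pairs are guaranteed to lose variants.
    """
    L = whitelist.length  # raises on ragged whitelists
    exact = {bc.sequence: bc.feature_id for bc in whitelist}

    close_pairs = [
        (a.feature_id, b.feature_id, hamming(a.sequence, b.sequence))
        for a, b in combinations(whitelist.barcodes, 2)
        if hamming(a.sequence, b.sequence) <= 2
    ]
    for id_a, id_b, d in close_pairs:
        logger.warning(
            "barcodes %s and %s are at Hamming distance %d (<= 2); "
            "some mismatch variants will be lost to collisions",
            id_a, id_b, d,
        )

    # claims: variant -> list of generating parents, in whitelist order
    claims: dict[str, list[str]] = {}
    variant_order: dict[str, list[str]] = {}
    for bc in whitelist:
        variant_order[bc.feature_id] = generate_mismatches(bc.sequence)
        for variant in variant_order[bc.feature_id]:
            claims.setdefault(variant, []).append(bc.feature_id)

    entries = dict(exact)
    ambiguous: set[str] = set()
    collisions: set[tuple[str, str]] = set()
    retained = {bc.feature_id: 0 for bc in whitelist}
    for variant, parents in claims.items():
        if variant in exact:
            # exact sequences win; suppress every variant claim on them
            for parent in parents:
                collisions.add((variant, parent))
        elif len(parents) > 1:
            ambiguous.add(variant)
        else:
            entries[variant] = parents[0]
            retained[parents[0]] += 1

    return MismatchMap(
        entries=entries,
        exact=exact,
        ambiguous_variants=ambiguous,
        exact_collisions=collisions,
        retained_variants=retained,
        L=L,
        n_parents=len(whitelist),
    )


def write_mismatch_fasta(mmap: MismatchMap, path: str | os.PathLike) -> None:
    """Serialize the map as FASTA, one record per entry.

    Header grammar: ``>{parent_id}`` for the exact sequence,
    ``>{parent_id}-{pos}.{base}`` for the variant substituting ``base`` at
    0-based position ``pos``.  Records are ordered by parent (whitelist
    order was preserved in ``exact``), then variant order (position-major,
    alphabetical).  One sequence line per record, no wrapping.
    """
    if not mmap.entries:
        raise ValidationError("refusing to write an empty mismatch FASTA")
    lines: list[str] = []
    for parent_seq, parent_id in mmap.exact.items():
        lines.append(f">{parent_id}\n{parent_seq}\n")
        for pos, orig in enumerate(parent_seq):
            for base in _BASES:
                if base == orig:
                    continue
                variant = parent_seq[:pos] + base + parent_seq[pos + 1 :]
                if mmap.entries.get(variant) == parent_id and variant not in mmap.exact:
                    lines.append(f">{parent_id}-{pos}.{base}\n{variant}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def read_mismatch_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Parse a mismatch FASTA back into a variant->parent dict.

    Parent id is the header stripped of any ``-{pos}.{base}`` variant suffix.
    """
    from Bio import SeqIO

    entries: dict[str, str] = {}
    for record in SeqIO.parse(os.fspath(path), "fasta"):
        name = record.id
        parent = name
        if "-" in name:
            stem, _, suffix = name.rpartition("-")
            if "." in suffix and suffix.split(".")[0].isdigit():
                parent = stem
        entries[str(record.seq)] = parent
    return entries
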