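"""Zero-mismatch, strand-aware mapping of short inserts to reference sets.

Perfect matching is the deliberate contract: piRNA profiling counts only
reads that align to the genome or a transposon consensus without a single
mismatch, so the mapper is a k-mer hash index (seed on the first 23-mer,
the minimum insert length) plus full-length verification on both strands.
All perfect hits are reported; downstream counting policies decide what a
multi-mapping read contributes.

Coordinates are 0-based half-open in reference orientation; a "-" strand
hit means the insert equals the reverse complement of the reference slice.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .dna import reverse_complement
from .preprocess import TrimmedRead, MIN_INSERT_LEN, MAX_INSERT_LEN


@dataclass
class Reference:
    id: str
    sequence: str
    category: str = "transposon"  # {genome, transposon, reas}


@dataclass
class Hit:
    """One perfect alignment of a read to a reference."""

    read_id: str
    reference_id: str
    start: int
    end: int  # exclusive
    strand: str  # "+" or "-"


class ExactIndex:
    """Hash index from fixed-length forward k-mers to (reference, offset).

    Only forward windows are stored; reverse-complement queries are handled
    at lookup time.  Windows containing N are skipped, so inserts with N
    can never map (harmless under the zero-mismatch contract).
    """

    def __init__(self, key_length: int) -> None:
        self.key_length = key_length
        self.table: dict[str, list[tuple[str, int]]] = defaultdict(list)
        self.sequences: dict[str, str] = {}

    def __len__(self) -> int:
        return len(self.table)


def build_index(references: Iterable[Reference], key_length: int = MIN_INSERT_LEN) -> ExactIndex:
    """Index every forward ``key_length``-mer of every reference."""
    if key_length < 1 or key_length > MAX_INSERT_LEN:
        raise ValueError(f"key_length must be in [1, {MAX_INSERT_LEN}], got {key_length}")
    index = ExactIndex(key_length)
    for ref in references:
        if ref.id in index.sequences:
            raise ValueError(f"duplicate reference id {ref.id!r}")
        seq = ref.sequence
        index.sequences[ref.id] = seq
        k = key_length
        for start in range(0, len(seq) - k + 1):
            window = seq[start : start + k]
            if "N" in window:
                continue
            index.table[window].append((ref.id, start))
    return index


def map_exact(insert: str, index: ExactIndex, read_id: str = "") -> list[Hit]:
    """All zero-mismatch hits of ``insert`` on both strands of the index.

    Candidate sites come from the index on the insert's first k-mer (and,
    for "-" hits, on the first k-mer of its reverse complement — which is a
    forward window of the reference); candidates are then verified over the
    full insert length.
    """
    n = len(insert)
    if n < MIN_INSERT_LEN or n > MAX_INSERT_LEN:
        raise ValueError(f"insert length {n} outside [{MIN_INSERT_LEN}, {MAX_INSERT_LEN}]")
    if "N" in insert:
        return []
    k = index.key_length
    hits: list[Hit] = []
    for ref_id, start in index.table.get(insert[:k], ()):
        if index.sequences[ref_id][start : start + n] == insert:
            hits.append(Hit(read_id, ref_id, start, start + n, "+"))
    rc = reverse_complement(insert)
    for ref_id, start in index.table.get(rc[:k], ()):
        if index.sequences[ref_id][start : start + n] == rc:
            hits.append(Hit(read_id, ref_id, start, start + n, "-"))
    return hits


@dataclass
class MappingResult:
    """Genome mappability plus all transposon hits for one library.

    ``genome_mapped_read_ids`` counts distinct reads (a multi-mapper counts
    once); its size is the RPM denominator.  ``transposon_hits`` holds every
    perfect transposon hit keyed by read id.
    """

    genome_mapped_read_ids: set[str]
    transposon_hits: dict[str, list[Hit]]

    @property
    def genome_mapped_total(self) -> int:
        return len(self.genome_mapped_read_ids)


def map_library(
    inserts: Sequence[TrimmedRead],
    genome_index: ExactIndex,
    transposon_index: ExactIndex,
) -> MappingResult:
    """Map a trimmed library against the genome and the transposon set.

    Reads are collapsed to unique insert sequences before mapping and the
    results re-expanded to read ids afterwards — provably identical output,
    at a fraction of the lookups for deeply duplicated libraries.
    """
    by_seq: dict[str, list[str]] = defaultdict(list)
    for tr in inserts:
        by_seq[tr.insert].append(tr.id)

    genome_mapped: set[str] = set()
    transposon_hits: dict[str, list[Hit]] = {}
    for seq, read_ids in by_seq.items():
        if genome_index.sequences and map_exact(seq, genome_index):
            genome_mapped.update(read_ids)
        t_hits = map_exact(seq, transposon_index)
        if t_hits:
            for rid in read_ids:
                transposon_hits[rid] = [
                    Hit(rid, h.reference_id, h.start, h.end, h.strand) for h in t_hits
                ]
    return MappingResult(genome_mapped, transposon_hits)
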