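"""Per-library piRNA statistics: RPM profiles, 1U bias, antisense bias.

Counts are of distinct reads: a read contributes at most once per
(transposon, strand) however many positions it hits, and contributes to
every transposon it hits.  Abundances are reads per million (RPM),
normalized to the number of distinct reads that map perfectly to the
genome — the library's sequencing-depth proxy.

The 1U bias (the hallmark 5'-uridine preference of primary piRNAs) is
computed over transposon-mapped reads, matching how the bias is reported
for transposon piRNAs; the same statistic over all genome-mapped reads is
exposed alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .align import Hit, MappingResult
from .preprocess import TrimmedRead


@dataclass
class TransposonCounts:
    transposon_id: str
    sense_reads: int
    antisense_reads: int


@dataclass
class LibraryProfile:
    """All per-library outputs of the profiling stage.

    ``table`` has one row per transposon: sense_reads, antisense_reads,
    sense_rpm, antisense_rpm (index: transposon_id).  ``one_u_bias`` is a
    percentage over distinct transposon-mapped reads; ``one_u_bias_genome``
    the same over all distinct genome-mapped reads; ``antisense_bias`` the
    pooled antisense/sense read-count ratio.
    """

    library_id: str
    genome_mapped_total: int
    table: pd.DataFrame
    one_u_bias: float
    antisense_bias: float
    one_u_bias_genome: Optional[float] = None

    def total_rpm(self, transposon_id: str) -> float:
        row = self.table.loc[transposon_id]
        return float(row["sense_rpm"] + row["antisense_rpm"])


def count_transposon_reads(
    transposon_hits: Mapping[str, Sequence[Hit]],
) -> list[TransposonCounts]:
    """Distinct-read counts per transposon and strand.

    Multiple hits of one read on one (transposon, strand) collapse to one;
    a read hitting several transposons counts toward each.
    """
    sense: dict[str, int] = {}
    anti: dict[str, int] = {}
    for hits in transposon_hits.values():
        seen = {(h.reference_id, h.strand) for h in hits}
        for tid, strand in seen:
            bucket = sense if strand == "+" else anti
            bucket[tid] = bucket.get(tid, 0) + 1
    ids = sorted(set(sense) | set(anti))
    return [TransposonCounts(t, sense.get(t, 0), anti.get(t, 0)) for t in ids]


def rpm_normalize(
    counts: Sequence[TransposonCounts],
    genome_mapped_total: int,
) -> pd.DataFrame:
    """Reads-per-million table: rpm = 1e6 * count / genome_mapped_total."""
    if genome_mapped_total <= 0:
        raise ValueError("genome_mapped_total must be positive (empty library?)")
    scale = 1e6 / genome_mapped_total
    df = pd.DataFrame(
        {
            "sense_reads": [c.sense_reads for c in counts],
            "antisense_reads": [c.antisense_reads for c in counts],
        },
        index=pd.Index([c.transposon_id for c in counts], name="transposon_id"),
    )
    df["sense_rpm"] = df["sense_reads"] * scale
    df["antisense_rpm"] = df["antisense_reads"] * scale
    return df


def filter_abundant(profile: LibraryProfile, threshold_rpm: float = 500.0) -> list[str]:
    """Transposons whose total (sense + antisense) RPM strictly exceeds the threshold.

    "More than 500 RPM" is read strictly: a transposon at exactly the
    threshold is excluded.
    """
    total = profile.table["sense_rpm"] + profile.table["antisense_rpm"]
    return sorted(total.index[total > threshold_rpm])


def one_u_bias(inserts: Iterable[str]) -> float:
    """Percentage of inserts whose 5'-most base is T (U in the RNA)."""
    total = 0
    with_u = 0
    for ins in inserts:
        total += 1
        if ins.startswith("T"):
            with_u += 1
    if total == 0:
        raise ValueError("1U bias undefined: no reads")
    return 100.0 * with_u / total


def antisense_bias(counts: Sequence[TransposonCounts]) -> float:
    """Pooled antisense/sense ratio over all transposons (not a mean of ratios)."""
    sense = sum(c.sense_reads for c in counts)
    anti = sum(c.antisense_reads for c in counts)
    if sense == 0:
        raise ValueError("antisense bias undefined: no pooled sense reads")
    return anti / sense


def build_profile(
    library_id: str,
    trimmed: Sequence[TrimmedRead],
    mapping: MappingResult,
    transposon_ids: Optional[Sequence[str]] = None,
) -> LibraryProfile:
    """Assemble the full per-library profile from trimmed reads and hits.

    ``transposon_ids``, when given, fixes the table's row set (zero rows
    included) so profiles over one reference set share a namespace.
    """
    counts = count_transposon_reads(mapping.transposon_hits)
    if transposon_ids is not None:
        have = {c.transposon_id for c in counts}
        counts = list(counts) + [
            TransposonCounts(t, 0, 0) for t in transposon_ids if t not in have
        ]
        counts.sort(key=lambda c: c.transposon_id)
    table = rpm_normalize(counts, mapping.genome_mapped_total)

    insert_by_id = {tr.id: tr.insert for tr in trimmed}
    t_inserts = [insert_by_id[rid] for rid in mapping.transposon_hits]
    g_inserts = [insert_by_id[rid] for rid in mapping.genome_mapped_read_ids]
    return LibraryProfile(
        library_id=library_id,
        genome_mapped_total=mapping.genome_mapped_total,
        table=table,
        one_u_bias=one_u_bias(t_inserts),
        antisense_bias=antisense_bias(counts),
        one_u_bias_genome=one_u_bias(g_inserts) if g_inserts else None,
    )
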