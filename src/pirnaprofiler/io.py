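"""File I/O: FASTA/FASTQ via Biopython, TSV tables, plain SAM emission."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import Hit, Reference
from .dna import reverse_complement
from .preprocess import RawRead, TrimmedRead
from .simulate import GroundTruthRecord


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def read_reads(path) -> list[RawRead]:
    """FASTQ or FASTA reads, decided by file extension."""
    path = Path(path)
    fmt = "fasta" if path.suffix.lower() in {".fa", ".fasta", ".fna"} else "fastq"
    out = []
    for rec in SeqIO.parse(str(path), fmt):
        qual = None
        if fmt == "fastq":
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(RawRead(rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(reads: Iterable[RawRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality or "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def write_ground_truth(truth: Iterable[GroundTruthRecord], path) -> None:
    df = pd.DataFrame(
        {
            "read_id": [t.read_id for t in truth],
            "source": [t.source for t in truth],
            "strand": [t.strand for t in truth],
            "true_insert": [t.true_insert for t in truth],
            "adapter_start": [("" if t.adapter_start is None else t.adapter_start) for t in truth],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> list[GroundTruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        start = None if row.adapter_start == "" else int(float(row.adapter_start))
        out.append(GroundTruthRecord(row.read_id, row.source, row.strand, row.true_insert, start))
    return out


def write_trim_report(tallies: dict[str, int], path) -> None:
    pd.DataFrame(
        {"category": list(tallies), "count": list(tallies.values())}
    ).to_csv(path, sep="\t", index=False)


def write_inserts_fasta(trimmed: Iterable[TrimmedRead], path) -> None:
    write_fasta(((t.id, t.insert) for t in trimmed), path)


def write_hits_tsv(hits: Iterable[Hit], path) -> None:
    pd.DataFrame(
        [(h.read_id, h.reference_id, h.start, h.end, h.strand) for h in hits],
        columns=["read_id", "reference_id", "start", "end", "strand"],
    ).to_csv(path, sep="\t", index=False)


def write_sam(
    hits: Iterable[Hit],
    references: Sequence[Reference],
    inserts_by_read: dict[str, str],
    path,
) -> None:
    """Plain unsorted SAM of perfect hits (flag 0/16, CIGAR nM, NM:i:0).

    Minus-strand records store the reverse complement of the insert, per
    the convention that SEQ is in reference-forward orientation.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for ref in references:
            fh.write(f"@SQ\tSN:{ref.id}\tLN:{len(ref.sequence)}\n")
        for h in hits:
            seq = inserts_by_read[h.read_id]
            flag = 0
            if h.strand == "-":
                flag = 16
                seq = reverse_complement(seq)
            length = h.end - h.start
            fh.write(
                f"{h.read_id}\t{flag}\t{h.reference_id}\t{h.start + 1}\t255\t"
                f"{length}M\t*\t0\t0\t{seq}\t*\tNM:i:0\n"
            )


def sha256_file(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()
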