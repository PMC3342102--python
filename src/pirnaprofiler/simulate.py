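"""Ground-truth synthetic references and small-RNA libraries.

The generator emulates the statistical structure a piRNA profiling run
assumes: a genome carrying verbatim copies of every transposon consensus
(so each transposon-derived read also maps perfectly to the genome, making
the RPM denominator well defined), adapter-ligated 36-cycle reads whose
23-30 nt inserts are drawn from the consensi with configurable
per-transposon abundance, antisense fraction, and 5'-uridine probability,
plus genome-background reads and adapterless junk reads.  Every read comes
with a ground-truth record (source, strand, pre-error insert, adapter
offset) so downstream stages can be verified exactly.

Presets encode the ovary libraries of the masculinized-silkworm study:
``wt-ovary`` a wild-type ovary (1U bias 73%, antisense bias 3.5) and
``kg-ovary`` the KG mutant ovary (1U bias 69%, antisense bias 3.7);
``KG_REDUCED_FACTOR`` scales designated transposons' abundances to encode
the ~40% piRNA reduction the mutant shows for the sex-determining-region
elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .dna import ALPHABET, reverse_complement, validate_nucleotides
from .preprocess import RawRead, find_adapter, MIN_INSERT_LEN, MAX_INSERT_LEN

# Stand-in 3' adapter (the study kit's sequence is unpublished); any >=6 nt
# ACGT string works, this 20-mer mirrors common small-RNA cloning adapters.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAG"

#: Generative parameters per library preset: the 5'-U probability equals the
#: printed 1U-bias percentage / 100, and the antisense fraction is r/(1+r)
#: for the printed pooled antisense/sense ratio r.
PRESETS: dict[str, dict[str, float]] = {
    "wt-ovary": {"u_probability": 0.73, "antisense_fraction": 3.5 / 4.5},
    "kg-ovary": {"u_probability": 0.69, "antisense_fraction": 3.7 / 4.7},
}

#: Abundance-weight factor for transposons silenced less effectively in the
#: mutant preset: relative expression 0.6 == ~40% reduction.
KG_REDUCED_FACTOR = 0.6

_MAX_START_RETRIES = 100


@dataclass
class TransposonModel:
    """One transposon consensus plus its generative parameters."""

    id: str
    consensus: str
    abundance_weight: float = 1.0
    antisense_fraction: float = 0.5
    u_probability: float = 0.25

    def __post_init__(self) -> None:
        validate_nucleotides(self.consensus, what=f"consensus of {self.id}")
        if self.abundance_weight < 0:
            raise ValueError(f"{self.id}: abundance_weight must be non-negative")
        if not 0.0 <= self.antisense_fraction <= 1.0:
            raise ValueError(f"{self.id}: antisense_fraction outside [0, 1]")
        if not 0.0 <= self.u_probability <= 1.0:
            raise ValueError(f"{self.id}: u_probability outside [0, 1]")


@dataclass
class LibraryConfig:
    """Knobs for one simulated sequencing library."""

    n_pirna_reads: int
    n_background_reads: int = 0
    n_junk_reads: int = 0
    adapter: str = DEFAULT_ADAPTER
    cycle_length: int = 36
    insert_length_weights: Mapping[int, float] = field(
        default_factory=lambda: {n: 1.0 for n in range(MIN_INSERT_LEN, MAX_INSERT_LEN + 1)}
    )
    error_rate: float = 0.0
    seed: int = 0
    library_id: str = "lib"

    def __post_init__(self) -> None:
        validate_nucleotides(self.adapter, what="adapter")
        if len(self.adapter) < 6:
            raise ValueError("adapter must be at least 6 nt")
        bad = [k for k in self.insert_length_weights if not MIN_INSERT_LEN <= k <= MAX_INSERT_LEN]
        if bad:
            raise ValueError(f"insert lengths outside [{MIN_INSERT_LEN}, {MAX_INSERT_LEN}]: {bad}")
        if self.cycle_length < max(self.insert_length_weights):
            raise ValueError("cycle_length shorter than the longest insert")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class GroundTruthRecord:
    """What the generator actually emitted for one read, pre-error."""

    read_id: str
    source: str  # transposon id | "genome" | "junk"
    strand: str  # "+" or "-"
    true_insert: str
    adapter_start: Optional[int]


@dataclass
class ReferenceSet:
    """Transposon consensi plus a genome hosting verbatim copies of each.

    ``copy_locations`` maps transposon id to (start, end) genome intervals;
    ``background_intervals`` are the copy-free intervals background reads
    are drawn from, so ground-truth source labels stay unambiguous.
    """

    transposons: list[TransposonModel]
    genome: str
    copy_locations: dict[str, list[tuple[int, int]]]
    background_intervals: list[tuple[int, int]]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def generate_references(
    n_transposons: int,
    length_range: tuple[int, int] = (500, 2000),
    genome_length: int = 400_000,
    n_transposon_copies_in_genome: int = 1,
    seed: int = 0,
) -> ReferenceSet:
    """Random transposon consensi embedded verbatim in a random genome.

    The genome alternates random background gaps with the shuffled copies,
    so every consensus window occurs in the genome at least once per copy.
    Raises ``ValueError`` when ``genome_length`` cannot host the requested
    copies plus at least 50 nt of background around each.
    """
    if n_transposons < 1:
        raise ValueError("n_transposons must be >= 1")
    if n_transposon_copies_in_genome < 0:
        raise ValueError("copy count must be non-negative")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    transposons = [
        TransposonModel(
            id=f"TE{i + 1:03d}",
            consensus=_random_seq(rng, int(rng.integers(lo, hi + 1))),
        )
        for i in range(n_transposons)
    ]

    pieces: list[str] = []
    for model in transposons:
        pieces.extend([model.id] * n_transposon_copies_in_genome)
    order = rng.permutation(len(pieces)) if pieces else np.array([], dtype=int)
    pieces = [pieces[i] for i in order]

    by_id = {m.id: m.consensus for m in transposons}
    total_copy = sum(len(by_id[p]) for p in pieces)
    n_gaps = len(pieces) + 1
    background_total = genome_length - total_copy
    min_gap = 50
    if background_total < n_gaps * min_gap:
        raise ValueError(
            f"genome_length {genome_length} too small for {len(pieces)} copies "
            f"({total_copy} nt) plus {min_gap} nt background per gap"
        )
    # Split the background budget over the gaps, min_gap each plus a random share.
    extra = background_total - n_gaps * min_gap
    shares = rng.multinomial(extra, np.full(n_gaps, 1.0 / n_gaps))
    gap_lengths = shares + min_gap

    parts: list[str] = []
    copy_locations: dict[str, list[tuple[int, int]]] = {m.id: [] for m in transposons}
    background_intervals: list[tuple[int, int]] = []
    pos = 0
    for i, piece in enumerate(pieces):
        gap = _random_seq(rng, int(gap_lengths[i]))
        parts.append(gap)
        background_intervals.append((pos, pos + len(gap)))
        pos += len(gap)
        cons = by_id[piece]
        parts.append(cons)
        copy_locations[piece].append((pos, pos + len(cons)))
        pos += len(cons)
    gap = _random_seq(rng, int(gap_lengths[-1]))
    parts.append(gap)
    background_intervals.append((pos, pos + len(gap)))
    genome = "".join(parts)
    assert len(genome) == genome_length
    return ReferenceSet(transposons, genome, copy_locations, background_intervals)


def apply_preset(
    transposons: Sequence[TransposonModel],
    preset: str,
    reduced_ids: Sequence[str] = (),
    reduction_factor: float = KG_REDUCED_FACTOR,
) -> list[TransposonModel]:
    """Return models with a preset's biases, optionally de-silencing some.

    ``reduced_ids`` transposons get their abundance weight multiplied by
    ``reduction_factor`` — the mutant-ovary situation where a designated set
    of (W-chromosome-derived) piRNAs drops while the rest are unchanged.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    params = PRESETS[preset]
    reduced = set(reduced_ids)
    unknown = reduced - {m.id for m in transposons}
    if unknown:
        raise ValueError(f"reduced_ids not in transposon set: {sorted(unknown)}")
    out = []
    for m in transposons:
        w = m.abundance_weight * (reduction_factor if m.id in reduced else 1.0)
        out.append(replace(m, abundance_weight=w, **params))
    return out


def _sample_insert(
    rng: np.random.Generator,
    consensus: str,
    length: int,
    antisense: bool,
    want_u: bool,
) -> str:
    """One insert from ``consensus``, 5' base conditioned on ``want_u``.

    The start position is rejection-resampled until the insert's first base
    is T (want_u) or non-T (not want_u); after a capped number of retries
    the first base is substituted instead — the only case where the insert
    can carry a mismatch against its source.
    """
    if length > len(consensus):
        raise ValueError(f"insert length {length} exceeds consensus length {len(consensus)}")
    span = len(consensus) - length + 1
    start = 0
    for _ in range(_MAX_START_RETRIES):
        start = int(rng.integers(0, span))
        insert = (
            reverse_complement(consensus[start : start + length])
            if antisense
            else consensus[start : start + length]
        )
        if (insert[0] == "T") == want_u:
            return insert
    # Fallback: force the 5' base by substitution (read may no longer map).
    first = "T" if want_u else str(rng.choice(["A", "C", "G"]))
    return first + insert[1:]


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0.0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < error_rate)
    for i in hits:
        current = chars[i]
        options = [b for b in ALPHABET if b != current]
        chars[i] = str(rng.choice(options))
    return "".join(chars)


def simulate_library(
    refs: ReferenceSet,
    models: Sequence[TransposonModel],
    config: LibraryConfig,
) -> tuple[list[RawRead], list[GroundTruthRecord]]:
    """Simulate one adapter-ligated library with per-read ground truth.

    piRNA reads: transposon chosen proportionally to abundance weight,
    strand antisense with that transposon's antisense fraction, insert
    length by ``insert_length_weights``, 5' base forced to T with the
    transposon's ``u_probability`` (else forced non-T), adapter appended and
    the read truncated to ``cycle_length``, then per-base substitution
    errors.  Background reads take their inserts from copy-free genome
    intervals; junk reads are random cycles verified to contain no adapter
    occurrence within the two-mismatch tolerance.
    """
    if not models:
        raise ValueError("models must be non-empty")
    rng = np.random.default_rng(config.seed)

    weights = np.array([m.abundance_weight for m in models], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("abundance weights must sum to a positive number")
    probs = weights / weights.sum()
    lengths = np.array(sorted(config.insert_length_weights), dtype=int)
    lweights = np.array([config.insert_length_weights[n] for n in lengths], dtype=float)
    if lweights.sum() <= 0:
        raise ValueError("insert_length_weights must sum to a positive number")
    lprobs = lweights / lweights.sum()
    for m in models:
        if int(lengths.max()) > len(m.consensus):
            raise ValueError(
                f"{m.id}: consensus ({len(m.consensus)} nt) shorter than the "
                f"longest insert ({int(lengths.max())} nt)"
            )

    reads: list[RawRead] = []
    truth: list[GroundTruthRecord] = []

    def emit(read_id: str, insert: str, source: str, strand: str) -> None:
        raw = (insert + config.adapter)[: config.cycle_length]
        raw = _apply_errors(rng, raw, config.error_rate)
        reads.append(RawRead(read_id, raw, "I" * len(raw)))
        truth.append(GroundTruthRecord(read_id, source, strand, insert, len(insert)))

    model_idx = rng.choice(len(models), size=config.n_pirna_reads, p=probs)
    anti_draw = rng.random(config.n_pirna_reads)
    len_draw = rng.choice(lengths, size=config.n_pirna_reads, p=lprobs)
    u_draw = rng.random(config.n_pirna_reads)
    for i in range(config.n_pirna_reads):
        m = models[int(model_idx[i])]
        antisense = anti_draw[i] < m.antisense_fraction
        want_u = u_draw[i] < m.u_probability
        insert = _sample_insert(rng, m.consensus, int(len_draw[i]), antisense, want_u)
        emit(f"{config.library_id}:pirna:{i}", insert, m.id, "-" if antisense else "+")

    usable = [(s, e) for s, e in refs.background_intervals if e - s >= int(lengths.max())]
    if config.n_background_reads and not usable:
        raise ValueError("no background interval long enough for the requested inserts")
    if config.n_background_reads:
        iv_weights = np.array([e - s for s, e in usable], dtype=float)
        iv_probs = iv_weights / iv_weights.sum()
        iv_idx = rng.choice(len(usable), size=config.n_background_reads, p=iv_probs)
        bg_len = rng.choice(lengths, size=config.n_background_reads, p=lprobs)
        bg_strand = rng.random(config.n_background_reads) < 0.5
        for i in range(config.n_background_reads):
            s, e = usable[int(iv_idx[i])]
            length = int(bg_len[i])
            start = int(rng.integers(s, e - length + 1))
            insert = refs.genome[start : start + length]
            strand = "-" if bg_strand[i] else "+"
            if strand == "-":
                insert = reverse_complement(insert)
            emit(f"{config.library_id}:bg:{i}", insert, "genome", strand)

    for i in range(config.n_junk_reads):
        while True:
            seq = _random_seq(rng, config.cycle_length)
            if find_adapter(seq, config.adapter, max_mismatches=2, min_overlap=6) is None:
                break
        seq = _apply_errors(rng, seq, config.error_rate)
        reads.append(RawRead(f"{config.library_id}:junk:{i}", seq, "I" * len(seq)))
        truth.append(GroundTruthRecord(f"{config.library_id}:junk:{i}", "junk", "+", "", None))

    return reads, truth
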