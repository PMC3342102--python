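"""Canonical preset experiments: simulate a library and profile it end to end.

These helpers wire the generator presets through the full
trim → map → profile chain with the study's defaults (121 transposons, one
genome copy each, 200,000 piRNA reads per library, error-free reads), so a
wild-type or mutant ovary library is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .align import ExactIndex, Reference, build_index, map_library
from .preprocess import trim_and_filter
from .profile import LibraryProfile, build_profile
from .simulate import (
    DEFAULT_ADAPTER,
    KG_REDUCED_FACTOR,
    LibraryConfig,
    ReferenceSet,
    apply_preset,
    generate_references,
    simulate_library,
)


@dataclass
class StudyContext:
    """One reference set plus its prebuilt exact indexes."""

    refs: ReferenceSet
    genome_index: ExactIndex
    transposon_index: ExactIndex

    @property
    def transposon_ids(self) -> list[str]:
        return [m.id for m in self.refs.transposons]


def make_study_context(
    seed: int,
    n_transposons: int = 121,
    length_range: tuple[int, int] = (500, 2000),
    genome_length: int = 400_000,
) -> StudyContext:
    """References sized like the study's mapping targets, indexed once."""
    refs = generate_references(
        n_transposons=n_transposons,
        length_range=length_range,
        genome_length=genome_length,
        n_transposon_copies_in_genome=1,
        seed=seed,
    )
    genome_index = build_index([Reference("genome", refs.genome, "genome")])
    te_index = build_index(
        [Reference(m.id, m.consensus, "transposon") for m in refs.transposons]
    )
    return StudyContext(refs, genome_index, te_index)


def simulate_and_profile(
    ctx: StudyContext,
    preset: str,
    seed: int,
    library_id: str,
    n_pirna_reads: int = 200_000,
    n_background_reads: int = 20_000,
    n_junk_reads: int = 2_000,
    error_rate: float = 0.0,
    reduced_ids: Sequence[str] = (),
    reduction_factor: float = KG_REDUCED_FACTOR,
) -> LibraryProfile:
    """Simulate one preset library and run trim → map → profile on it."""
    models = apply_preset(
        ctx.refs.transposons, preset, reduced_ids=reduced_ids, reduction_factor=reduction_factor
    )
    config = LibraryConfig(
        n_pirna_reads=n_pirna_reads,
        n_background_reads=n_background_reads,
        n_junk_reads=n_junk_reads,
        adapter=DEFAULT_ADAPTER,
        error_rate=error_rate,
        seed=seed,
        library_id=library_id,
    )
    reads, _ = simulate_library(ctx.refs, models, config)
    trimmed, _ = trim_and_filter(reads, config.adapter)
    mapping = map_library(trimmed, ctx.genome_index, ctx.transposon_index)
    return build_profile(library_id, trimmed, mapping, transposon_ids=ctx.transposon_ids)
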