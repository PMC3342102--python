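"""End-to-end orchestration: simulate → trim → map → profile → compare.

One :class:`RunConfig` (typically a YAML file) drives a full reproducible
run with a fixed on-disk layout under ``out_dir``::

    references/genome.fasta, references/transposons.fasta   (when simulated)
    libraries/<id>.fastq, libraries/<id>.truth.tsv          (when simulated)
    trim/<id>.report.tsv, trim/<id>.inserts.fasta
    map/<id>.hits.tsv [, map/<id>.sam]
    profile/<id>.tsv, profile/library_stats.tsv
    compare/records.tsv, compare/summary.tsv, compare/abundant.txt
    manifest.json

Re-running with the same config and inputs reproduces byte-identical TSV
outputs; the manifest records config, package version, seed, input
checksums and per-stage read tallies (and deliberately no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import io as pio
from .align import Reference, build_index, map_library
from .compare import compare_profiles
from .preprocess import trim_and_filter
from .profile import build_profile, filter_abundant
from .simulate import (
    DEFAULT_ADAPTER,
    KG_REDUCED_FACTOR,
    LibraryConfig,
    apply_preset,
    generate_references,
    simulate_library,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; ``stage`` names where the run aborted."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Every constant of the analysis, defaulted to the study's values.

    The defaults (two adapter mismatches, 23-30 nt inserts, the 500 RPM
    abundance filter, the 0.6/1.6 relative-expression bands) make the
    canonical run the zero-argument configuration; each is overridable.
    """

    out_dir: str
    baseline: str
    libraries: list[dict] = field(default_factory=list)  # {id, reads} paths
    genome_fasta: Optional[str] = None
    transposon_fasta: Optional[str] = None
    simulate: Optional[dict] = None
    adapter: str = DEFAULT_ADAPTER
    max_mismatches: int = 2
    min_overlap: int = 6
    min_len: int = 23
    max_len: int = 30
    rpm_threshold: float = 500.0
    band_lower: float = 0.6
    band_upper: float = 1.6
    seed: int = 0
    write_sam: bool = False

    def __post_init__(self) -> None:
        for name in ("max_mismatches", "min_overlap", "min_len", "max_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.rpm_threshold < 0:
            raise ValueError("rpm_threshold must be non-negative")
        if not self.band_lower < self.band_upper:
            raise ValueError("band_lower must be < band_upper")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _simulate_stage(config: RunConfig, out: Path) -> None:
    sim = dict(config.simulate or {})
    lib_specs = sim.pop("libraries", [])
    ref_dir = out / "references"
    lib_dir = out / "libraries"
    ref_dir.mkdir(parents=True, exist_ok=True)
    lib_dir.mkdir(parents=True, exist_ok=True)

    refs = generate_references(
        n_transposons=sim.get("n_transposons", 121),
        length_range=tuple(sim.get("length_range", (500, 2000))),
        genome_length=sim.get("genome_length", 400_000),
        n_transposon_copies_in_genome=sim.get("n_transposon_copies", 1),
        seed=sim.get("seed", config.seed),
    )
    pio.write_fasta([("genome", refs.genome)], ref_dir / "genome.fasta")
    pio.write_fasta(
        [(m.id, m.consensus) for m in refs.transposons], ref_dir / "transposons.fasta"
    )
    config.genome_fasta = str(ref_dir / "genome.fasta")
    config.transposon_fasta = str(ref_dir / "transposons.fasta")

    for spec in lib_specs:
        models = apply_preset(
            refs.transposons,
            spec.get("preset", "wt-ovary"),
            reduced_ids=spec.get("reduced_ids", ()),
            reduction_factor=spec.get("reduction_factor", KG_REDUCED_FACTOR),
        )
        lib_cfg = LibraryConfig(
            n_pirna_reads=spec.get("n_pirna_reads", 200_000),
            n_background_reads=spec.get("n_background_reads", 20_000),
            n_junk_reads=spec.get("n_junk_reads", 2_000),
            adapter=config.adapter,
            error_rate=spec.get("error_rate", 0.0),
            seed=spec.get("seed", config.seed),
            library_id=spec["id"],
        )
        reads, truth = simulate_library(refs, models, lib_cfg)
        fastq = lib_dir / f"{spec['id']}.fastq"
        pio.write_fastq(reads, fastq)
        pio.write_ground_truth(truth, lib_dir / f"{spec['id']}.truth.tsv")
        config.libraries.append({"id": spec["id"], "reads": str(fastq)})
        logger.info("simulated library %s: %d reads", spec["id"], len(reads))


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "status": "incomplete",
        "stages": {},
        "inputs": {},
        "outputs": [],
    }
    from . import __version__

    manifest["version"] = __version__

    def record(path: Path) -> None:
        manifest["outputs"].append(str(path.relative_to(out)))

    try:
        if config.simulate:
            _simulate_stage(config, out)

        if not config.genome_fasta or not config.transposon_fasta:
            raise PipelineError("config", "genome_fasta and transposon_fasta are required")
        if not config.libraries:
            raise PipelineError("config", "no libraries configured")
        for path in [config.genome_fasta, config.transposon_fasta] + [
            lib["reads"] for lib in config.libraries
        ]:
            if not Path(path).exists():
                raise PipelineError("config", f"missing input: {path}")
            manifest["inputs"][path] = pio.sha256_file(path)
        lib_ids = [lib["id"] for lib in config.libraries]
        if config.baseline not in lib_ids:
            raise PipelineError("config", f"baseline {config.baseline!r} not among {lib_ids}")

        genome_refs = [Reference(i, s, "genome") for i, s in pio.read_fasta(config.genome_fasta)]
        te_refs = [Reference(i, s, "transposon") for i, s in pio.read_fasta(config.transposon_fasta)]
        genome_index = build_index(genome_refs)
        te_index = build_index(te_refs)
        te_ids = [r.id for r in te_refs]

        (out / "trim").mkdir(exist_ok=True)
        (out / "map").mkdir(exist_ok=True)
        (out / "profile").mkdir(exist_ok=True)
        profiles = {}
        stats_rows = []
        for lib in config.libraries:
            lid = lib["id"]
            reads = pio.read_reads(lib["reads"])
            trimmed, tallies = trim_and_filter(
                reads,
                config.adapter,
                config.max_mismatches,
                config.min_overlap,
                config.min_len,
                config.max_len,
            )
            pio.write_trim_report(tallies, out / "trim" / f"{lid}.report.tsv")
            pio.write_inserts_fasta(trimmed, out / "trim" / f"{lid}.inserts.fasta")
            record(out / "trim" / f"{lid}.report.tsv")
            record(out / "trim" / f"{lid}.inserts.fasta")

            mapping = map_library(trimmed, genome_index, te_index)
            all_hits = [h for hits in mapping.transposon_hits.values() for h in hits]
            pio.write_hits_tsv(all_hits, out / "map" / f"{lid}.hits.tsv")
            record(out / "map" / f"{lid}.hits.tsv")
            if config.write_sam:
                inserts = {t.id: t.insert for t in trimmed}
                pio.write_sam(all_hits, te_refs, inserts, out / "map" / f"{lid}.sam")
                record(out / "map" / f"{lid}.sam")

            prof = build_profile(lid, trimmed, mapping, transposon_ids=te_ids)
            prof.table.to_csv(out / "profile" / f"{lid}.tsv", sep="\t")
            record(out / "profile" / f"{lid}.tsv")
            profiles[lid] = prof
            manifest["stages"][lid] = {
                "input_reads": len(reads),
                "tallies": tallies,
                "genome_mapped": mapping.genome_mapped_total,
                "transposon_mapped": len(mapping.transposon_hits),
            }
            stats_rows.append(
                {
                    "library_id": lid,
                    "genome_mapped_total": prof.genome_mapped_total,
                    "one_u_bias_pct": prof.one_u_bias,
                    "one_u_bias_genome_pct": prof.one_u_bias_genome,
                    "antisense_bias": prof.antisense_bias,
                }
            )

        import pandas as pd

        pd.DataFrame(stats_rows).to_csv(
            out / "profile" / "library_stats.tsv", sep="\t", index=False
        )
        record(out / "profile" / "library_stats.tsv")

        baseline_prof = profiles[config.baseline]
        sample_profs = [profiles[lid] for lid in lib_ids if lid != config.baseline]
        if sample_profs:
            (out / "compare").mkdir(exist_ok=True)
            abundant = filter_abundant(baseline_prof, config.rpm_threshold)
            (out / "compare" / "abundant.txt").write_text("\n".join(abundant) + "\n")
            record(out / "compare" / "abundant.txt")
            records, summary = compare_profiles(
                baseline_prof, sample_profs, config.band_lower, config.band_upper
            )
            records = records[records["transposon_id"].isin(abundant)]
            summary = summary[summary["transposon_id"].isin(abundant)]
            records.to_csv(out / "compare" / "records.tsv", sep="\t", index=False)
            summary.to_csv(out / "compare" / "summary.tsv", sep="\t", index=False)
            record(out / "compare" / "records.tsv")
            record(out / "compare" / "summary.tsv")
        manifest["status"] = "complete"
    finally:
        manifest["config"] = dataclasses.asdict(config)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return manifest
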