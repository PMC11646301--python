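"""Pipeline configuration and the umbrella orchestration (run_all).

``PipelineConfig`` carries every threshold of the processing chain with
its default: merge overlap 50 / 10 diffs, ±10 bp length window, expected
errors < 1, mean Q >= 30, swarm d=1 fastidious, chimera abundance skew
16, 90% minimum identity, 95% species threshold, 5000 max hits, DCA with
26 segments and rare-taxon downweighting.  Unknown keys are rejected.

``run_all`` executes reference curation -> read processing -> taxonomic
assignment -> morphotype comparison, writing a funnel log of record
counts at every stage.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import amplicon as ap
from . import compare as cmp
from . import io as sio
from . import taxassign as ta
from .refdb import PRIMER_SETS, PrimerSet, ReferenceRecord, build_amplicon_db
from .taxonomy import read_lineage_tsv


class PipelineConfig(BaseModel):
    """All thresholds of the pipeline with their default values."""

    model_config = ConfigDict(extra="forbid")

    primer_set: str = "CH"
    expected_insert_len: Optional[int] = None  # None -> primer-set default

    # reference curation / in-silico PCR
    min_ref_length: int = Field(200, ge=1)
    pcr_max_mismatch: int = Field(1, ge=0)
    pcr_length_tolerance: int = Field(10, ge=0)

    # read processing
    min_overlap: int = Field(50, ge=1)
    max_diffs: int = Field(10, ge=0)
    trim_error_rate: float = Field(0.1, ge=0.0, le=0.5)
    len_tolerance: int = Field(10, ge=0)
    max_ee: float = Field(1.0, gt=0.0)
    min_mean_q: float = Field(30.0, ge=0.0, le=93.0)
    swarm_d: int = Field(1, ge=1, le=1)  # d=1 single-linkage semantics
    fastidious: bool = True
    fastidious_boundary: int = Field(3, ge=2)
    abundance_skew: float = Field(16.0, ge=1.0)
    map_max_diffs: int = Field(1, ge=0)

    # taxonomic assignment
    min_identity: float = Field(90.0, ge=0.0, le=100.0)
    species_threshold: float = Field(95.0, ge=0.0, le=100.0)
    max_hits: int = Field(5000, ge=1)

    # comparison
    dca_segments: int = Field(26, ge=1)
    downweight_rare: bool = True

    seed: int = 0

    # paths (used by run_all)
    reference_fasta: Optional[str] = None
    lineage_tsv: Optional[str] = None
    reads_manifest: Optional[str] = None
    crosswalk_tsv: Optional[str] = None
    out_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    @property
    def primers(self) -> PrimerSet:
        try:
            return PRIMER_SETS[self.primer_set]
        except KeyError:
            raise ValueError(f"unknown primer set {self.primer_set!r}") from None

    @property
    def insert_len(self) -> int:
        return (
            self.expected_insert_len
            if self.expected_insert_len is not None
            else self.primers.expected_insert_len
        )


def process_reads(
    pairs_by_sample: dict[str, list[tuple[ap.QualityRead, ap.QualityRead]]],
    cfg: PipelineConfig,
) -> dict:
    """Run merge -> trim -> filter -> derep -> denoise -> chimera -> numt
    -> map, returning ESVs, the abundance table and the stage log."""
    primers = cfg.primers
    log = ap.StageLog()

    merged: list[ap.QualityRead] = []
    reasons: dict[str, int] = {}
    n_pairs = 0
    for sample, pairs in pairs_by_sample.items():
        for r1, r2 in pairs:
            n_pairs += 1
            read, why = ap.merge_pairs(r1, r2, cfg.min_overlap, cfg.max_diffs)
            if read is None:
                reasons[why] = reasons.get(why, 0) + 1
            else:
                merged.append(read)
    log.record("merge", n_pairs, len(merged), reasons)

    trimmed, reasons = [], {}
    for read in merged:
        out, why = ap.trim_primers(read, primers, cfg.trim_error_rate)
        if out is None:
            reasons[why] = reasons.get(why, 0) + 1
        else:
            trimmed.append(out)
    log.record("trim_primers", len(merged), len(trimmed), reasons)

    filtered, reasons = [], {}
    for read in trimmed:
        keep, why = ap.quality_filter(
            read, cfg.insert_len, cfg.len_tolerance, cfg.max_ee, cfg.min_mean_q
        )
        if keep:
            filtered.append(read)
        else:
            reasons[why] = reasons.get(why, 0) + 1
    log.record("quality_filter", len(trimmed), len(filtered), reasons)

    uniques = ap.dereplicate(filtered)
    log.record("dereplicate", len(filtered), len(uniques), {}, conserved=False)

    esvs, membership = ap.denoise_d1(
        uniques, fastidious=cfg.fastidious, boundary=cfg.fastidious_boundary
    )
    log.record("denoise", len(uniques), len(esvs), {}, conserved=False)

    esvs, chimeras = ap.detect_chimeras(esvs, cfg.abundance_skew)
    log.record("chimera_filter", len(esvs) + len(chimeras), len(esvs),
               {"chimera": len(chimeras)})

    esvs, numts, numt_reasons = ap.filter_numts(
        esvs, primers.reading_frame_offset
    )
    log.record("numt_filter", len(esvs) + len(numts), len(esvs), numt_reasons)

    abundance, unmapped = ap.map_reads(filtered, esvs, cfg.map_max_diffs)
    log.record("map_reads", len(filtered), len(filtered) - unmapped,
               {"unmapped": unmapped})
    log.check_conservation()

    return {
        "esvs": esvs,
        "abundance": abundance,
        "membership": membership,
        "chimeras": chimeras,
        "numts": numts,
        "stage_log": log,
        "filtered_reads": filtered,
    }


def run_all(cfg: PipelineConfig) -> dict:
    """Full pipeline from files named in the config.

    Expects ``reference_fasta`` + ``lineage_tsv`` (reference set), a
    ``reads_manifest`` TSV with columns sample, r1, r2, an optional
    ``crosswalk_tsv``, and an ``out_dir``.  All inputs are checked before
    any computation starts.
    """
    required = {
        "reference_fasta": cfg.reference_fasta,
        "lineage_tsv": cfg.lineage_tsv,
        "reads_manifest": cfg.reads_manifest,
        "out_dir": cfg.out_dir,
    }
    for key, value in required.items():
        if value is None:
            raise ValueError(f"config is missing {key}")
    paths = [cfg.reference_fasta, cfg.lineage_tsv, cfg.reads_manifest]
    if cfg.crosswalk_tsv is not None:
        paths.append(cfg.crosswalk_tsv)
    manifest = None
    for p in paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    manifest = sio.read_tsv(cfg.reads_manifest, dtype=str)
    for col in ("sample", "r1", "r2"):
        if col not in manifest.columns:
            raise ValueError("reads manifest needs columns sample, r1, r2")
    for row in manifest.itertuples(index=False):
        for p in (row.r1, row.r2):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # reference database
    lineages = read_lineage_tsv(cfg.lineage_tsv)
    raw_refs = [
        ReferenceRecord(seq_id, seq, lineages[seq_id])
        for seq_id, seq, _ in sio.read_fasta(cfg.reference_fasta)
        if seq_id in lineages
    ]
    refdb, ref_log = build_amplicon_db(
        raw_refs,
        cfg.primers,
        min_length=cfg.min_ref_length,
        max_mismatch=cfg.pcr_max_mismatch,
        length_tolerance=cfg.pcr_length_tolerance,
    )
    sio.write_fasta(((r.seq_id, r.sequence) for r in refdb), out_dir / "refdb.fasta")

    # reads
    pairs_by_sample: dict[str, list] = {}
    for row in manifest.itertuples(index=False):
        r1 = sio.read_fastq(row.r1, sample=row.sample)
        r2 = sio.read_fastq(row.r2, sample=row.sample)
        if len(r1) != len(r2):
            raise ValueError(f"sample {row.sample}: R1/R2 read counts differ")
        pairs_by_sample.setdefault(row.sample, []).extend(zip(r1, r2))

    result = process_reads(pairs_by_sample, cfg)
    sio.write_esv_fasta(result["esvs"], out_dir / "esvs.fasta")
    sio.write_tsv(result["abundance"], out_dir / "abundance.tsv", index=True)

    assignments = ta.assign_all(
        result["esvs"],
        refdb,
        min_identity=cfg.min_identity,
        species_threshold=cfg.species_threshold,
        max_hits=cfg.max_hits,
    )
    sio.write_tsv(ta.assignments_to_frame(assignments), out_dir / "assignments.tsv")

    comparison = None
    if cfg.crosswalk_tsv is not None:
        crosswalk = cmp.MorphotypeCrosswalk.read_tsv(cfg.crosswalk_tsv)
        taxa = cmp.taxa_from_assignments(assignments, result["abundance"])
        detections, dropped = cmp.translate(taxa, crosswalk)
        incidence = cmp.incidence_from_detections(detections)
        sio.write_tsv(incidence, out_dir / "incidence.tsv", index=True)
        comparison = {
            "detections": detections,
            "dropped": dropped,
            "incidence": incidence,
        }
        if incidence.shape[0] >= 3 and incidence.shape[1] >= 3:
            ordination = cmp.dca(
                incidence,
                downweight_rare=cfg.downweight_rare,
                segments=cfg.dca_segments,
            )
            sio.write_tsv(
                ordination.sample_scores, out_dir / "dca_samples.tsv", index=True
            )
            comparison["ordination"] = ordination

    sio.write_tsv(result["stage_log"].to_frame(), out_dir / "stage_log.tsv")
    return {
        "refdb": refdb,
        "ref_log": ref_log,
        "assignments": assignments,
        "comparison": comparison,
        **result,
    }
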