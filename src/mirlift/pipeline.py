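"""End-to-end orchestration: annotate -> compare -> quantify -> arms -> qpcr.

Two entry points:

* :func:`run_all` — the file-based pipeline behind the command line: reads a
  :class:`PipelineConfig` (YAML), runs every stage, writes stage outputs and
  a JSON report into one results directory.  Stage boundaries log input
  hashes and thresholds so every reported count is auditable.

* :func:`run_synthetic_study` — the same stages wired directly to the
  synthetic-data generator, in memory, returning all intermediate objects
  plus the planted ground truth.  This is the harness used by the test
  suite and the acceptance script.

The report mirrors the accounting shape of a small RNA-seq study: per-sample
read counts (sequenced, after filtering, mapped at 0 and 1 mismatches, with
Mean and Sum columns), expressed-miRNA counts, per-precursor arm
classification tallies, and the cross-platform Venn counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from . import arms as arms_mod
from . import conservation as cons
from . import expression as expr
from . import io as mio
from . import qpcr as qpcr_mod
from . import simulate as sim

log = logging.getLogger("mirlift")


@dataclass
class PipelineConfig:
    """Paths and thresholds of one pipeline run."""

    genome: list[str] = field(default_factory=list)
    precursors: str = ""
    matures: str = ""
    fastq: list[str] = field(default_factory=list)
    ct_table: str | None = None
    ref_matures: str | None = None
    ref_precursors: str | None = None
    ref_genome: str | None = None
    outdir: str = "results"

    prefix: str = "tfa"
    min_identity: float = 0.90
    max_mature_mm: int = 3
    min_len: int = 18
    min_mean_q: float = 20.0
    max_mm: int = 0
    min_total: int = 15
    expressed_min: int = 15
    novel_min: int = 15
    max_ct: float = 32.0
    stemloop_max_mm: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("precursors", "matures"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"config field {name!r}: missing path {p}")
        for name in ("ct_table", "ref_matures", "ref_precursors", "ref_genome"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config field {name!r}: missing path {p}")
        for name in ("genome", "fastq"):
            for p in getattr(self, name):
                if not Path(p).exists():
                    raise FileNotFoundError(f"config field {name!r}: missing path {p}")
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")
        if self.max_mm not in (0, 1):
            raise ValueError("max_mm must be 0 or 1")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def summarize_table1(
    filter_acct: dict[str, dict[str, int]],
    matrix_0mm: expr.CountMatrix,
    matrix_1mm: expr.CountMatrix | None = None,
) -> pd.DataFrame:
    """Per-sample read accounting with Mean and Sum columns.

    Rows: sequencing reads, reads after filtering, reads mapped at 0 (and,
    when available, 1) mismatches.  A zero-read sample simply contributes
    zeros.
    """
    samples = list(filter_acct)
    rows = {
        "sequencing_reads": [filter_acct[s]["input"] for s in samples],
        "reads_after_filtering": [filter_acct[s]["kept"] for s in samples],
    }

    def assigned(matrix: expr.CountMatrix) -> list[int]:
        acct = matrix.accounting.set_index("sample")["assigned"]
        return [int(acct.get(s, 0)) for s in samples]

    rows["mapped_0mm"] = assigned(matrix_0mm)
    if matrix_1mm is not None:
        rows["mapped_1mm"] = assigned(matrix_1mm)
    df = pd.DataFrame(rows, index=samples).T
    df["Mean"] = df[samples].mean(axis=1)
    df["Sum"] = df[samples].sum(axis=1)
    return df


def _suffixless_names(matures: dict[str, "ann.MatureRecord"]) -> list[str]:
    return [n for n in matures if not ann._ARM_RE.search(n)]


def _annotated_arm_totals(
    matures: dict[str, "ann.MatureRecord"], totals: pd.Series
) -> dict[str, dict[str, int]]:
    """precursor -> {arm: combined read total of its annotated mature(s)}."""
    out: dict[str, dict[str, int]] = {}
    for name, rec in matures.items():
        t = int(totals.get(name, 0))
        for parent in rec.parent_precursors:
            arm_map = out.setdefault(parent, {})
            arm_map[rec.arm] = arm_map.get(rec.arm, 0) + t
    return out


@dataclass
class StudyResult:
    """Everything one pipeline run produced, in memory."""

    annotations: dict
    mature_records: dict
    name_map: dict  # source mature name -> renamed target name
    filter_acct: dict
    matrix_0mm: expr.CountMatrix
    matrix_1mm: expr.CountMatrix
    calls: list
    expressed: set
    norm_matrix: expr.CountMatrix
    top: list
    profiles: dict
    suffixless_arms: dict
    conservation_calls: list | None
    matches: dict | None
    venn: qpcr_mod.VennPartition | None
    report: dict


def _run_stages(
    precursors: dict[str, str],
    matures: dict[str, str],
    genomes: list,
    reads_by_sample: dict[str, list],
    ct_table: pd.DataFrame | None,
    cfg: PipelineConfig,
    ref_matures: dict[str, str] | None = None,
    ref_precursors: dict[str, str] | None = None,
    ref_genome=None,
) -> StudyResult:
    thresholds = ann.Thresholds(cfg.min_identity, cfg.max_mature_mm)

    # --- annotate -----------------------------------------------------------
    annotations = ann.annotate_catalog(precursors, genomes, thresholds)
    mature_records = ann.annotate_matures(matures, annotations, cfg.max_mature_mm)
    records_before = dict(mature_records)  # rename mutates records in place
    annotations, mature_records = ann.rename_catalog(
        annotations, mature_records, cfg.prefix
    )
    name_map = {old: rec.name for old, rec in records_before.items()}
    n_accepted = sum(
        1 for a in annotations.values() if a.status == ann.STATUS_ACCEPTED
    )
    log.info("annotate: %d/%d precursors accepted, %d matures placed",
             n_accepted, len(precursors), len(mature_records))

    accepted_prec_seqs = {
        a.name: a.sequence
        for a in annotations.values()
        if a.status == ann.STATUS_ACCEPTED
    }
    mature_seqs = {rec.name: rec.sequence for rec in mature_records.values()}

    # --- conservation -------------------------------------------------------
    conservation_calls = None
    if ref_matures:
        precursor_of = {
            rec.name: accepted_prec_seqs.get(rec.parent_precursors[0], "")
            for rec in mature_records.values()
            if rec.parent_precursors
        }
        conservation_calls = cons.classify_cohort(
            mature_seqs,
            ref_matures,
            ref_precursors,
            ref_genome,
            precursor_of,
            cfg.min_identity,
            cfg.stemloop_max_mm,
        )

    # --- quantify -----------------------------------------------------------
    params = expr.ReadFilterParams(cfg.min_len, cfg.min_mean_q)
    filter_acct: dict[str, dict[str, int]] = {}
    kept_by_sample: dict[str, list] = {}
    for sample, reads in reads_by_sample.items():
        kept, acct = expr.filter_reads(reads, params)
        filter_acct[sample] = acct
        kept_by_sample[sample] = kept
    matrix_0mm = expr.map_reads(kept_by_sample, mature_seqs, max_mm=0)
    matrix_1mm = expr.map_reads(kept_by_sample, mature_seqs, max_mm=1)
    calls = expr.call_expressed(matrix_0mm, cfg.min_total)
    expressed = expr.expressed_set(calls)
    calls_1mm = expr.call_expressed(matrix_1mm, cfg.min_total)
    norm_matrix = expr.tmm_normalize(matrix_0mm)
    top = expr.top_k(norm_matrix, 10)
    log.info("quantify: %d expressed at 0 mm, %d at 1 mm",
             len(expressed), len(expr.expressed_set(calls_1mm)))

    # --- arms ---------------------------------------------------------------
    all_kept = [r for reads in kept_by_sample.values() for r in reads]
    totals = matrix_0mm.row_totals()
    arm_totals_map = _annotated_arm_totals(mature_records, totals)
    profiles = arms_mod.profile_precursors(
        all_kept,
        accepted_prec_seqs,
        arm_totals_map,
        expressed_min=cfg.expressed_min,
        novel_min=cfg.novel_min,
        max_mm=0,
    )
    suffixless = {
        n: mature_seqs[n] for n in _suffixless_names(mature_records)
    }
    suffixless_arms = arms_mod.resolve_suffixless(
        suffixless,
        {n: mature_records[n].parent_precursors for n in suffixless},
        accepted_prec_seqs,
        profiles,
    )

    # --- qpcr ---------------------------------------------------------------
    matches = None
    venn_partition = None
    if ct_table is not None:
        assay_seqs = dict(zip(ct_table.assay_id, ct_table.target_sequence))
        matches = qpcr_mod.match_assays(assay_seqs, mature_seqs, max_mm=1)
        detected_assays = qpcr_mod.call_detected(ct_table, cfg.max_ct)
        qpcr_set = qpcr_mod.detected_matures(detected_assays, matches)
        tested = qpcr_mod.tested_matures(matches)
        venn_partition = qpcr_mod.venn(set(mature_seqs), expressed, tested, qpcr_set)
        log.info("qpcr: %d tested, %d detected, %d on both platforms",
                 len(tested), len(qpcr_set), len(venn_partition.both))

    # --- report -------------------------------------------------------------
    table1 = summarize_table1(filter_acct, matrix_0mm, matrix_1mm)
    class_counts: dict[str, int] = {}
    for prof in profiles.values():
        class_counts[prof.classification] = class_counts.get(prof.classification, 0) + 1
    novel_seqs = {
        f"{p.precursor}-novel-{p.classification[-2:]}": p.novel_consensus_seq
        for p in profiles.values()
        if p.novel_consensus_seq
    }
    status_counts: dict[str, int] = {}
    for a in annotations.values():
        status_counts[a.status] = status_counts.get(a.status, 0) + 1
    report = {
        "annotation": {
            "n_precursors_in": len(precursors),
            "status_counts": status_counts,
            "n_matures_in": len(matures),
            "n_matures_placed": len(mature_records),
        },
        "table1": {
            row: {c: float(v) for c, v in table1.loc[row].items()}
            for row in table1.index
        },
        "expression": {
            "expressed_0mm": len(expressed),
            "expressed_1mm": len(expr.expressed_set(calls_1mm)),
            "norm_factors": {
                s: float(f) for s, f in norm_matrix.norm_factors.items()
            },
            "top10": top,
        },
        "arms": {
            "classification_counts": class_counts,
            "n_novel": len(novel_seqs),
            "suffixless": {
                arm: sum(1 for a in suffixless_arms.values() if a.arm == arm)
                for arm in ("5p", "3p", "unknown")
            },
        },
    }
    if conservation_calls is not None:
        report["conservation"] = cons.tier_counts(conservation_calls)
    if venn_partition is not None:
        report["qpcr"] = venn_partition.counts()

    return StudyResult(
        annotations=annotations,
        mature_records=mature_records,
        name_map=name_map,
        filter_acct=filter_acct,
        matrix_0mm=matrix_0mm,
        matrix_1mm=matrix_1mm,
        calls=calls,
        expressed=expressed,
        norm_matrix=norm_matrix,
        top=top,
        profiles=profiles,
        suffixless_arms=suffixless_arms,
        conservation_calls=conservation_calls,
        matches=matches,
        venn=venn_partition,
        report=report,
    )


def run_synthetic_study(
    sim_cfg: sim.SimConfig, pipe_cfg: PipelineConfig | None = None
) -> tuple[StudyResult, sim.SourceCatalog, sim.GroundTruth]:
    """Generate a synthetic study and run the full pipeline on it."""
    cfg = pipe_cfg or PipelineConfig(seed=sim_cfg.seed)
    catalog = sim.make_source_catalog(sim_cfg)
    genome, gt = sim.plant_genome(catalog, sim_cfg)
    reads = sim.simulate_reads(catalog, gt, sim_cfg)
    ct = sim.simulate_ct(gt, sim_cfg)
    result = _run_stages(
        catalog.precursors, catalog.matures, [genome], reads, ct, cfg
    )
    return result, catalog, gt


def run_all(cfg: PipelineConfig) -> dict:
    """Run the file-based pipeline and write all outputs under ``cfg.outdir``."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("precursors", "matures"):
        log.info("input %s: %s (sha256 %s)", name, getattr(cfg, name),
                 _sha256(getattr(cfg, name)))
    precursors = mio.read_fasta(cfg.precursors)
    matures = mio.read_fasta(cfg.matures)
    genomes = [
        ann.EncodedGenome(mio.read_fasta(p), label=Path(p).stem) for p in cfg.genome
    ]
    reads_by_sample = {
        Path(p).stem: list(mio.iter_fastq(p)) for p in cfg.fastq
    }
    ct = pd.read_csv(cfg.ct_table, sep="\t") if cfg.ct_table else None
    ref_matures = mio.read_fasta(cfg.ref_matures) if cfg.ref_matures else None
    ref_precursors = (
        mio.read_fasta(cfg.ref_precursors) if cfg.ref_precursors else None
    )
    ref_genome = mio.read_fasta(cfg.ref_genome) if cfg.ref_genome else None

    result = _run_stages(
        precursors, matures, genomes, reads_by_sample, ct,
        cfg, ref_matures, ref_precursors, ref_genome,
    )

    # stage outputs, fixed names
    accepted = [
        dict(name=a.name, chrom=a.chrom, start=a.start, end=a.end,
             strand=a.strand, score=a.mismatches,
             attributes={"source_name": a.source_name, "mismatches": a.mismatches})
        for a in result.annotations.values()
        if a.status == ann.STATUS_ACCEPTED
    ]
    mio.write_gff3(accepted, outdir / "stemloops.gff3")
    mio.write_bed(accepted, outdir / "stemloops.bed")
    mio.write_fasta(
        {a.name: a.sequence for a in result.annotations.values()
         if a.status == ann.STATUS_ACCEPTED},
        outdir / "precursors.fa",
    )
    mio.write_fasta(
        {r.name: r.sequence for r in result.mature_records.values()},
        outdir / "matures.fa",
    )
    ann.status_report(result.annotations).to_csv(
        outdir / "stemloop_status.tsv", sep="\t", index=False
    )
    result.matrix_0mm.counts.to_csv(outdir / "counts_raw.tsv", sep="\t")
    result.norm_matrix.norm.round(4).to_csv(outdir / "counts_cpm_tmm.tsv", sep="\t")
    pd.DataFrame(
        [dict(name=c.name, total=c.total, expressed=c.expressed) for c in result.calls]
    ).to_csv(outdir / "expression_calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            dict(precursor=p.precursor, reads_5p=p.reads_5p, reads_3p=p.reads_3p,
                 loop_spanning=p.loop_spanning,
                 annotated_arms="/".join(sorted(p.annotated_arms)),
                 classification=p.classification,
                 novel_consensus=p.novel_consensus_seq or "")
            for p in result.profiles.values()
        ]
    ).to_csv(outdir / "arm_profiles.tsv", sep="\t", index=False)
    novel = {
        f"{p.precursor}-novel": p.novel_consensus_seq
        for p in result.profiles.values()
        if p.novel_consensus_seq
    }
    if novel:
        mio.write_fasta(novel, outdir / "novel_matures.fa")
    if result.conservation_calls is not None:
        pd.DataFrame(
            [dict(mature=c.mature_name, tier=c.tier, detail=c.detail,
                  counterpart=c.counterpart or "")
             for c in result.conservation_calls]
        ).to_csv(outdir / "conservation.tsv", sep="\t", index=False)
    if result.venn is not None:
        with open(outdir / "venn_counts.json", "w") as fh:
            json.dump(result.venn.counts(), fh, indent=2, sort_keys=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
    return result.report
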