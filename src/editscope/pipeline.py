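"""End-to-end orchestration: simulate -> call editing per condition ->
differential editing -> Nm scoring, with plain-file handoff between stages
so each stage is independently testable and CLI-invocable.

Determinism contract: identical config + seed produce byte-identical
outputs. One global seed fans out to fixed per-stage offsets inside the
simulator; the run report echoes the config and seed so any run can be
reproduced from its report alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from . import __version__
from . import differential_editing as de
from . import editing_caller as ec
from . import nm_quant as nm
from . import synthetic_data as sd
from . import seq_io

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run; sim holds the generator block."""

    outdir: str = "editscope_run"
    seed: int = 0
    min_phred: int = 30
    min_depth: int = 10
    min_alt: int = 2
    q_threshold: float = 0.05
    fc: float = 2.0
    nm_window: int = 5
    nm_eps: float = 0.5
    paired: bool = True
    sim: sd.SimConfig = field(default_factory=sd.SimConfig)

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = sd.SimConfig(**self.sim)
        # the run seed governs every random draw
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> Dict:
    """Execute the full pipeline, writing stage outputs and a run report.

    Returns the report dict (also written to <outdir>/report.json). Counts
    along the candidate -> masked -> classified chain are monotone
    non-increasing by construction.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: Dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    try:
        _stage_simulate(config, outdir, report)
        comparison = _stage_editing(config, outdir, report)
        _stage_differential(config, outdir, comparison, report)
        _stage_nm(config, outdir, report)
    except Exception as exc:
        stage = getattr(exc, "stage", "unknown")
        (outdir / ".partial").write_text(f"failed at stage {stage}: {exc}\n")
        raise
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _stage_simulate(config: RunConfig, outdir: Path, report: Dict) -> None:
    try:
        cfg = config.sim
        reference = sd.simulate_reference(cfg)
        editing, mask, snps, nm_sites = sd.plant_truth(reference, cfg)
        seq_io.write_fasta(reference, outdir / "ref.fa")
        seq_io.write_features(reference.features, outdir / "features.bed")
        seq_io.write_snp_vcf(mask, reference, outdir / "snps.vcf")
        sd.write_truth_tables(outdir, editing, snps, nm_sites)
        n_reads = {}
        for label, shift, offset in (("a", 0.0, 0), ("b", cfg.editing_rate_shift, 1)):
            reads = sd.simulate_rnaseq(
                reference, editing, snps, cfg, rate_shift=shift, seed_offset=offset
            )
            seq_io.write_sam(reads, reference, outdir / f"cond_{label}.sam")
            sd.write_fastq(reads, outdir / f"cond_{label}.fastq")
            n_reads[label] = len(reads)
        for mode in ("high", "low"):
            rt_reads = sd.simulate_rtstop(reference, nm_sites, mode, cfg)
            seq_io.write_sam(rt_reads, reference, outdir / f"rtstop_{mode}.sam")
            n_reads[f"rt_{mode}"] = len(rt_reads)
        report["stages"]["simulate"] = {
            "n_editing_truth": len(editing),
            "n_snps": len(snps),
            "n_nm_truth": len(nm_sites),
            "reads": n_reads,
        }
    except Exception as exc:
        raise StageError("simulate", exc) from exc


def call_editing_file(
    aln_path: str | Path,
    reference: seq_io.Reference,
    mask: seq_io.SNPMask,
    min_phred: int,
    min_depth: int,
    min_alt: int,
    drop_duplicates: bool = False,
):
    """Shared call chain: pileup -> mismatches -> SNP mask -> A-to-I class.

    Returns (sites, stage_counts)."""
    reads = seq_io.read_alignments(aln_path, drop_duplicates=drop_duplicates)
    columns = list(
        seq_io.pileup(reads, reference, min_phred=min_phred)
    )
    candidates = ec.collect_mismatches(
        columns, reference, min_alt=min_alt, min_depth=min_depth
    )
    masked = ec.mask_snps(candidates, mask)
    sites = ec.classify_editing(masked, reference.features)
    counts = {
        "columns": len(columns),
        "candidates": len(candidates),
        "after_snp_mask": len(masked),
        "editing_sites": len(sites),
    }
    return sites, counts


def _stage_editing(config: RunConfig, outdir: Path, report: Dict):
    try:
        reference = seq_io.read_fasta(outdir / "ref.fa")
        reference.features = seq_io.read_features(outdir / "features.bed")
        mask = seq_io.read_snp_mask(outdir / "snps.vcf")
        frames = {}
        for label in ("a", "b"):
            sites, counts = call_editing_file(
                outdir / f"cond_{label}.sam",
                reference,
                mask,
                config.min_phred,
                config.min_depth,
                config.min_alt,
            )
            ec.write_sites(sites, outdir / f"sites_{label}.tsv")
            frames[label] = ec.sites_to_frame(sites)
            report["stages"][f"call_editing_{label}"] = counts
        comparison = de.compare_sites(
            frames["a"], frames["b"], min_depth=config.min_depth
        )
        return comparison
    except Exception as exc:
        raise StageError("call_editing", exc) from exc


def _stage_differential(
    config: RunConfig, outdir: Path, comparison, report: Dict
) -> None:
    try:
        comparison.to_csv(outdir / "comparison.tsv", sep="\t", index=False)
        shift = de.global_shift_from_comparison(comparison, paired=config.paired)
        genes = de.gene_variation(comparison, q_threshold=config.q_threshold)
        genes.to_csv(outdir / "variable_genes.tsv", sep="\t", index=False)
        shift_payload = dataclasses.asdict(shift)
        with open(outdir / "shift.json", "w") as fh:
            json.dump(shift_payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        report["stages"]["differential"] = {
            "tested_sites": int(len(comparison)),
            "flagged_genes": int(len(genes)),
            "global_shift": shift_payload,
        }
    except Exception as exc:
        raise StageError("differential", exc) from exc


def _stage_nm(config: RunConfig, outdir: Path, report: Dict) -> None:
    try:
        reference = seq_io.read_fasta(outdir / "ref.fa")
        windows = nm.score_windows(
            seq_io.read_alignments(outdir / "rtstop_low.sam"),
            seq_io.read_alignments(outdir / "rtstop_high.sam"),
            reference,
            width=config.nm_window,
            eps=config.nm_eps,
        )
        nm.windows_to_frame(windows).to_csv(
            outdir / "nm_windows.tsv", sep="\t", index=False
        )
        report["stages"]["nm_score"] = {
            "n_windows": len(windows),
            "top_score": windows[0].score if windows else None,
        }
    except Exception as exc:
        raise StageError("nm_score", exc) from exc
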