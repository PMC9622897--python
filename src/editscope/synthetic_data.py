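"""Synthetic sequencing data with planted ground truth.

Generates a toy multi-transcript reference, germline SNP confounders,
editing-bearing RNA-seq libraries, and paired high/low-dNTP RT-stop
libraries, standing in for raw sequencing from an A-to-I editing /
2'-O-methylation study. Every output is deterministic under the config
seed; truth tables are written as TSV alongside each dataset and are the
only ground truth tests consume.

Model sketch:

* Editing: at a planted site inside a feature, each covering read carries
  the edited allele (genomic G on + features, genomic C on - features)
  independently with the site's true rate - binomial read sampling.
* SNPs: a fixed alternative-allele fraction of 0.5 (het) or 1.0 (hom) per
  site, mimicking germline genotypes as distinct from the typically
  intermediate editing rates.
* Qualities: a two-component Phred model (high ~Q37, low ~Q20) so that a
  Phred < 30 base filter is actually exercised.
* RT stops: reverse transcription walks 3'->5' from a random priming
  position; at a 2'-O-methylated residue the walk terminates with
  probability 1 - stop_through_rate(mode), and every terminated molecule
  yields a read whose 5' reference start is 1 nt downstream of the stop.
  Background stops occur at a low per-nucleotide rate in both modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .seq_io import AlignedRead, Feature, Reference, SNPMask

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class TruthEditingSite:
    contig: str
    pos: int  # 0-based; genomic A on + features, genomic T on - features
    strand: str
    gene_id: str
    true_rate: float


@dataclass(frozen=True)
class TruthSNP:
    contig: str
    pos: int
    ref_base: str
    alt_base: str
    allele_fraction: float  # 0.5 het or 1.0 hom


@dataclass(frozen=True)
class TruthNmSite:
    contig: str
    pos: int
    stop_through_rate_low: float
    stop_through_rate_high: float

    def __post_init__(self) -> None:
        if not 0 <= self.stop_through_rate_low < self.stop_through_rate_high <= 1:
            raise ValueError("require 0 <= stop_through_low < stop_through_high <= 1")

    def stop_through(self, mode: str) -> float:
        if mode == "low":
            return self.stop_through_rate_low
        if mode == "high":
            return self.stop_through_rate_high
        raise ValueError(f"mode must be 'high' or 'low', got {mode!r}")


@dataclass
class SimConfig:
    """All knobs of the simulator; the defaults are the demo study
    conditions used throughout the tests.

    Depth/read-length give ~depth-fold coverage of each contig. The
    quality model draws Phred ~37+-3 for most bases and ~20+-3 for a
    low_quality_fraction of them, so roughly that fraction of bases fall
    below the Q30 filter.
    """

    n_contigs: int = 2
    contig_length: int = 5000
    n_features: int = 8
    n_editing_sites: int = 60
    rate_alpha: float = 2.0
    rate_beta: float = 5.0
    n_snps: int = 30
    depth: int = 200
    read_length: int = 100
    sequencing_error_rate: float = 0.002
    mean_phred_high: int = 37
    mean_phred_low: int = 20
    low_quality_fraction: float = 0.15
    phred_jitter: int = 3
    editing_rate_shift: float = 0.1  # global decrease applied in condition B
    # RT-stop (2'-O-methylation) block
    n_nm_sites: int = 2
    nm_stop_through_low: float = 0.2
    nm_stop_through_high: float = 0.98
    rt_background_stop: float = 0.002
    n_rt_molecules: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_contigs",
            "contig_length",
            "n_features",
            "read_length",
            "n_rt_molecules",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "sequencing_error_rate",
            "low_quality_fraction",
            "nm_stop_through_low",
            "nm_stop_through_high",
            "rt_background_stop",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rate_alpha <= 0 or self.rate_beta <= 0:
            raise ValueError("Beta parameters must be positive")


class ConfigError(ValueError):
    """The requested simulation cannot be constructed."""


# ---------------------------------------------------------------------------
# Reference and truth
# ---------------------------------------------------------------------------

def simulate_reference(cfg: SimConfig) -> Reference:
    """Uniform-random contigs with non-overlapping strand-labelled features.

    Features are laid out on a regular grid per contig (deterministic for a
    fixed seed); strands alternate with random assignment.
    """
    rng = np.random.default_rng(cfg.seed)
    contigs: Dict[str, str] = {}
    for i in range(cfg.n_contigs):
        seq = "".join(np.array(list(BASES))[rng.integers(0, 4, cfg.contig_length)])
        contigs[f"contig{i + 1}"] = seq

    per_contig = -(-cfg.n_features // cfg.n_contigs)  # ceil
    slot = cfg.contig_length // per_contig
    feat_len = max(cfg.read_length, int(slot * 0.8))
    if feat_len + 1 > slot:
        raise ConfigError(
            f"cannot place {per_contig} non-overlapping features of length "
            f"{feat_len} on a {cfg.contig_length} bp contig"
        )
    features: List[Feature] = []
    gene_no = 0
    for name in contigs:
        for j in range(per_contig):
            if gene_no >= cfg.n_features:
                break
            start = j * slot
            strand = "+" if rng.random() < 0.5 else "-"
            gene_no += 1
            features.append(
                Feature(name, start, start + feat_len, strand, f"gene{gene_no}")
            )
    return Reference(contigs=contigs, features=features)


def plant_truth(
    reference: Reference, cfg: SimConfig
) -> Tuple[List[TruthEditingSite], SNPMask, List[TruthSNP], List[TruthNmSite]]:
    """Plant editing sites, SNP confounders and Nm sites.

    Editing sites sit only at feature-strand adenosines (genomic A on +,
    genomic T on - features), with true rates drawn Beta(alpha, beta).
    SNP positions are disjoint from editing sites by construction. Nm
    sites go on the first contig, away from its edges.
    """
    if not reference.features:
        raise ConfigError("reference has no features to plant editing sites in")
    rng = np.random.default_rng(cfg.seed + 1)

    eligible: List[Tuple[str, int, str, str]] = []
    for f in reference.features:
        target = "A" if f.strand == "+" else "T"
        seq = reference.contigs[f.contig]
        for pos in range(f.start, f.end):
            if seq[pos] == target:
                eligible.append((f.contig, pos, f.strand, f.gene_id))
    if len(eligible) < cfg.n_editing_sites:
        raise ConfigError(
            f"only {len(eligible)} eligible adenosines for "
            f"{cfg.n_editing_sites} editing sites"
        )
    picks = rng.choice(len(eligible), size=cfg.n_editing_sites, replace=False)
    rates = rng.beta(cfg.rate_alpha, cfg.rate_beta, size=cfg.n_editing_sites)
    editing = [
        TruthEditingSite(*eligible[k], true_rate=float(r))
        for k, r in zip(sorted(picks), rates)
    ]
    taken = {(s.contig, s.pos) for s in editing}

    all_positions = [
        (name, pos)
        for name, seq in reference.contigs.items()
        for pos in range(len(seq))
        if (name, pos) not in taken
    ]
    if len(all_positions) < cfg.n_snps:
        raise ConfigError("not enough positions for the requested SNP count")
    snp_picks = rng.choice(len(all_positions), size=cfg.n_snps, replace=False)
    snps: List[TruthSNP] = []
    for k in sorted(snp_picks):
        contig, pos = all_positions[k]
        ref_base = reference.contigs[contig][pos]
        alt_base = rng.choice([b for b in BASES if b != ref_base])
        fraction = 0.5 if rng.random() < 0.5 else 1.0
        snps.append(TruthSNP(contig, pos, ref_base, str(alt_base), fraction))
    mask = SNPMask({(s.contig, s.pos) for s in snps})

    first_contig = next(iter(reference.contigs))
    length = len(reference.contigs[first_contig])
    margin = length // 5
    nm_positions = rng.choice(
        np.arange(margin, length - margin), size=cfg.n_nm_sites, replace=False
    )
    nm_sites = [
        TruthNmSite(
            first_contig,
            int(p),
            cfg.nm_stop_through_low,
            cfg.nm_stop_through_high,
        )
        for p in sorted(nm_positions)
    ]
    return editing, mask, snps, nm_sites


# ---------------------------------------------------------------------------
# RNA-seq simulation
# ---------------------------------------------------------------------------

def _draw_quals(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    low = rng.random(n) < cfg.low_quality_fraction
    mean = np.where(low, cfg.mean_phred_low, cfg.mean_phred_high)
    jitter = rng.integers(-cfg.phred_jitter, cfg.phred_jitter + 1, n)
    return np.clip(mean + jitter, 2, 41)


def simulate_rnaseq(
    reference: Reference,
    editing: List[TruthEditingSite],
    snps: List[TruthSNP],
    cfg: SimConfig,
    rate_shift: float = 0.0,
    seed_offset: int = 0,
) -> List[AlignedRead]:
    """Emit pre-aligned unstranded reads (cigar all-M) at ~cfg.depth.

    rate_shift is subtracted from every true editing rate (clipped at 0),
    modelling a global editing decrease in a knockdown condition.
    """
    rng = np.random.default_rng(cfg.seed + 10 + seed_offset)
    site_by_pos = {
        (s.contig, s.pos): max(0.0, min(1.0, s.true_rate - rate_shift))
        for s in editing
    }
    edited_base = {
        (s.contig, s.pos): "G" if s.strand == "+" else "C" for s in editing
    }
    snp_by_pos = {(s.contig, s.pos): s for s in snps}

    reads: List[AlignedRead] = []
    serial = 0
    for contig, seq in reference.contigs.items():
        length = len(seq)
        n_reads = int(round(cfg.depth * length / cfg.read_length))
        if n_reads == 0:
            import warnings

            warnings.warn(f"depth produces no reads on {contig}", stacklevel=2)
            continue
        starts = np.sort(rng.integers(0, length - cfg.read_length + 1, n_reads))
        variant_positions = np.array(
            sorted(
                pos
                for (c, pos) in list(site_by_pos) + list(snp_by_pos)
                if c == contig
            ),
            dtype=np.int64,
        )
        for start in starts:
            serial += 1
            bases = list(seq[start : start + cfg.read_length])
            lo = np.searchsorted(variant_positions, start, side="left")
            hi = np.searchsorted(variant_positions, start + cfg.read_length, side="left")
            for pos in variant_positions[lo:hi]:
                pos = int(pos)
                key = (contig, pos)
                if key in site_by_pos and rng.random() < site_by_pos[key]:
                    bases[pos - start] = edited_base[key]
                elif key in snp_by_pos and rng.random() < snp_by_pos[key].allele_fraction:
                    bases[pos - start] = snp_by_pos[key].alt_base
            if cfg.sequencing_error_rate > 0:
                err = np.nonzero(rng.random(cfg.read_length) < cfg.sequencing_error_rate)[0]
                for i in err:
                    bases[i] = rng.choice([b for b in BASES if b != bases[i]])
            quals = _draw_quals(rng, cfg.read_length, cfg)
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(
                AlignedRead(
                    contig=contig,
                    start=int(start),
                    strand=strand,
                    seq="".join(bases),
                    quals=tuple(int(q) for q in quals),
                    cigar=(("M", cfg.read_length),),
                    name=f"sim{serial}",
                )
            )
    return reads


def write_fastq(reads: List[AlignedRead], path: str | Path) -> None:
    """Write reads as FASTQ in read space (reverse-strand reads are
    reverse-complemented, qualities reversed)."""
    with open(path, "w") as fh:
        for read in reads:
            seq, quals = read.seq, read.quals
            if read.strand == "-":
                seq = seq.translate(_COMPLEMENT)[::-1]
                quals = quals[::-1]
            qual_str = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{read.name}\n{seq}\n+\n{qual_str}\n")


# ---------------------------------------------------------------------------
# RT-stop simulation
# ---------------------------------------------------------------------------

def simulate_rtstop(
    reference: Reference,
    nm_truth: List[TruthNmSite],
    mode: str,
    cfg: SimConfig,
    seed_offset: int = 0,
) -> List[AlignedRead]:
    """Simulate one dNTP-mode RT-stop library on the first contig.

    Each molecule primes at a uniform random 3' position and is reverse
    transcribed towards the 5' end. Background stops occur per nucleotide
    at cfg.rt_background_stop; at an Nm site the walk instead terminates
    with probability 1 - stop_through_rate(mode). A molecule stopped at
    position s yields a read starting at s+1; run-off molecules yield a
    read starting at 0.
    """
    if mode not in {"high", "low"}:
        raise ValueError(f"mode must be 'high' or 'low', got {mode!r}")
    rng = np.random.default_rng(cfg.seed + 20 + seed_offset + (0 if mode == "high" else 1))
    contig = next(iter(reference.contigs))
    seq = reference.contigs[contig]
    length = len(seq)
    nm_sites = sorted(
        (s for s in nm_truth if s.contig == contig), key=lambda s: -s.pos
    )
    b = cfg.rt_background_stop

    reads: List[AlignedRead] = []
    p3_positions = rng.integers(0, length, cfg.n_rt_molecules)
    for serial, p3 in enumerate(p3_positions, start=1):
        stop: Optional[int] = None
        cur = int(p3)  # next position the RT will traverse
        for site in nm_sites:
            if site.pos > cur:
                continue
            gap = cur - site.pos  # background-only positions before the Nm site
            if b > 0 and gap > 0:
                g = rng.geometric(b)
                if g <= gap:
                    stop = cur - g + 1
                    break
            if rng.random() < 1.0 - site.stop_through(mode):
                stop = site.pos
                break
            cur = site.pos - 1
            if cur < 0:
                break
        if stop is None and cur >= 0 and b > 0:
            g = rng.geometric(b)
            if g <= cur + 1:
                stop = cur - g + 1
        start = 0 if stop is None else stop + 1
        end = min(int(p3) + 1, start + cfg.read_length)
        if end <= start:
            continue
        n = end - start
        reads.append(
            AlignedRead(
                contig=contig,
                start=start,
                strand="+",
                seq=seq[start:end],
                quals=tuple([37] * n),
                cigar=(("M", n),),
                name=f"rt_{mode}_{serial}",
            )
        )
    return reads


# ---------------------------------------------------------------------------
# Truth table I/O
# ---------------------------------------------------------------------------

def write_truth_tables(
    outdir: str | Path,
    editing: List[TruthEditingSite],
    snps: List[TruthSNP],
    nm_sites: List[TruthNmSite],
) -> None:
    outdir = Path(outdir)
    pd.DataFrame([asdict(s) for s in editing]).to_csv(
        outdir / "truth_editing.tsv", sep="\t", index=False
    )
    pd.DataFrame([asdict(s) for s in snps]).to_csv(
        outdir / "truth_snps.tsv", sep="\t", index=False
    )
    pd.DataFrame([asdict(s) for s in nm_sites]).to_csv(
        outdir / "truth_nm.tsv", sep="\t", index=False
    )


def read_truth_editing(path: str | Path) -> List[TruthEditingSite]:
    df = pd.read_csv(path, sep="\t")
    return [TruthEditingSite(**row) for row in df.to_dict("records")]


def read_truth_nm(path: str | Path) -> List[TruthNmSite]:
    df = pd.read_csv(path, sep="\t")
    return [TruthNmSite(**row) for row in df.to_dict("records")]
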