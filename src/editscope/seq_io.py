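"""Readers/writers for the standard formats the pipeline touches, plus the
quality-filtered pileup engine every downstream caller consumes.

Coordinate convention: everything in memory is 0-based, half-open.
Conversion to/from 1-based happens only at file boundaries (VCF, display
columns of output TSVs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Sequence, Set, Tuple

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# ASCII base encoding used by the vectorised pileup: byte value -> 0..3, or -1.
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True)
class Feature:
    """Strand-annotated interval used for gene assignment of editing sites."""

    contig: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.gene_id}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature {self.gene_id}: strand must be + or -")


@dataclass
class Reference:
    """Contig sequences plus optional strand-annotated features.

    Sequences are uppercase A/C/G/T/N strings; contig names are unique by
    dict construction; every feature interval must lie within its contig.
    """

    contigs: Dict[str, str]
    features: List[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"contig {name}: non-nucleotide characters {sorted(bad)}")
        for f in self.features:
            if f.contig not in self.contigs:
                raise ValueError(f"feature {f.gene_id}: unknown contig {f.contig}")
            if f.end > len(self.contigs[f.contig]):
                raise ValueError(f"feature {f.gene_id}: interval exceeds contig length")

    def __contains__(self, name: str) -> bool:
        return name in self.contigs


@dataclass(frozen=True)
class AlignedRead:
    """A placed read: leftmost 0-based reference position, forward-strand
    sequence, per-base Phred qualities and a cigar over {M, I, D, S}."""

    contig: str
    start: int
    strand: str
    seq: str
    quals: Tuple[int, ...]
    cigar: Tuple[Tuple[str, int], ...]
    name: str = "read"
    flag: int = 0

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(f"{self.name}: sequence and quality lengths differ")
        if any(q < 0 or q > 93 for q in self.quals):
            raise ValueError(f"{self.name}: Phred values must lie in [0, 93]")

    @property
    def reference_span(self) -> int:
        """Number of reference bases consumed (M and D operations)."""
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & 0x400)


@dataclass(frozen=True)
class PileupColumn:
    """Quality-filtered base counts at one reference position."""

    contig: str
    pos: int
    counts: Dict[str, int]
    depth: int

    def __post_init__(self) -> None:
        if self.depth != sum(self.counts.values()):
            raise ValueError("pileup depth must equal the sum of base counts")


class SNPMask:
    """Set of (contig, 0-based position) pairs to exclude from editing calls,
    standing in for a dbSNP catalogue of known germline variants."""

    def __init__(self, positions: Iterable[Tuple[str, int]] = ()) -> None:
        self.positions: Set[Tuple[str, int]] = set(positions)
        for contig, pos in self.positions:
            if pos < 0:
                raise FormatError(f"negative coordinate {pos} on {contig}")

    def __contains__(self, key: Tuple[str, int]) -> bool:
        return key in self.positions

    def __len__(self) -> int:
        return len(self.positions)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SNPMask) and self.positions == other.positions


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Reference:
    """Read a FASTA file into a Reference (sequences only, uppercased).

    Raises FormatError naming the offending line for malformed headers or
    non-nucleotide characters.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    contigs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        contigs[rec.id] = str(rec.seq).upper()
    return Reference(contigs=contigs)


def _validate_fasta_lines(path: Path) -> None:
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                seen_header = True
            else:
                if not seen_header:
                    raise FormatError(f"{path}:{lineno}: sequence before any header")
                bad = set(line.upper()) - VALID_BASES
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: non-nucleotide characters {sorted(bad)}"
                    )


def write_fasta(reference: Reference, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in reference.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED features
# ---------------------------------------------------------------------------

def read_features(path: str | Path) -> List[Feature]:
    """Read strand-annotated features from BED6 (name column = gene id)."""
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 requires 6 columns")
            contig, start, end, name, _score, strand = parts[:6]
            try:
                features.append(Feature(contig, int(start), int(end), strand, name))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return features


def write_features(features: Sequence[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{f.gene_id}\t0\t{f.strand}\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_SKIP_FLAGS = 0x4 | 0x100 | 0x800  # unmapped, secondary, supplementary


def read_alignments(
    path: str | Path, drop_duplicates: bool = False
) -> Iterator[AlignedRead]:
    """Stream mapped primary alignments from SAM (or BAM) as AlignedRead.

    Unmapped, secondary and supplementary records are skipped. Base
    qualities come from pysam already decoded from ASCII offset 33.
    Duplicate-flagged reads (0x400) are kept unless drop_duplicates is set.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        for rec in sam:
            if rec.flag & _SKIP_FLAGS:
                continue
            if drop_duplicates and rec.flag & 0x400:
                continue
            if rec.reference_id < 0 or rec.reference_name is None:
                raise FormatError(f"read {rec.query_name}: unknown reference contig")
            cigar = tuple(
                ("MIDNSHP=X"[op], n) for op, n in (rec.cigartuples or ())
            )
            unsupported = {op for op, _ in cigar} - set("MIDS")
            if unsupported:
                raise FormatError(
                    f"read {rec.query_name}: unsupported cigar ops {sorted(unsupported)}"
                )
            quals = tuple(int(q) for q in (rec.query_qualities or ()))
            yield AlignedRead(
                contig=rec.reference_name,
                start=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                seq=rec.query_sequence or "",
                quals=quals,
                cigar=cigar,
                name=rec.query_name,
                flag=rec.flag,
            )


def write_sam(
    reads: Iterable[AlignedRead], reference: Reference, path: str | Path
) -> int:
    """Write reads as a plain-text SAM with a header naming all contigs.

    Returns the number of records written. Output is deterministic for a
    deterministic input stream (no @PG line, no timestamps).
    """
    names = list(reference.contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(reference.contigs[n])} for n in names],
    }
    n = 0
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.name
            rec.flag = read.flag | (0x10 if read.strand == "-" else 0)
            rec.reference_id = names.index(read.contig)
            rec.reference_start = read.start
            rec.mapping_quality = 60
            rec.cigarstring = "".join(f"{ln}{op}" for op, ln in read.cigar)
            rec.query_sequence = read.seq
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in read.quals)
            )
            out.write(rec)
            n += 1
    return n


# ---------------------------------------------------------------------------
# SNP masks (VCF / BED)
# ---------------------------------------------------------------------------

def read_snp_mask(path: str | Path) -> SNPMask:
    """Load a SNP mask from VCF (1-based POS) or BED3 (0-based half-open),
    auto-detected by file extension. All positions are stored 0-based."""
    path = Path(path)
    if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz"):
        return _read_snp_vcf(path)
    if path.suffix == ".bed":
        return _read_snp_bed(path)
    raise FormatError(f"{path}: cannot detect SNP mask format (expect .vcf or .bed)")


def _read_snp_vcf(path: Path) -> SNPMask:
    positions = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.pos < 1:
                raise FormatError(f"{path}: non-positive VCF coordinate {rec.pos}")
            positions.add((rec.chrom, rec.pos - 1))
    return SNPMask(positions)


def _read_snp_bed(path: Path) -> SNPMask:
    positions = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED3 requires 3 columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start},{end})")
            positions.update((contig, p) for p in range(start, end))
    return SNPMask(positions)


def write_snp_vcf(mask: SNPMask, reference: Reference, path: str | Path) -> None:
    """Write mask positions as a minimal VCF v4.2 (REF from the reference,
    ALT '.'), sorted by contig order then position."""
    order = {name: i for i, name in enumerate(reference.contigs)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in reference.contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for contig, pos in sorted(mask.positions, key=lambda t: (order[t[0]], t[1])):
            ref_base = reference.contigs[contig][pos]
            fh.write(f"{contig}\t{pos + 1}\t.\t{ref_base}\t.\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# Pileup engine
# ---------------------------------------------------------------------------

def pileup_arrays(
    reads: Iterable[AlignedRead],
    reference: Reference,
    min_phred: int = 30,
    drop_duplicates: bool = False,
) -> Dict[str, np.ndarray]:
    """Accumulate quality-filtered base counts per contig.

    Returns contig -> int64 array of shape (4, contig_length), rows indexed
    A,C,G,T. A base contributes only if its Phred >= min_phred; the filter
    applies to every aligned base, matching or not, so editing-rate
    denominators are built from the same filtered pool as the mismatches.
    Deletions and soft-clips contribute nothing; insertions consume query
    only. Reads overrunning their contig are skipped with a warning.
    """
    arrays: Dict[str, np.ndarray] = {
        name: np.zeros((4, len(seq)), dtype=np.int64)
        for name, seq in reference.contigs.items()
    }
    for read in reads:
        if drop_duplicates and read.is_duplicate:
            continue
        if read.contig not in arrays:
            raise FormatError(f"read {read.name}: unknown contig {read.contig}")
        arr = arrays[read.contig]
        if read.start + read.reference_span > arr.shape[1]:
            warnings.warn(
                f"read {read.name} overruns contig {read.contig}; skipped",
                stacklevel=2,
            )
            continue
        codes = _BASE_CODE[np.frombuffer(read.seq.encode(), dtype=np.uint8)]
        quals = np.asarray(read.quals, dtype=np.int32)
        rpos = read.start
        qpos = 0
        for op, n in read.cigar:
            if op == "M":
                seg_codes = codes[qpos : qpos + n]
                seg_quals = quals[qpos : qpos + n]
                keep = (seg_quals >= min_phred) & (seg_codes >= 0)
                positions = np.arange(rpos, rpos + n)[keep]
                np.add.at(arr, (seg_codes[keep], positions), 1)
                rpos += n
                qpos += n
            elif op == "D":
                rpos += n
            elif op in ("I", "S"):
                qpos += n
            else:  # pragma: no cover - filtered upstream
                raise FormatError(f"read {read.name}: unsupported cigar op {op}")
    return arrays


def pileup(
    reads: Iterable[AlignedRead],
    reference: Reference,
    min_phred: int = 30,
    drop_duplicates: bool = False,
) -> Iterator[PileupColumn]:
    """Yield one PileupColumn per covered position, in (contig, pos) order.

    Positions whose reference base is N are suppressed: a mismatch is
    undefined there.
    """
    arrays = pileup_arrays(reads, reference, min_phred, drop_duplicates)
    for contig, arr in arrays.items():
        seq = reference.contigs[contig]
        depths = arr.sum(axis=0)
        for pos in np.nonzero(depths)[0]:
            if seq[pos] == "N":
                continue
            counts = {b: int(arr[i, pos]) for b, i in BASE_INDEX.items()}
            yield PileupColumn(
                contig=contig, pos=int(pos), counts=counts, depth=int(depths[pos])
            )
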