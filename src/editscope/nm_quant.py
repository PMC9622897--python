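"""2'-O-methylation (Nm) scoring from paired high/low-dNTP RT-stop libraries.

Ribose 2'-O-methylation pauses reverse transcriptase when dNTPs are scarce,
so a low-dNTP library accumulates read 5' ends one nucleotide downstream of
each methylated residue while a high-dNTP library reads through. The
analysis counts read 5' ends (shifted by the stated 1 nt offset back to the
stop position), normalizes each library by its mapped-read count, sums the
signal in non-overlapping 5 bp windows, and contrasts low vs high dNTP
signal per window:

    score = (low + eps) / (low + high + 2 * eps),     eps = 0.5

The score is bounded in (0, 1), depth-invariant after normalization, and
monotone in any low-over-high enrichment; values near 1 indicate
methylation, values near 0.5 background.

Stop extraction assumes a single-stranded (+) template (rRNA-like); a
symmetric rule for reverse-strand reads (3'-most genomic position) is
available behind the count_reverse flag, default off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .seq_io import AlignedRead, Reference


@dataclass
class RTStopProfile:
    """Per-position RT-stop counts for one dNTP-mode library."""

    counts: Dict[str, np.ndarray]  # contig -> float vector, len == contig length
    mode: str  # {"high", "low"}
    mapped_reads: int
    normalized: bool = False

    def total(self) -> float:
        return float(sum(v.sum() for v in self.counts.values()))


@dataclass(frozen=True)
class MethWindow:
    contig: str
    start: int  # 0-based, width-sized tiling from 0
    width: int
    low_sum: float
    high_sum: float
    score: float
    partial: bool = False


def extract_rtstops(
    reads: Iterable[AlignedRead],
    reference: Reference,
    mode: str,
    count_reverse: bool = False,
) -> RTStopProfile:
    """Count RT stops from read 5' ends.

    A forward read whose 5'-most reference position is p marks the RT stop
    at p - 1; reads starting at position 0 are dropped (their stop lies off
    the contig). Reverse-strand reads are ignored unless count_reverse is
    set, in which case their 3'-most genomic position p3 marks a stop at
    p3 + 1 symmetrically. mapped_reads counts every read seen, the
    normalization denominator.
    """
    if mode not in {"high", "low"}:
        raise ValueError(f"mode must be 'high' or 'low', got {mode!r}")
    counts = {
        name: np.zeros(len(seq), dtype=float)
        for name, seq in reference.contigs.items()
    }
    mapped = 0
    for read in reads:
        mapped += 1
        vec = counts[read.contig]
        if read.strand == "+":
            if read.start == 0:
                continue
            vec[read.start - 1] += 1
        elif count_reverse:
            stop = read.start + read.reference_span
            if stop < len(vec):
                vec[stop] += 1
    return RTStopProfile(counts=counts, mode=mode, mapped_reads=mapped)


def normalize_profile(profile: RTStopProfile, scale: float = 1e6) -> RTStopProfile:
    """Scale every count by scale / mapped_reads (counts per million mapped
    reads at the default scale)."""
    if profile.mapped_reads <= 0:
        raise ValueError("cannot normalize a profile with zero mapped reads")
    factor = scale / profile.mapped_reads
    return RTStopProfile(
        counts={k: v * factor for k, v in profile.counts.items()},
        mode=profile.mode,
        mapped_reads=profile.mapped_reads,
        normalized=True,
    )


def window_sums(
    profile: RTStopProfile, width: int = 5
) -> Dict[str, np.ndarray]:
    """Sum the profile in non-overlapping windows tiling from position 0.

    Returns contig -> vector of window sums; a final partial window is
    kept (detectable from the contig length)."""
    if width < 1:
        raise ValueError("window width must be >= 1")
    out = {}
    for contig, vec in profile.counts.items():
        n_windows = -(-len(vec) // width)
        padded = np.zeros(n_windows * width)
        padded[: len(vec)] = vec
        out[contig] = padded.reshape(n_windows, width).sum(axis=1)
    return out


def meth_score(
    low: Dict[str, np.ndarray],
    high: Dict[str, np.ndarray],
    width: int = 5,
    contig_lengths: Optional[Dict[str, int]] = None,
    eps: float = 0.5,
    eps_low: Optional[float] = None,
    eps_high: Optional[float] = None,
) -> List[MethWindow]:
    """Score each window by its low-vs-high dNTP contrast, ranked by score.

    Both inputs must come from window_sums over the same tiling. The
    pseudocount eps is half a read per window per library; on normalized
    profiles pass eps_low/eps_high = eps * scale / mapped_reads so the
    smoothing stays worth half a *raw* read in each library (otherwise a
    single background read in an otherwise empty window would dominate the
    ranking). Empty windows score exactly 0.5 when eps_low == eps_high.
    """
    if set(low) != set(high) or any(len(low[c]) != len(high[c]) for c in low):
        raise ValueError("low and high window tilings disagree")
    e_lo = eps if eps_low is None else eps_low
    e_hi = eps if eps_high is None else eps_high
    windows: List[MethWindow] = []
    for contig in low:
        n = len(low[contig])
        length = contig_lengths.get(contig) if contig_lengths else None
        for i in range(n):
            lo, hi = float(low[contig][i]), float(high[contig][i])
            score = (lo + e_lo) / (lo + hi + e_lo + e_hi)
            partial = bool(
                length is not None and i == n - 1 and length % width != 0
            )
            windows.append(
                MethWindow(contig, i * width, width, lo, hi, score, partial)
            )
    windows.sort(key=lambda w: (-w.score, w.contig, w.start))
    return windows


def windows_to_frame(windows: Sequence[MethWindow]) -> pd.DataFrame:
    """Tabulate windows; window_start_display is the 1-based first base."""
    return pd.DataFrame(
        [
            {
                "contig": w.contig,
                "window_start": w.start,
                "window_start_display": w.start + 1,
                "width": w.width,
                "low_sum": w.low_sum,
                "high_sum": w.high_sum,
                "score": w.score,
                "partial": w.partial,
            }
            for w in windows
        ],
        columns=[
            "contig",
            "window_start",
            "window_start_display",
            "width",
            "low_sum",
            "high_sum",
            "score",
            "partial",
        ],
    )


def score_windows(
    low_reads: Iterable[AlignedRead],
    high_reads: Iterable[AlignedRead],
    reference: Reference,
    width: int = 5,
    eps: float = 0.5,
    scale: float = 1e6,
) -> List[MethWindow]:
    """End-to-end Nm scoring: extract stops from each library, normalize by
    mapped reads, window and score."""
    raw_low = extract_rtstops(low_reads, reference, "low")
    raw_high = extract_rtstops(high_reads, reference, "high")
    low_prof = normalize_profile(raw_low, scale)
    high_prof = normalize_profile(raw_high, scale)
    lengths = {c: len(s) for c, s in reference.contigs.items()}
    return meth_score(
        window_sums(low_prof, width),
        window_sums(high_prof, width),
        width=width,
        contig_lengths=lengths,
        eps=eps,
        eps_low=eps * scale / raw_low.mapped_reads,
        eps_high=eps * scale / raw_high.mapped_reads,
    )


def site_report(
    windows_by_sample: Dict[str, Sequence[MethWindow]],
    positions: Sequence[int],
    contig: Optional[str] = None,
) -> pd.DataFrame:
    """Report the covering window per queried position for each sample.

    Positions are 1-based user coordinates. With exactly two samples a
    score_diff column (second minus first) is added. Positions outside
    the windowed region produce a warning and no row.
    """
    import warnings

    rows = []
    sample_names = list(windows_by_sample)
    for pos1 in positions:
        pos = pos1 - 1
        row: Dict[str, object] = {"position_display": pos1}
        found = True
        for name in sample_names:
            windows = windows_by_sample[name]
            hit = next(
                (
                    w
                    for w in windows
                    if (contig is None or w.contig == contig)
                    and w.start <= pos < w.start + w.width
                ),
                None,
            )
            if hit is None:
                warnings.warn(
                    f"position {pos1} not covered by any window in {name}",
                    stacklevel=2,
                )
                found = False
                break
            row[f"{name}_low_sum"] = hit.low_sum
            row[f"{name}_high_sum"] = hit.high_sum
            row[f"{name}_score"] = hit.score
        if not found:
            continue
        if len(sample_names) == 2:
            row["score_diff"] = (
                row[f"{sample_names[1]}_score"] - row[f"{sample_names[0]}_score"]
            )
        rows.append(row)
    return pd.DataFrame(rows)
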