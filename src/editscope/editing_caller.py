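"""A-to-I editing detection from quality-filtered pileups.

The caller collects every mismatch between reads and the reference after a
per-base Phred filter, removes positions catalogued as germline SNPs,
restricts to the A-to-I signature (A>G inside + strand features, T>C
inside - strand features, since inosine is read as guanosine), and reports
the per-site editing rate n_alt / (n_ref + n_alt).

Strand is assigned from feature annotation, not read orientation: an
unstranded poly-A library makes read orientation uninformative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .seq_io import Feature, PileupColumn, Reference, SNPMask

BASES = "ACGT"


@dataclass(frozen=True)
class CandidateSite:
    """A position where the most frequent non-reference base passes the
    alt-count and depth thresholds. Ties between alternative bases are
    broken alphabetically."""

    contig: str
    pos: int
    ref_base: str
    alt_base: str
    n_ref: int
    n_alt: int
    depth: int

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("alt base must differ from reference base")
        if self.n_ref + self.n_alt > self.depth:
            raise ValueError("informative counts cannot exceed depth")


@dataclass(frozen=True)
class EditingSite:
    """A candidate classified as A-to-I: (A>G) on a + feature or (T>C) on
    a - feature, both read as A>G on the transcript."""

    contig: str
    pos: int
    ref_base: str
    alt_base: str
    n_ref: int
    n_alt: int
    depth: int
    strand: str
    gene_id: str

    @property
    def edit_class(self) -> str:
        return "A>G"

    @property
    def rate(self) -> float:
        return editing_rate(self)


def collect_mismatches(
    columns: Iterable[PileupColumn],
    reference: Reference,
    min_alt: int = 2,
    min_depth: int = 10,
) -> List[CandidateSite]:
    """Collect all mismatch sites passing depth/alt-count thresholds.

    Expects columns already filtered at the caller's Phred threshold
    (default pipeline: Q30). Positions with reference base N never reach
    this function (the pileup suppresses them) but are skipped defensively.
    """
    candidates: List[CandidateSite] = []
    for col in columns:
        ref_base = reference.contigs[col.contig][col.pos]
        if ref_base == "N":
            continue
        if col.depth < min_depth:
            continue
        # alphabetical tie-break: max() keeps the first maximum in BASES order
        alt_base = max(
            (b for b in BASES if b != ref_base), key=lambda b: col.counts[b]
        )
        n_alt = col.counts[alt_base]
        if n_alt < min_alt:
            continue
        candidates.append(
            CandidateSite(
                contig=col.contig,
                pos=col.pos,
                ref_base=ref_base,
                alt_base=alt_base,
                n_ref=col.counts[ref_base],
                n_alt=n_alt,
                depth=col.depth,
            )
        )
    return candidates


def mask_snps(
    candidates: Sequence[CandidateSite], mask: SNPMask
) -> List[CandidateSite]:
    """Drop every candidate at a catalogued SNP position, preserving order."""
    return [c for c in candidates if (c.contig, c.pos) not in mask]


def classify_editing(
    candidates: Sequence[CandidateSite], features: Sequence[Feature]
) -> List[EditingSite]:
    """Keep A>G candidates inside + features and T>C inside - features.

    Sites outside any feature are dropped; a site covered by features of
    both strands is dropped with a warning (ambiguous strand).
    """
    by_contig: Dict[str, List[Feature]] = {}
    for f in features:
        by_contig.setdefault(f.contig, []).append(f)

    sites: List[EditingSite] = []
    for cand in candidates:
        hits = [
            f
            for f in by_contig.get(cand.contig, ())
            if f.start <= cand.pos < f.end
        ]
        if not hits:
            continue
        strands = {f.strand for f in hits}
        if len(strands) > 1:
            warnings.warn(
                f"site {cand.contig}:{cand.pos} overlaps features of both "
                "strands; dropped as strand-ambiguous",
                stacklevel=2,
            )
            continue
        strand = strands.pop()
        expected = ("A", "G") if strand == "+" else ("T", "C")
        if (cand.ref_base, cand.alt_base) != expected:
            continue
        sites.append(
            EditingSite(
                contig=cand.contig,
                pos=cand.pos,
                ref_base=cand.ref_base,
                alt_base=cand.alt_base,
                n_ref=cand.n_ref,
                n_alt=cand.n_alt,
                depth=cand.depth,
                strand=strand,
                gene_id=hits[0].gene_id,
            )
        )
    return sites


def editing_rate(site: EditingSite | CandidateSite) -> float:
    """Editing rate n_alt / (n_ref + n_alt).

    The denominator excludes third-allele noise, the conventional
    editing-ratio definition.
    """
    informative = site.n_ref + site.n_alt
    if informative == 0:
        raise ValueError("editing rate undefined at zero informative depth")
    return site.n_alt / informative


def sites_to_frame(sites: Sequence[EditingSite]) -> pd.DataFrame:
    """Tabulate editing sites; `pos` stays 0-based, `pos_display` is 1-based."""
    return pd.DataFrame(
        [
            {
                "contig": s.contig,
                "pos": s.pos,
                "pos_display": s.pos + 1,
                "strand": s.strand,
                "gene_id": s.gene_id,
                "n_ref": s.n_ref,
                "n_alt": s.n_alt,
                "depth": s.depth,
                "rate": s.rate,
            }
            for s in sites
        ],
        columns=[
            "contig",
            "pos",
            "pos_display",
            "strand",
            "gene_id",
            "n_ref",
            "n_alt",
            "depth",
            "rate",
        ],
    )


def write_sites(sites: Sequence[EditingSite], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
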