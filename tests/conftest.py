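"""Shared fixtures: a small simulated dataset and brute-force oracles."""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, Tuple

import numpy as np
import pytest

from editscope import synthetic_data as sd
from editscope.seq_io import AlignedRead, Reference


def brute_force_pileup(
    reads: Iterable[AlignedRead], min_phred: int
) -> Dict[Tuple[str, int], Dict[str, int]]:
    """Per-read, per-base enumeration of quality-filtered counts —
    independent of the vectorised pileup engine."""
    counts: Dict[Tuple[str, int], Dict[str, int]] = defaultdict(
        lambda: defaultdict(int)
    )
    for read in reads:
        rpos, qpos = read.start, 0
        for op, n in read.cigar:
            if op == "M":
                for i in range(n):
                    base = read.seq[qpos + i]
                    if read.quals[qpos + i] >= min_phred and base in "ACGT":
                        counts[(read.contig, rpos + i)][base] += 1
                rpos += n
                qpos += n
            elif op == "D":
                rpos += n
            else:  # I, S consume query only
                qpos += n
    return counts


def make_read(
    contig: str,
    start: int,
    seq: str,
    quals=None,
    cigar=None,
    strand: str = "+",
    name: str = "r",
    flag: int = 0,
) -> AlignedRead:
    if quals is None:
        quals = (37,) * len(seq)
    if cigar is None:
        cigar = (("M", len(seq)),)
    return AlignedRead(
        contig=contig,
        start=start,
        strand=strand,
        seq=seq,
        quals=tuple(quals),
        cigar=tuple(cigar),
        name=name,
        flag=flag,
    )


@pytest.fixture(scope="session")
def small_cfg() -> sd.SimConfig:
    return sd.SimConfig(
        n_contigs=1,
        contig_length=2000,
        n_features=4,
        n_editing_sites=20,
        n_snps=10,
        depth=80,
        read_length=50,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """Reference + truth + condition-A reads, shared across read-only tests."""
    reference = sd.simulate_reference(small_cfg)
    editing, mask, snps, nm_sites = sd.plant_truth(reference, small_cfg)
    reads = sd.simulate_rnaseq(reference, editing, snps, small_cfg)
    return {
        "cfg": small_cfg,
        "reference": reference,
        "editing": editing,
        "mask": mask,
        "snps": snps,
        "nm_sites": nm_sites,
        "reads": reads,
    }
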