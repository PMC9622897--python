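# Methods

## Coordinate and format conventions

All in-memory coordinates are 0-based, half-open. Conversion happens only
at file boundaries: VCF `POS` is 1-based, BED is 0-based half-open, and
output TSVs carry both a 0-based `pos` and a 1-based `pos_display`
column. SAM and VCF are read and written through pysam, FASTA through
Biopython; plain-text SAM is the tested contract (BAM works through the
same reader). SAM writing emits no `@PG` line or timestamps so identical
runs are byte-identical.

## Pileup and editing calling

The pileup engine walks each read's CIGAR (`M` adds bases, `D` consumes
reference only, `I`/`S` consume query only) and accumulates per-position
base counts per contig. A base contributes only if its Phred score is at
or above the threshold (default Q30, i.e. 0.1% call-error). The filter is
applied to **every** aligned base, matching or not, so the editing-rate
denominator is built from the same filtered pool as the mismatches; an
asymmetric filter (mismatches only) would bias rates downward at noisy
positions. Reference-N positions yield no columns (a mismatch is
undefined there). Duplicate-flagged reads are kept by default; a
`--drop-duplicates` switch removes flag-0x400 records.

A candidate site requires filtered depth ≥ `min_depth` (default 10) and a
most-frequent non-reference base with count ≥ `min_alt` (default 2); ties
between alternative bases break alphabetically, deterministically. These
floors are deliberate caller-side defaults: with Q ≥ 30 bases, two
independent identical errors at one position are rare at desk-scale
depth, which keeps type-I calls low without masking intermediate editing
rates. Candidates at SNP-mask positions are removed before
classification. Strand is assigned from gene annotation, not read
orientation (an unstranded poly-A library carries no strand information
in the read itself): A>G inside `+` features and T>C inside `-` features
are A-to-I; everything else is discarded, as are sites outside any
feature or under features of conflicting strand. The editing rate is
`n_alt / (n_ref + n_alt)`, excluding third-allele noise from the
denominator.

## Differential editing

Per site, the 2×2 table `[[alt_A, ref_A], [alt_B, ref_B]]` is tested with
a two-sided Fisher's exact test — exact at the low counts typical of
editing sites, and verifiable by hypergeometric enumeration. Tables with
an empty margin across both conditions return p = 1 by convention.
Benjamini–Hochberg adjustment (statsmodels' step-up) controls the FDR
across sites; a gene is flagged "variable" when its minimum site q-value
passes the threshold (default 0.05) — min-q aggregation is transparent
and easy to audit, at the cost of favouring genes with many sites.

The global shift statistic defaults to a Wilcoxon signed-rank test over
per-site rate differences of sites shared between conditions, matching a
paired knockdown-vs-control design on the same cell population; a
Mann–Whitney variant over pooled rates is available for unpaired designs.
Direction is the sign of the median difference; an all-zero difference
vector returns p = 1 with direction `none`.

Dysregulated-gene overlap consumes two differential-expression tables
(gene, linear fold-change, FDR) and selects genes with
`|log2 FC| > log2(fc)` (default fc = 2, so 2-fold up **or** down) and
`FDR < 0.05`, returning the intersection and selection sizes. Duplicate
gene identifiers are an error, not silently collapsed.

## Nm (2′-O-methylation) scoring

Each read's 5′-most reference position `p` marks an RT stop at `p − 1`
(the library protocol places read starts 1 nt downstream of the stop);
reads starting at position 0 are dropped since their stop lies off the
contig. Whether the methylated ribose sits at the stop position or one
nucleotide 5′ of it differs between protocols by at most one 5 bp window;
the simulator's truth table pins the convention used here (stop at the Nm
position itself). Profiles are normalized to counts per million mapped
reads, summed in non-overlapping 5 bp windows tiling from coordinate 0
(a terminal partial window is kept and flagged), and scored

    score = (low + ε_low) / (low + ε_low + high + ε_high)

with ε worth half a raw read in each library (ε_mode = 0.5 ×
scale / mapped_reads_mode). Applying the pseudocount in raw-read units
matters: a fixed ε on CPM-scale sums is numerically void, and a single
stray background read in an otherwise empty window would then outrank a
genuinely methylated window. The score is bounded, monotone in any
low-over-high enrichment, and depth-invariant in expectation; its exact
functional form is this package's own definition. Stop extraction
assumes a single-stranded (+) template (rRNA-like); reverse-strand reads
can be counted by the symmetric 3′-end rule behind a flag, default off.

## The simulator: what it emulates, and what it does not

The generator stands in for the raw libraries of an editing/Nm study:

* **Reference**: uniform-random contigs (default 2 × 5 kb) with
  non-overlapping strand-labelled gene features on a regular grid.
* **Editing**: default 60 sites at feature-strand adenosines, true rates
  Beta(2, 5) (mean ≈ 0.29, right-skewed — typical of editing-rate
  distributions); each covering read carries the edited allele
  independently with the site rate (binomial sampling). The knockdown
  condition subtracts a global 0.1 from every rate (clipped at 0).
* **SNPs**: default 30 positions, disjoint from editing sites by
  construction, with fixed allele fractions 0.5 (het) or 1.0 (hom) —
  the separability the dbSNP mask exploits in real data.
* **Qualities and errors**: two-component Phred model (≈Q37 and ≈Q20 ± 3,
  15% low) so the Q30 filter actually removes bases; independent
  substitution errors at 0.2%.
* **RT stops**: molecules prime at uniform random 3′ positions and walk
  3′→5′; per-nucleotide background stop probability 0.002 (an RT that
  can traverse a few kb, matching observed processivity at saturating
  dNTPs); at an Nm site the walk terminates with probability
  1 − stop-through, with stop-through defaults 0.2 (low dNTP: strong
  pausing) and 0.98 (high dNTP: near-complete read-through). Each
  stopped molecule yields one read starting 1 nt downstream; run-off
  molecules yield reads at position 0, which the scorer discards.

Reads are emitted pre-aligned at their true positions with all-M CIGARs:
alignment is outside this package's scope, so passing tests demonstrate
the *quantification* is correct given correct alignments — they say
nothing about alignment artefacts, splicing, indels, PCR duplicates,
paired-end effects, hyper-edited reads that fail to map, or
position-dependent error profiles, none of which the simulator models.
All randomness flows from a single integer seed (per-stage offsets are
fixed), making every output file byte-reproducible.

## Problem sizes and numerical choices

The default demo (2 × 5 kb contigs at 200× coverage, 4 000 RT molecules
per library) runs in seconds and is the unit the test suite and
`scripts/acceptance.py` exercise end-to-end; rate-recovery checks use a
single 12 kb contig with 500 sites at 2 000×, and replicate-based checks
(global-shift power, Nm ranking) use 20–100 seeded replicates at reduced
contig sizes. Floating-point identities (FPKM conservation, window-sum
conservation) are asserted at 1e-9 relative tolerance; the BH oracle
comparison at 1e-12.

## Known limitations

* Editing calls at very low rates (< ~2/min_depth) are censored by the
  alt-count floor; recovery statements are conditioned on detectable
  sites.
* Min-q gene aggregation does not correct for the number of sites per
  gene; Fisher-combination or hierarchical alternatives are out of scope.
* The global-shift test treats sites as independent; clustered editing
  within a transcript violates this mildly.
* The Nm score contrasts exactly two libraries; replicate-aware scoring
  and overlapping windows are not implemented.
* No effective-length modelling in FPKM, and no amplification-efficiency
  (Pfaffl) correction in the ΔΔCt computation.
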