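# Methods

## Problem and model

An insect host co-sequenced with an intracellular endosymbiont (here modelled
on an ant carrying *Wolbachia*) yields a mixed assembly: most scaffolds are
purely host or purely symbiont, but two confusable classes remain. A genuine
**horizontal gene transfer (HGT)** is a symbiont-derived fragment integrated
into a host chromosome; it lives in host chromatin and is therefore sequenced
at *host* depth throughout, including across its boundaries. A **chimeric
mis-assembly** joins a host molecule and a symbiont molecule in silico; each
side retains the depth of its source, so read depth steps at the join.
`hgtscan` operationalises that distinction:

1. **TAGC screening** (`hgtscan.tagc`). Each scaffold is summarised by GC
   fraction, mean read depth, and the union coverage of host-bin and
   symbiont-bin similarity hits. A scaffold is *symbiont* when symbiont hits
   cover ≥ `f_pure` (default 0.90) of its length and host coverage stays
   under `min_block`; *hgt_candidate* when both bins contribute ≥
   `min_block` (default 300 bp); *host* in the symmetric case; otherwise
   *unassigned*. Reference depths for the depth-cluster annotation are the
   medians of the host- and symbiont-labelled cohorts from a hits-only first
   pass (medians resist outliers); a scaffold within log2(`tau_depth`)
   (default ratio 1.5) of both is *intermediate*. GC is computed for the
   blob plot but is not a decision criterion: a ~36% GC host and ~35% GC
   symbiont are inseparable on that axis, which is exactly why taxonomy +
   coverage carry the decision.
2. **Block discovery** (`hgtscan.detect.anchor_chain_align`). A light exact
   k-mer anchor chainer stands in for a genome aligner at desk scale:
   anchors (default k = 21) are chained along diagonals when consecutive
   anchors are ≤ `max_gap` (500 bp) apart, chains with query and reference
   gaps both ≤ `max_gap` merge into blocks, and blocks shorter than
   `min_block` are dropped. Reference k-mers occurring more than `m_rep`
   (10) times anchor nothing, which suppresses repeat-driven block joins.
   Forward strand only: the simulator plants forward insertions, and the
   evidence the pipeline extracts from blocks (coverage, boundaries) is
   strand-agnostic.
3. **Segmentation** (`segment_candidate`). A candidate insertion is a
   maximal run of symbiont blocks (merged across ≤ `max_gap` gaps) flanked
   by a host block on at least one side or by a scaffold end. Junctions are
   placed at the midpoint of the inter-block gap — anchors fray where edits
   are dense, and the midpoint halves the worst-case boundary error. Where
   host and symbiont blocks overlap, the lower-identity block is trimmed;
   overlaps ≤ 30 bp (chance anchor extension across a clean boundary) are
   split at the midpoint; larger identity ties create an ambiguous zone
   whose junctions are excluded from evidence.
4. **Junction depth test** (`junction_depth_test`). Mean depth in
   `[pos-guard-window, pos-guard)` vs `[pos+guard, pos+guard+window)`
   (window 500 bp, guard 50 bp), compared as a log2 ratio with pseudo-depth
   ε = 0.5 against the band log2(`tau_junction`), default ratio 1.5. At
   ~47× depth the standard error of a 500 bp window mean is ≈ 0.3×, so the
   band comfortably absorbs sampling noise while a 47× → 120× step
   (|log2 ratio| ≈ 1.34) is unambiguous. Windows leaving the scaffold, or
   with fewer than `w_min` covered bases, give *indeterminate*.
5. **Cross-assembly corroboration** (`corroborate_junction`). The junction
   ± `flank` (500 bp) window is aligned against each independently produced
   assembly; an assembly corroborates when one contig carries a single block
   covering ≥ `flank_covered` (200 bp) on each side of the junction. The
   call-level corroboration count is the minimum over internal junctions.
6. **Verdict** (`call_hgt`). Any step-change junction ⇒ *chimera_suspect*.
   All junctions continuous — edge junctions, which have no second side to
   test, do not block — and corroborations ≥ `c_min` (1) ⇒ *hgt*. Anything
   else ⇒ *unresolved* (e.g. a clean insertion with no corroborating
   assembly available). When host and symbiont reference depths fall within
   the junction band of each other, the depth test cannot separate chimeras;
   this confound is reported in the call notes rather than silently passed.
7. **Annotation.** Transposase proximity is the minimum gap to a transposase
   feature (0 when overlapping; absent beyond `max_dist` = 2 kb); genes
   overlap by ≥ 1 bp under half-open arithmetic; a gene is transcribed when
   its FPKM ≥ `min_fpkm` (0.01).

## Multi-strain evidence (`hgtscan.strains`)

Co-infecting symbiont strains distort a short-read assembly in three
measurable ways, scored independently: single-copy reference genes placed at
≥ 2 non-overlapping loci (placements qualify at identity ≥ `id_min` = 0.90
covering ≥ `cov_min` = 0.80 of the gene; overlapping placements merge as
split hits of one locus); single-copy genes containing ≥ `v_min` = 2 variant
sites at depth ≥ `d_min` = 10 and minor-allele fraction ≥ `maf_min` = 0.10;
and typing markers (MLST genes *ftsZ*, *hcpA*, *gatB* and the CI pair
*cifA*/*cifB*) duplicated across scaffolds. The assembly is flagged
multi-strain when duplicated genes reach `t_dup` = 5, polymorphic genes
reach `t_poly` = 5, or any marker duplicates — OR semantics, since each line
is individually diagnostic and the thresholds are set conservatively against
split-hit and noise artifacts.

Gene-set recovery percentages are **truncated** (not rounded) to two
decimals — the convention under which 80/84 prints as 95.23% — via decimal
arithmetic, as are library yield totals (fixed-point two-decimal sums, so
printed gigabase figures add exactly).

## Coordinate conventions

Internally everything is 0-based half-open; conversions happen once, at the
I/O boundary. BLAST tabular and GFF3 input (1-based inclusive) get
`start − 1`; reversed subject coordinates are normalised to forward with
strand recorded. Printed interval strings of the form
`scaffold: start–end` are a separate dialect whose published lengths equal
`end − start`; the parser therefore keeps the printed numbers verbatim as
half-open bounds. Whether the printed start is itself 0- or 1-based is not
recoverable from length arithmetic; only the length convention is fixed, and
the parser documents the ambiguity.

## The synthetic study (`hgtscan.simulate`)

The generator reproduces the statistical structure the detector assumes, at
desk scale. Defaults: a 1 Mb host at GC 0.36 sequenced to 47.37×, a 300 kb
symbiont at GC 0.3513 at 120×, three planted insertions of 0.5–20 kb, one
chimera, 100 bp reads. The host splits into 4 scaffolds (the last always
insertion-free, as a negative control) and the symbiont into 6. These sizes
keep a full study under ~10 s while leaving every depth-window and
block-length relationship at realistic scale; the genuine study this design
emulates involved a ~278 Mb host and ~3 Mb symbiont assembled from ~100 Gb
of reads, which is far outside desk scope, so assembly-scale headline
numbers (total lengths, gene counts) are not reproduction targets.

Key design choices:

- **Reads are placed, not mapped.** Uniform single-end placements per
  replicon, `round(depth·L/read_length)` reads; depth tracks are computed
  exactly from the placements. The evidence channel is depth, so a mapping
  step would add machinery without adding signal. Reads are error-free by
  default (an error knob exists but no implemented statistic consumes
  errors); read starts are uniform — GC bias is out of scope.
- **Insertions** are non-overlapping symbiont fragments at uniform host
  positions, kept 3 kb from scaffold ends and apart from each other; truth
  records source and destination, and the planted subsequence equals the
  destination subsequence exactly. Source fragments are drawn within single
  symbiont reference scaffolds: the donor is one molecule, and a fragment
  straddling an arbitrary reference split would only test the reference
  bookkeeping, not the biology. A transposase feature is annotated within
  2 kb of each insertion (flag-controlled) as an *annotation*, not a
  realistic transposase sequence — the detector consumes annotations.
- **Chimeras** concatenate a host and a symbiont fragment with reads
  simulated per fragment, so depth steps exactly at the join and no read
  spans it. With equal configured depths a chimera is *designed* to be
  indistinguishable from an insertion by depth — that confound is real and
  the pipeline reports it.
- **Alternative assemblies** are shreds of the true (post-insertion)
  scaffolds: a Poisson breakpoint process with `round(L/mean)−1` expected
  cuts (exponential spacing), fragments shuffled, tiling the genome exactly.
  Breakpoints falling within 1.5 kb of a truth junction are dropped,
  emulating the observed study outcome in which every independent
  re-assembly contained contigs spanning every junction; an assembler has
  no systematic reason to break at a genuine insertion boundary. The
  negative control (a forced breakpoint at the junction) is constructed
  explicitly in tests.
- **Strain mixtures** pool reads from `n_strains` variant genomes (i.i.d.
  substitutions at the configured divergence, default 3%) at equal
  proportions. The variant-site table is computed from the actual pooled
  read placements overlapping each planted difference — the simulator emits
  the pileup-like table directly; variant *calling* from raw reads is out of
  scope. In the strain-evidence study each single-copy gene's second-strain
  copy either assembles as a separate locus (probability `p_split` = 0.3 →
  a duplicated gene) or collapses (→ polymorphism at the planted sites);
  markers always split when more than one strain is present.

### What the simulation does not capture

Real data add alignment fraying, repeat-induced mis-anchoring, GC-coverage
bias, indel divergence between strains (the aligner chains per diagonal,
which substitution-only divergence never shifts), rearrangements between
donor and recipient, and reference databases that are neither complete nor
clean. Passing tests therefore demonstrate that the *logic* of the evidence
combination is correct under its stated model, not that field performance on
a new genome will match the simulated sensitivity of 1.0.

## Numerical and degenerate-input choices

- Pseudo-depth ε = 0.5 in every depth log-ratio (dropout windows).
- GC excludes ambiguity codes from numerator and denominator; an
  all-ambiguous sequence has GC 0.
- Nxx tie-handling is QUAST-style: the qualifying contig's own length is
  reported even when shared; Lxx counts through the first qualifying contig.
- Junction tests at scaffold edges return *indeterminate* rather than
  erroring; edge inserts (a symbiont run starting within `max_gap` of a
  scaffold end) keep one testable junction and the missing one does not
  block an *hgt* verdict.
- The classifier's first pass uses hit coverage only; if a cohort is empty
  the overall median depth stands in for its reference depth.

## Problem sizes used in validation

The test suite runs 20 seeded full-condition studies (1 Mb host, 300 kb
symbiont, 3 insertions, 1 alternative assembly each) for parameter recovery,
200 random/planted sequence pairs ≤ 2 kb against a brute-force per-diagonal
block finder, 1000 random length multisets against a cumulative-scan Nxx
oracle, and 10 + 10 strain-study seeds for the multi-strain flag. The
acceptance script re-runs a 6-study detection sweep, one 69 + 5 + 1-scaffold
partition study, and 5 + 5 strain studies, all derived from a single seed.

## Known limitations

Forward-strand alignment only; no indel-aware chaining; single-end reads;
depth-equality chimeras are undetectable by design (reported, not resolved);
the strain module consumes placements and pileups rather than raw reads; the
printed-interval parser fixes only the length convention, not the start
basis.
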