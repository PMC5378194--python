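# Methods

This note documents the models, parameter choices and numerical
conventions behind `tss_atlas`, and what the simulator-based validation
does and does not demonstrate.

## Coordinate and data conventions

All internal coordinates are 0-based half-open on the forward genome
strand; GFF3 I/O converts to/from 1-based inclusive, BED6 is native. A
read's *head* is its 5′ end: `start` for a `+` read, `end − 1` for a `−`
read. The SAM reader accepts mapped primary records only and applies no
CIGAR-aware clipping — adequate for simulated end-to-end alignments, a
documented limitation for real data. Library metadata (id, kind ∈
{plus, minus, whole}, condition) comes from a YAML manifest rather than
file-name conventions.

## TSS calling

Same-strand reads connected by ≥ 1 bp overlap form contigs (abutting
reads do not merge). Within a contig the position with the maximal
(+)-library head count is the primary TSS iff the count ≥ `theta_primary`
(default 10 reads); without a primary the contig yields no calls.
Additional positions become secondary TSSs when they carry
≥ `theta_secondary` (5) heads, are local maxima within
± `local_max_halfwidth` (2 nt) and lie ≥ `min_tss_spacing` (5 nt) from
every already-accepted call, accepted greedily by descending count.
Design choices where the procedure is under-determined:

* **Ties** at equal head counts resolve to the 5′-most position relative
  to the strand (maximises the UTR; deterministic).
* **Local-maximum + spacing** constraints on secondaries prevent the
  ragged shoulder of one promoter from being called as many TSSs.
* An optional per-site **(+)/(−) enrichment ratio** filter exists but is
  disabled by default: the literal calling criterion uses only
  (+)-library counts.
* A secondary is not required to have strictly fewer heads than the
  primary; a distant equal-count peak is callable (the tie at the
  primary itself is already resolved 5′-most).

Calls are made per condition and merged on exact (position, strand); the
original study's manual curation step is replaced by the deterministic
refinement rule below.

## Coverage-continuity refinement

A TSS linked to a downstream same-strand start codon within `max_utr`
(500 nt, motivated by the longest observed UTR of 497 nt) must show
whole-transcript coverage ≥ `min_cov` (1) at every base from
TSS + `gap_allow` to the codon; `gap_allow` defaults to 30 nt, the upper
end of the 20–30 nt 5′-terminal under-representation of conventional
RNA-seq. Refinement never moves a call. A call failing the rule is *not*
deleted — it merely cannot be the gene TSS of that ORF (the flag is
recorded and classification re-applies the rule). Deleting such calls
would erase genuine sRNA TSSs that happen to lie within 500 nt of some
gene start; keeping them matches the category semantics, where the same
site may be iTSS/aTSS/nTSS instead.

## Classification

Categories are non-exclusive: **g** (nearest same-strand ORF start within
(TSS, TSS+500] downstream, continuity holding; ties to the nearest
start), **i** (strictly inside a same-strand CDS, terminal bases
excluded), **a** (opposite-strand within the gene's transcript span = CDS
extended 5′ by that gene's longest *called* UTR and 3′ by a fixed
`utr3_allowance` of 50 nt, since 3′ ends are not mapped), **n** (outside
all CDS on both strands and not a gTSS — a 5′ UTR is not a non-coding
RNA). Classification is two-pass so the antisense spans can use the gTSS
index of the first pass. TSSs downstream of an annotated start are iTSS
only; re-annotating ORF starts from iTSS evidence is out of scope.
Intergenic regions (IGRs) are the gaps between merged CDS intervals,
numbered left to right; mutually antisense sRNA pairs are opposite-strand
nTSS pairs sharing an IGR ordinal.

## Quantification and differential analysis

HRPM sums head counts over the 50-nt window starting at the TSS in the
direction of transcription, scaled per million mapped reads. RPKM counts
same-strand alignments overlapping a CDS by ≥ 1 bp. Fold changes add a
pseudocount expressed in *reads* and converted to HRPM units via each
library's size, so it is depth-aware; sRNA classes use the ≥ 35× (up in
the cold) and ≥ 4× (down) bounds. Temperature-dependent TSS selection is
operationalised — the source procedure is unstated — as: dominant TSS
flips between conditions, or any usage share `u_i = HRPM_i / Σ HRPM_j`
moves by ≥ `min_delta` (0.3); a condition with zero total HRPM leaves the
call undefined rather than negative. No replicate-aware statistical test
or multiple-testing correction is applied (thresholded fold changes only);
this is an explicit extension point. Spike-in QC is the Pearson r of
log2(RPKM) vs log2(concentration) over spike-ins with non-zero signal.

## Operons

Candidates are maximal same-strand runs with intergenic gaps
≤ `max_gap` = 200 nt — a neutral, configurable stand-in for external
operon predictors, not a published value. Refinement keeps a candidate
iff its transcription-first gene owns a gTSS and coverage is continuous
from that gTSS (minus `gap_allow`) through the last CDS end; candidates
with a zero-coverage intergenic hole are split there and the pieces
re-evaluated (idempotent). Refinement uses the condition with the deeper
(w) library. Internal gTSSs of member genes are suboperon starts; a TSS
serving several member genes is counted once.

## Promoter scanning

The 50-nt window upstream of a TSS (TSS base excluded, strand-oriented,
truncated at reference edges) is scanned for an IUPAC consensus —
default TTTAWA for the archaeal TATA box — or a 4×L PWM scored by
log2-odds against a uniform background. The reported offset is the
distance from the TSS to the motif's 3′ edge; ties prefer the canonical
19–22 nt band, then the 5′-most placement. This is a deterministic
stand-in for de novo motif discovery; promoter regions export to FASTA
for external motif tools.

## The simulator

The generator defines the study conditions used by all recovery tests.

* **Layout.** Gene entities (operons of 2–3 genes with 20–80 nt internal
  gaps, or standalone genes) are placed left to right with 300–500 nt
  between entities, each keeping a 545-nt upstream reserve so any UTR up
  to 500 nt plus a promoter fits without touching a neighbour; CDS
  lengths are 300–900 nt with real start/stop codons. Inter-entity gaps
  therefore always exceed the operon-candidate `max_gap`, so the planted
  operon map is identifiable.
* **UTRs.** A point mass below 10 nt (leaderless, default fraction 0.16,
  matching the observed 15.6–16%) mixed with a discretised log-normal
  (median 55 nt, log-sd 1.4, truncated to [10, 500]) — this reproduces
  the observed range and median without claiming the exact distribution.
* **Multi-TSS and switching.** 30% of standalone genes get a second TSS
  whose UTR is ≥ 60 nt longer (so the two HRPM windows never overlap);
  half of those flip dominant usage 0.8/0.2 → 0.2/0.8 between conditions,
  with the long-UTR isoform dominating in the cold; stable multi-TSS
  genes sit at 0.7/0.3 in both conditions.
* **sRNAs.** Placed in intergenic windows that exclude the 5′ UTR zone
  of any flanking gene whose start codon faces the gap — structurally
  guaranteeing a coverage hole between the sRNA and any downstream ORF,
  so a planted sRNA can never satisfy the gTSS continuity rule. 30% are
  cold-induced at 100× (the study reports changes up to > 1000-fold),
  30% cold-repressed at 8×. Two IGRs host opposite-strand (mutually
  antisense) pairs.
* **Libraries.** Head sites carry weights: the TSS gets
  expression × (1 − `processed_fraction`), each planted processed (5′P)
  site its share of `processed_fraction`; the (−) library draws `depth`
  reads multinomially from these, the (+) library from the same sites
  re-weighted by `e_tex` (0.9) for 5′PPP heads and `rho` (0.05) for 5′P
  heads. TEX efficiency is not quantified in the source; these are
  simulator parameters, not chemistry estimates. Processed sites are
  planted 10–50 nt into the first covered CDS (degradation
  intermediates), so a leaked 5′P call presents as an iTSS. The (w)
  library tiles each unit with fixed-length reads at half-read-length
  stride starting `fiveprime_loss` = 25 nt into the transcript
  (reproducing the 20–30 nt 5′-terminal loss), with read counts
  multinomial in expression × length; whole-transcript libraries default
  to 5× the 5′-end depth, mirroring the deeper (w) sequencing of such
  studies and giving the continuity rule dense coverage to work with.
  Spike-ins (2-fold, 8-step concentration ladder on separate reference
  records) are added to (w) libraries as Poisson counts around
  proportionality, on top of the genomic depth.
* **Depth.** `depth` = 4 000 reads per 5′-end library ≈ 55 reads per
  transcription unit under the default census (~70 units) — enough for
  near-complete recovery at the ≥ 10-read primary threshold while
  keeping the weakest planted isoforms close to the calling boundary,
  which is the interesting regime. Tests of near-threshold fold-change
  classes (the 35× sRNA bound) use 16 000 reads, since at 55 reads/unit
  the pseudocount dominates the repressed condition's 1–3 counts.
* **Determinism.** All stages draw from `default_rng([seed, stage])`;
  identical parameters give byte-identical output files.

**What the simulator does not model:** sequencing errors, quality
strings, adapter artifacts, PCR duplication, multi-mapping, rRNA
contamination, fragment-length variation, or operon read-through
variation. Passing recovery tests therefore demonstrates the correctness
and calibration of the *procedure* under its stated assumptions, not
robustness to real-library noise.

## Numerical details and degenerate inputs

Empty libraries yield empty tracks; a library with `M = 0` cannot be
normalised (error). `utr_stats` requires ≥ 1 gTSS; spike-in QC requires
≥ 3 usable points and non-constant concentrations. Head-count ties and
all greedy orders are fully deterministic, so results are independent of
read order. Generator placement failures raise errors naming the violated
constraint (e.g. `genome_length` too small).

## Validation strategy

Two-route checks back every core step: the caller is compared against a
literal per-position scan built on a pairwise-overlap graph, and the
classifier against an exhaustive per-(TSS, gene) oracle, both living in
the test suite and sharing no code with the implementation. Everything
else is validated by parameter recovery against the simulator's truth
tables and by property tests (normalisation invariances, usage-share
identities, fold-change reciprocity, strand symmetry of motif offsets).
Problem sizes in the tests (toy genomes of 2–10 kb for oracles, the
default 100-kb simulation, 20 seeded replicates for switch detection)
were chosen to exercise every code path at interactive runtimes.
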