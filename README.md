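# tss-atlas

Primary-transcriptome analysis from differential RNA-seq (dRNA-seq) for
prokaryotes, with a ground-truthed synthetic-data generator. The package
re-implements, as a tested pipeline, the genome-wide transcription start
site (TSS) analysis used for cold-adaptation studies in methanogenic
archaea: TSS calling from TEX-enriched 5′-end libraries, TSS
classification, 5′ UTR architecture, HRPM/RPKM quantification,
temperature-dependent TSS selection, sRNA differential expression, operon
refinement and core-promoter scanning. It is aimed at microbial
transcriptomics researchers who want the full analysis chain as an
auditable, scriptable library rather than a collection of one-off scripts.

## The method

dRNA-seq compares two 5′-end libraries: a **(+)** library treated with
Terminator 5′-phosphate-dependent exonuclease (TEX), which degrades
processed 5′-monophosphate RNAs and so enriches primary transcripts
(5′ PPP), and an untreated **(−)** library containing both populations. A
strand-specific whole-transcript **(w)** library provides coverage for
refinement. Per condition:

1. **Contigs.** Mapped reads are clustered into contigs — maximal
   same-strand groups connected by ≥ 1 bp overlap.
2. **Calling.** The 5′ end of each read (its *head*) is counted per
   position. Within a contig, the position with the highest (+)-library
   head count is the **primary TSS** if it carries ≥ 10 reads; further
   head-count local maxima with ≥ 5 reads become **secondary TSSs**.
3. **Refinement.** A gene TSS must show continuous (w)-library coverage
   from the TSS to its downstream start codon, allowing the first
   20–30 nt to be missing (conventional RNA-seq under-represents the
   proximal 5′ terminus).
4. **Classification.** TSSs get the non-exclusive categories **g**
   (gene: same-strand ORF start within 500 nt downstream, continuity
   holding; defines the 5′ UTR, *leaderless* below 10 nt), **i** (inside
   a same-strand CDS), **a** (antisense: opposite-strand within a gene's
   transcript span) and **n** (non-coding/intergenic sRNA).
5. **Quantification.** Per TSS and library,
   `HRPM = H / (M / 10⁶)` where `H` sums head reads over the 50-nt
   window downstream of the TSS and `M` is the library's mapped reads;
   per gene, `RPKM = c / (L_kb · M/10⁶)`. Multi-TSS genes whose dominant
   TSS flips between conditions (or whose relative usage
   `u_i = HRPM_i / Σ_j HRPM_j` shifts by ≥ 0.3) show
   temperature-dependent TSS selection; nTSSs are binned by thresholded
   fold change (≥ 35× up in the cold, ≥ 4× down). ERCC-style spike-ins
   validate quantification linearity (Pearson *r* on the log2 scale).
6. **Operons & promoters.** Candidate same-strand gene runs are kept as
   operons when the first gene owns a gTSS and (w) coverage is continuous
   through the run; internal gTSSs mark suboperons. The 50-nt windows
   upstream of TSSs are scanned for the archaeal TATA box (TTTAWA),
   expected ~19–22 nt upstream of the TSS.

Because the original study's raw sequencing data are not available at
desk scale, a first-class simulator (`tss_atlas.synthetic`) generates a
toy genome and all six libraries with complete ground truth — planted
TSSs, UTRs, switch genes, cold-responsive sRNAs, operons and a 2-fold
spike-in ladder — so every step of the analysis is validated by
parameter recovery and by independent brute-force oracles.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
simulator's default conditions (50 genes, 5 operons, 10 sRNAs, 5
antisense units; 4 000 reads per 5′-end library, 20 000 per (w) library;
two conditions 8C/18C):

```bash
cd analysis
python 01_simulate.py && python 02_call_tss.py && python 03_classify_utr.py
python 04_quantify_diff.py && python 05_operons.py && python 06_promoters.py
```

prints, among other things:

```
8C: 67 TSSs (65 primary, 2 secondary)
18C: 67 TSSs (64 primary, 3 secondary)
merged: 71 non-redundant TSSs (63 in both conditions)
classified 71 TSSs: gTSS=55, iTSS=2, aTSS=5, nTSS=10
multi-TSS genes: 11 recovered (planted: 11, exact match: True)
temperature-dependent TSS selection: 7 of 11 multi-TSS genes (planted: 7)
sRNAs: 10 nTSSs, 3 cold-induced (>=35x), 3 cold-repressed (>=4x)
spike-in QC 8C: r = 0.979 over 8 spike-ins (log2 RPKM vs log2 concentration)
operons: 5 refined (planted 5, exact: True); 2 with suboperon starts
TATA (TTTAWA) found upstream of 63/71 TSSs (88.7%); 100.0% of hits at 19-22 nt
```

Reading: every planted TSS was recovered at single-nucleotide resolution
(71 called vs 70 planted; the one extra call sits on a processed 5′P site
that leaked through the TEX residual), the 11 planted multi-TSS genes and
all 7 planted switch genes were identified, the planted operon map was
recovered exactly, and the planted TATA boxes were located at their true
offset (21 nt). Tables land under `results/`.

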