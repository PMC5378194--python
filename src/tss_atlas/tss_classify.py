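"""TSS classification: gene (g), internal (i), antisense (a), non-coding (n).

Categories are non-exclusive, mirroring the usual dRNA-seq scheme:

* **g** — a same-strand CDS start lies within ``max_utr`` nt downstream of
  the TSS and the whole-transcript coverage-continuity rule holds; the
  nearest such start wins and defines the 5' UTR (leaderless below
  ``leaderless_cutoff``).
* **i** — the TSS lies strictly inside a same-strand CDS.
* **a** — the TSS lies opposite-strand within a gene's transcript span
  (CDS extended 5' by that gene's longest called UTR and 3' by a fixed
  allowance, since 3' ends are not mapped); sub-classified as
  internal/utr5/utr3 by where it falls.
* **n** — the TSS is outside every CDS on both strands and is not a gTSS
  (a 5' UTR is not a non-coding RNA); nTSSs get the ordinal of their
  intergenic region so mutually antisense sRNA pairs can be read off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import CallerConfig
from .io_formats import Gene
from .tss_calling import MergedTss, TssCall, refine_with_coverage


@dataclass
class TssAnnotation:
    """Category assignment for one (merged) TSS."""

    position: int
    strand: str
    categories: frozenset
    g_gene: Optional[str] = None
    utr_length: Optional[int] = None
    leaderless: bool = False
    i_genes: List[str] = field(default_factory=list)
    a_genes: List[str] = field(default_factory=list)
    a_overlap_class: Dict[str, str] = field(default_factory=dict)
    igr_id: Optional[int] = None


def _downstream_cds_start(position: int, strand: str, genes: Sequence[Gene],
                          max_utr: int) -> Optional[Gene]:
    """Nearest same-strand CDS whose start codon is 0..max_utr downstream."""
    best, best_d = None, None
    for g in genes:
        if g.strand != strand:
            continue
        d = (g.cds_start - position) if strand == "+" \
            else (position - (g.cds_end - 1))
        if 0 <= d <= max_utr and (best_d is None or d < best_d):
            best, best_d = g, d
    return best


def _strictly_inside(position: int, g: Gene) -> bool:
    """Inside the CDS, excluding both terminal bases."""
    return g.cds_start + 1 <= position <= g.cds_end - 2


def classify_tss(position: int, strand: str, genes: Sequence[Gene],
                 gtss_index: Dict[str, List[int]], config: CallerConfig,
                 whole_coverage: Optional[Dict[str, np.ndarray]] = None,
                 igr_lookup=None) -> TssAnnotation:
    """Assign the (non-exclusive) g/i/a/n categories to one TSS.

    ``gtss_index`` maps locus tags to already-assigned gTSS positions and
    is used to extend each gene's transcript span 5' by its longest called
    UTR for antisense classification. When ``whole_coverage`` is given,
    the g assignment additionally requires coverage continuity (first
    ``gap_allow`` nt exempt).
    """
    cats = set()
    g_gene = utr = None
    leaderless = False

    target = _downstream_cds_start(position, strand, genes, config.max_utr)
    if target is not None:
        ok = True
        if whole_coverage is not None:
            probe = TssCall(position, strand, "primary", 0, 0)
            ok = refine_with_coverage(probe, whole_coverage,
                                      target.start_codon_pos, config)
        if ok:
            cats.add("g")
            g_gene = target.locus_tag
            utr = (target.cds_start - position) if strand == "+" \
                else (position - (target.cds_end - 1))
            leaderless = utr < config.leaderless_cutoff

    i_genes = sorted(g.locus_tag for g in genes
                     if g.strand == strand and _strictly_inside(position, g))
    if i_genes:
        cats.add("i")

    a_genes: List[str] = []
    a_class: Dict[str, str] = {}
    for g in genes:
        if g.strand == strand:
            continue
        utr5 = max((abs(p - g.start_codon_pos)
                    for p in gtss_index.get(g.locus_tag, [])), default=0)
        if g.strand == "+":
            span_lo = g.cds_start - utr5
            span_hi = g.cds_end + config.utr3_allowance
        else:
            span_lo = g.cds_start - config.utr3_allowance
            span_hi = g.cds_end + utr5
        if span_lo <= position < span_hi:
            a_genes.append(g.locus_tag)
            if g.cds_start <= position < g.cds_end:
                a_class[g.locus_tag] = "internal"
            elif (g.strand == "+" and position < g.cds_start) or \
                 (g.strand == "-" and position >= g.cds_end):
                a_class[g.locus_tag] = "utr5"
            else:
                a_class[g.locus_tag] = "utr3"
    if a_genes:
        cats.add("a")

    inside_any_cds = any(g.cds_start <= position < g.cds_end for g in genes)
    igr = None
    if not inside_any_cds and "g" not in cats:
        cats.add("n")
        if igr_lookup is not None:
            igr = igr_lookup(position)

    return TssAnnotation(position, strand, frozenset(cats), g_gene, utr,
                         leaderless, i_genes, sorted(a_genes), a_class, igr)


def make_igr_lookup(genes: Sequence[Gene], genome_length: int):
    """Map a position to the ordinal of its intergenic gap (CDS-defined)."""
    ivs = sorted((g.cds_start, g.cds_end) for g in genes)
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    gaps = []
    prev = 0
    for s, e in merged:
        gaps.append((prev, s))
        prev = e
    gaps.append((prev, genome_length))

    def lookup(position: int) -> Optional[int]:
        for k, (s, e) in enumerate(gaps):
            if s <= position < e:
                return k
        return None

    return lookup


def classify_all(merged_calls: Sequence[MergedTss], genes: Sequence[Gene],
                 genome_length: int, config: CallerConfig,
                 whole_coverage: Optional[Dict[str, np.ndarray]] = None
                 ) -> List[TssAnnotation]:
    """Two-pass classification of a merged TSS set.

    Pass 1 assigns gTSSs and UTRs; pass 2 re-classifies with the gTSS
    index populated so antisense spans include each gene's longest called
    5' UTR.
    """
    igr_lookup = make_igr_lookup(genes, genome_length)
    gtss_index: Dict[str, List[int]] = {}
    prelim = [classify_tss(m.position, m.strand, genes, {}, config,
                           whole_coverage) for m in merged_calls]
    for ann in prelim:
        if ann.g_gene is not None:
            gtss_index.setdefault(ann.g_gene, []).append(ann.position)
    return [classify_tss(m.position, m.strand, genes, gtss_index, config,
                         whole_coverage, igr_lookup) for m in merged_calls]


# ---------------------------------------------------------------- summaries

def utr_stats(annotations: Sequence[TssAnnotation],
              leaderless_cutoff: int = 10,
              bins: Sequence[int] = (0, 10, 25, 50, 100, 150, 250, 500)
              ) -> dict:
    """Summarise the 5' UTR length distribution over gTSSs."""
    utrs = np.array([a.utr_length for a in annotations
                     if a.utr_length is not None])
    if utrs.size == 0:
        raise ValueError("no gTSS with a defined UTR")
    edges_in = list(bins) + [max(bins[-1] + 1, int(utrs.max()) + 1)]
    hist, edges = np.histogram(utrs, bins=edges_in)
    return {
        "n": int(utrs.size),
        "median": float(np.median(utrs)),
        "max": int(utrs.max()),
        "leaderless_fraction": float((utrs < leaderless_cutoff).mean()),
        "frac_gt_50": float((utrs > 50).mean()),
        "frac_gt_150": float((utrs > 150).mean()),
        "histogram": {f"[{int(edges[i])},{int(edges[i + 1])})": int(h)
                      for i, h in enumerate(hist)},
    }


def multi_tss_genes(annotations: Sequence[TssAnnotation]
                    ) -> Dict[str, List[int]]:
    """Genes with >= 2 distinct gTSS positions, with their TSS lists."""
    per_gene: Dict[str, set] = {}
    for a in annotations:
        if a.g_gene is not None:
            per_gene.setdefault(a.g_gene, set()).add(a.position)
    return {g: sorted(ps) for g, ps in per_gene.items() if len(ps) >= 2}


def pair_mutual_antisense(annotations: Sequence[TssAnnotation]
                          ) -> List[Tuple[TssAnnotation, TssAnnotation]]:
    """Opposite-strand nTSS pairs sharing an intergenic region."""
    ntss = [a for a in annotations
            if "n" in a.categories and a.igr_id is not None]
    pairs = []
    by_igr: Dict[int, List[TssAnnotation]] = {}
    for a in ntss:
        by_igr.setdefault(a.igr_id, []).append(a)
    for members in by_igr.values():
        plus = [a for a in members if a.strand == "+"]
        minus = [a for a in members if a.strand == "-"]
        pairs.extend((p, m) for p in plus for m in minus)
    return pairs


def annotations_table(annotations: Sequence[TssAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append({
            "position": a.position, "strand": a.strand,
            "categories": "".join(sorted(a.categories)),
            "g_gene": a.g_gene or "", "utr_length": a.utr_length,
            "leaderless": a.leaderless,
            "i_genes": ",".join(a.i_genes), "a_genes": ",".join(a.a_genes),
            "igr_id": a.igr_id,
        })
    return pd.DataFrame(rows)
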