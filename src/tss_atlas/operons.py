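"""Operon candidates and coverage/gTSS-based refinement.

Candidates are maximal runs of same-strand adjacent genes with small
intergenic gaps — a deliberately simple, configurable stand-in for
external operon predictors. Refinement applies two criteria: the first
gene must own a mapped upstream gTSS, and whole-transcript coverage must
be continuous from that gTSS (minus a 5'-terminal allowance) through the
last gene's CDS end. Candidates failing continuity are split at
zero-coverage intergenic gaps and re-evaluated. Internal gTSSs of member
genes mark suboperon starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .config import CallerConfig
from .io_formats import Gene


@dataclass
class Operon:
    """A refined operon (genes in 5'->3' transcription order)."""

    genes: List[Gene]
    strand: str
    lead_gtss: int
    suboperon_starts: List[int] = field(default_factory=list)
    coverage_ok: bool = True

    @property
    def locus_tags(self) -> tuple:
        return tuple(g.locus_tag for g in self.genes)


def candidate_operons(annotation: Sequence[Gene], max_gap: int = 200
                      ) -> List[List[Gene]]:
    """Maximal same-strand runs with intergenic gap <= ``max_gap``.

    Runs are built over the coordinate-sorted annotation; a strand flip or
    an oversized gap breaks the run. Only runs of >= 2 genes are
    candidates.
    """
    runs: List[List[Gene]] = []
    for g in sorted(annotation, key=lambda x: x.cds_start):
        if runs and g.strand == runs[-1][-1].strand \
                and g.cds_start - runs[-1][-1].cds_end <= max_gap:
            runs[-1].append(g)
        else:
            runs.append([g])
    return [r for r in runs if len(r) >= 2]


def _transcription_order(run: Sequence[Gene]) -> List[Gene]:
    run = sorted(run, key=lambda g: g.cds_start)
    return run if run[0].strand == "+" else run[::-1]


def _lead_gtss(run_ordered: Sequence[Gene],
               gtss_by_gene: Dict[str, List[int]]) -> Optional[int]:
    """5'-most gTSS mapped to the transcription-first gene, if any."""
    first = run_ordered[0]
    positions = gtss_by_gene.get(first.locus_tag, [])
    if not positions:
        return None
    return min(positions) if first.strand == "+" else max(positions)


def _continuous(cov: np.ndarray, lo: int, hi: int, min_cov: int) -> bool:
    return bool((cov[max(lo, 0):hi] >= min_cov).all()) if lo < hi else True


def refine_operons(candidates: Sequence[Sequence[Gene]],
                   whole_coverage: Dict[str, np.ndarray],
                   gtss_by_gene: Dict[str, List[int]],
                   config: CallerConfig) -> List[Operon]:
    """Keep candidates meeting the gTSS + coverage-continuity criteria.

    ``gtss_by_gene`` maps locus tags to called gTSS positions. A candidate
    failing continuity is split at zero-coverage intergenic gaps and each
    piece (>= 2 genes) is re-evaluated; splitting is idempotent.
    """
    out: List[Operon] = []
    for cand in candidates:
        out.extend(_refine_one(list(cand), whole_coverage, gtss_by_gene,
                               config))
    return out


def _refine_one(run: List[Gene], whole_coverage, gtss_by_gene,
                config: CallerConfig) -> List[Operon]:
    if len(run) < 2:
        return []
    ordered = _transcription_order(run)
    strand = ordered[0].strand
    cov = whole_coverage[strand]
    lead = _lead_gtss(ordered, gtss_by_gene)

    # continuity holes in intergenic gaps decide splitting regardless of
    # the lead gTSS, so a run with a covered head piece still survives
    coord = sorted(run, key=lambda g: g.cds_start)
    for i in range(len(coord) - 1):
        gap_lo, gap_hi = coord[i].cds_end, coord[i + 1].cds_start
        if not _continuous(cov, gap_lo, gap_hi, config.min_cov):
            left = _refine_one(coord[:i + 1], whole_coverage, gtss_by_gene,
                               config)
            right = _refine_one(coord[i + 1:], whole_coverage, gtss_by_gene,
                                config)
            return left + right

    if lead is None:
        return []
    if strand == "+":
        lo, hi = lead + config.gap_allow, max(g.cds_end for g in run)
    else:
        lo, hi = min(g.cds_start for g in run), lead - config.gap_allow + 1
    if not _continuous(cov, lo, hi, config.min_cov):
        return []
    op = Operon(ordered, strand, lead)
    return [op]


def detect_suboperons(operon: Operon,
                      gtss_by_gene: Dict[str, List[int]]) -> Operon:
    """Record gTSSs of non-first member genes as suboperon starts.

    A TSS that is the gTSS of several member genes is counted once.
    """
    starts: List[int] = []
    for g in operon.genes[1:]:
        for p in gtss_by_gene.get(g.locus_tag, []):
            if p != operon.lead_gtss and p not in starts:
                starts.append(p)
    operon.suboperon_starts = sorted(starts)
    return operon


def audit_operon(operon: Operon, whole_coverage, config: CallerConfig
                 ) -> bool:
    """Self-audit: re-check both refinement criteria on a reported operon."""
    cov = whole_coverage[operon.strand]
    genes = operon.genes
    if operon.strand == "+":
        lo = operon.lead_gtss + config.gap_allow
        hi = max(g.cds_end for g in genes)
    else:
        lo = min(g.cds_start for g in genes)
        hi = operon.lead_gtss - config.gap_allow + 1
    return len(genes) >= 2 and _continuous(cov, lo, hi, config.min_cov)
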