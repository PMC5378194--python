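"""TSS calling from 5'-end library head counts.

The procedure mirrors the published dRNA-seq analysis: mapped reads are
clustered into *contigs* (maximal same-strand groups connected by >= 1 bp
overlap); per contig, the position with the highest (+)-library head count
is the primary TSS if it carries >= ``theta_primary`` reads; further
head-count local maxima with >= ``theta_secondary`` reads become secondary
TSSs. Calls are then refined against whole-transcript coverage: a gene TSS
must show continuous coverage from the TSS to its downstream start codon,
with the first ``gap_allow`` nt (the 5'-terminal under-representation of
conventional RNA-seq) allowed to be missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import CallerConfig
from .io_formats import AlignmentSet


@dataclass
class HeadCountTrack:
    """Per-position, per-strand counts of read 5' ends for one library."""

    library_id: str
    plus: np.ndarray   # head counts on the '+' strand
    minus: np.ndarray  # head counts on the '-' strand

    @property
    def total(self) -> int:
        return int(self.plus.sum() + self.minus.sum())

    def strand(self, s: str) -> np.ndarray:
        return self.plus if s == "+" else self.minus


@dataclass(frozen=True)
class Contig:
    """A maximal same-strand read cluster (>= 1 bp overlap relation)."""

    strand: str
    start: int
    end: int
    n_reads: int


@dataclass
class TssCall:
    """A called transcription start site."""

    position: int
    strand: str
    rank: str                      # "primary" | "secondary"
    head_plus: int
    head_minus: int
    source_contig: Optional[Contig] = None
    refined: Optional[bool] = None
    condition: str = ""


@dataclass
class MergedTss:
    """A non-redundant TSS merged across conditions."""

    position: int
    strand: str
    conditions: Dict[str, TssCall] = field(default_factory=dict)

    @property
    def present_in(self) -> Tuple[str, ...]:
        return tuple(sorted(self.conditions))

    def head_plus(self, condition: str) -> int:
        call = self.conditions.get(condition)
        return 0 if call is None else call.head_plus


def head_counts(alignments: AlignmentSet, genome_length: int,
                reference_id: str = "chr") -> HeadCountTrack:
    """Count read 5' ends per position and strand.

    A '+'-strand read contributes at ``start``; a '-'-strand read at
    ``end - 1``.
    """
    m = alignments.reference_ids == reference_id
    starts, ends = alignments.starts[m], alignments.ends[m]
    strands = alignments.strands[m]
    plus_m = strands == "+"
    plus = np.bincount(starts[plus_m], minlength=genome_length
                       ).astype(np.int64)[:genome_length]
    minus = np.bincount(ends[~plus_m] - 1, minlength=genome_length
                        ).astype(np.int64)[:genome_length]
    return HeadCountTrack(alignments.library.library_id, plus, minus)


def coverage_track(alignments: AlignmentSet, genome_length: int,
                   reference_id: str = "chr") -> Dict[str, np.ndarray]:
    """Strand-specific per-base read coverage (difference-array sweep)."""
    out = {}
    m = alignments.reference_ids == reference_id
    for s in "+-":
        sm = m & (alignments.strands == s)
        diff = np.zeros(genome_length + 1, dtype=np.int64)
        np.add.at(diff, np.clip(alignments.starts[sm], 0, genome_length), 1)
        np.add.at(diff, np.clip(alignments.ends[sm], 0, genome_length), -1)
        out[s] = np.cumsum(diff)[:genome_length]
    return out


def cluster_contigs(alignments: AlignmentSet, strand: Optional[str] = None,
                    reference_id: str = "chr") -> List[Contig]:
    """Maximal connected components of same-strand reads under >= 1 bp
    overlap, sorted by start. Abutting reads (shared boundary, no shared
    base) stay in separate contigs."""
    strands = [strand] if strand else ["+", "-"]
    contigs: List[Contig] = []
    for s in strands:
        m = (alignments.reference_ids == reference_id) & \
            (alignments.strands == s)
        if not m.any():
            continue
        starts, ends = alignments.starts[m], alignments.ends[m]
        order = np.lexsort((ends, starts))
        starts, ends = starts[order], ends[order]
        cur_s, cur_e, n = int(starts[0]), int(ends[0]), 1
        for st, en in zip(starts[1:], ends[1:]):
            if st < cur_e:  # >= 1 shared base
                cur_e = max(cur_e, int(en))
                n += 1
            else:
                contigs.append(Contig(s, cur_s, cur_e, n))
                cur_s, cur_e, n = int(st), int(en), 1
        contigs.append(Contig(s, cur_s, cur_e, n))
    return sorted(contigs, key=lambda c: (c.start, c.strand))


def _fiveprime_key(strand: str):
    """Sort key ranking positions 5'-most first for the given strand."""
    return (lambda p: p) if strand == "+" else (lambda p: -p)


def call_tss(contigs: Sequence[Contig], plus_track: HeadCountTrack,
             minus_track: Optional[HeadCountTrack],
             config: CallerConfig, condition: str = "") -> List[TssCall]:
    """Call primary and secondary TSSs from (+)-library head counts.

    Per contig: the maximum-count position (ties broken 5'-most) is the
    primary TSS iff its count >= ``theta_primary``; without a primary the
    contig yields nothing. Secondary TSSs need >= ``theta_secondary``
    counts, must be head-count local maxima within
    ``+/- local_max_halfwidth`` and >= ``min_tss_spacing`` nt from every
    already-accepted call (greedy, by descending count then 5'-most).
    The optional ``enrichment_ratio`` additionally requires
    ``head_plus >= ratio * head_minus`` at each site.
    """
    if minus_track is not None and plus_track.library_id == minus_track.library_id:
        raise ValueError("plus and minus tracks must come from different "
                         "libraries")
    calls: List[TssCall] = []
    for contig in contigs:
        track = plus_track.strand(contig.strand)
        window = track[contig.start:contig.end]
        if window.size == 0 or window.max() < config.theta_primary:
            continue
        key = _fiveprime_key(contig.strand)
        peak = window.max()
        prim = min((contig.start + i for i in np.flatnonzero(window == peak)),
                   key=key)
        if not _enriched(prim, contig.strand, plus_track, minus_track,
                         config):
            continue
        mtrack = minus_track.strand(contig.strand) if minus_track is not None \
            else None
        calls.append(TssCall(prim, contig.strand, "primary", int(track[prim]),
                             int(mtrack[prim]) if mtrack is not None else 0,
                             contig, condition=condition))
        accepted = [prim]
        cands = [contig.start + i
                 for i in np.flatnonzero(window >= config.theta_secondary)
                 if contig.start + i != prim]
        cands = [p for p in cands
                 if _is_local_max(track, p, contig, config.local_max_halfwidth)]
        cands.sort(key=lambda p: (-track[p], key(p)))
        for p in cands:
            if any(abs(p - q) < config.min_tss_spacing for q in accepted):
                continue
            if not _enriched(p, contig.strand, plus_track, minus_track,
                             config):
                continue
            accepted.append(p)
            calls.append(TssCall(p, contig.strand, "secondary",
                                 int(track[p]),
                                 int(mtrack[p]) if mtrack is not None else 0,
                                 contig, condition=condition))
    return sorted(calls, key=lambda c: (c.position, c.strand))


def _is_local_max(track: np.ndarray, p: int, contig: Contig,
                  halfwidth: int) -> bool:
    lo = max(contig.start, p - halfwidth)
    hi = min(contig.end, p + halfwidth + 1)
    return bool(track[p] >= track[lo:hi].max())


def _enriched(p: int, strand: str, plus_track: HeadCountTrack,
              minus_track: Optional[HeadCountTrack],
              config: CallerConfig) -> bool:
    if config.enrichment_ratio is None or minus_track is None:
        return True
    return plus_track.strand(strand)[p] >= \
        config.enrichment_ratio * minus_track.strand(strand)[p]


def refine_with_coverage(call: TssCall, whole_coverage: Dict[str, np.ndarray],
                         start_codon_pos: Optional[int],
                         config: CallerConfig) -> bool:
    """Apply the whole-transcript coverage-continuity rule.

    A call with a candidate downstream start codon is accepted iff every
    base from the TSS shifted 3' by ``gap_allow`` up to the start codon has
    coverage >= ``min_cov``. Calls without a start codon within ``max_utr``
    pass unrefined (``refined=False``) — they may be nTSS/aTSS/iTSS.
    Refinement never moves the call, it only accepts or rejects it.
    """
    if start_codon_pos is None:
        call.refined = False
        return True
    cov = whole_coverage[call.strand]
    if call.strand == "+":
        lo, hi = call.position + config.gap_allow, start_codon_pos
    else:
        lo, hi = start_codon_pos + 1, call.position - config.gap_allow + 1
    ok = bool((cov[lo:hi] >= config.min_cov).all()) if lo < hi else True
    call.refined = ok
    return ok


def merge_conditions(calls_a: Sequence[TssCall],
                     calls_b: Sequence[TssCall]) -> List[MergedTss]:
    """Unify calls at identical (position, strand) across two conditions,
    keeping per-condition presence and counts."""
    merged: Dict[Tuple[int, str], MergedTss] = {}
    for call in list(calls_a) + list(calls_b):
        site = merged.setdefault((call.position, call.strand),
                                 MergedTss(call.position, call.strand))
        site.conditions[call.condition] = call
    return [merged[k] for k in sorted(merged)]
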