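"""HRPM/RPKM quantification, spike-in QC, fold changes, TSS switching.

HRPM (head reads per million mapped reads) sums 5'-end counts over a
50-nt window downstream of a TSS and scales by library size; RPKM is the
usual reads per kilobase of region per million mapped reads. Differential
TSS usage ("switching") follows the relative usage of each gTSS of a
multi-TSS gene between two conditions; condition-responsive sRNAs are
binned by thresholded fold change (no replicate-aware testing is applied —
an explicit extension point).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .config import CallerConfig
from .io_formats import AlignmentSet, Gene
from .tss_calling import HeadCountTrack


@dataclass
class TssQuant:
    """HRPM of one TSS in one library."""

    position: int
    strand: str
    library_id: str
    head_window_sum: int
    hrpm: float


@dataclass
class GeneQuant:
    """RPKM of one gene in one library."""

    locus_tag: str
    library_id: str
    count: int
    rpkm: float


@dataclass
class SpikeInQC:
    """log2-scale Pearson correlation of RPKM vs known concentration."""

    r: float
    n_used: int
    pvalue: float


@dataclass
class DiffRecord:
    """Per-feature differential summary between two conditions."""

    feature: str
    hrpm: Dict[str, float]
    fold_change: float
    category: str = "none"            # for sRNAs: up / down / none
    usage: Dict[str, Dict[int, float]] = field(default_factory=dict)
    switch: Optional[bool] = None


def hrpm(position: int, strand: str, head_track: HeadCountTrack,
         total_mapped: int, config: CallerConfig) -> TssQuant:
    """Head reads per million over the 50-nt window downstream of a TSS.

    The window starts at the TSS itself and extends ``hrpm_window``
    positions in the direction of transcription.
    """
    if total_mapped <= 0:
        raise ValueError("library has no mapped reads (M = 0)")
    track = head_track.strand(strand)
    w = config.hrpm_window
    if strand == "+":
        H = int(track[position:position + w].sum())
    else:
        H = int(track[max(0, position - w + 1):position + 1].sum())
    return TssQuant(position, strand, head_track.library_id, H,
                    H / (total_mapped / 1e6))


def rpkm(gene: Gene, alignments: AlignmentSet,
         total_mapped: Optional[int] = None) -> GeneQuant:
    """RPKM from alignments overlapping the CDS (>= 1 bp, same strand)."""
    if gene.length <= 0:
        raise ValueError(f"{gene.locus_tag}: zero-length gene")
    M = total_mapped if total_mapped is not None else len(alignments)
    if M <= 0:
        raise ValueError("library has no mapped reads (M = 0)")
    m = ((alignments.reference_ids == gene.reference_id)
         & (alignments.strands == gene.strand)
         & (alignments.starts < gene.cds_end)
         & (alignments.ends > gene.cds_start))
    count = int(m.sum())
    len_kb = gene.length / 1000.0
    return GeneQuant(gene.locus_tag, alignments.library.library_id, count,
                     count / (len_kb * M / 1e6))


def spike_in_qc(spike_table, gene_quants: Dict[str, float],
                eps: float = 0.0) -> SpikeInQC:
    """Pearson r of log2(concentration) vs log2(RPKM + eps).

    ``spike_table`` needs columns ``spike_id`` and ``concentration``;
    ``gene_quants`` maps spike ids to RPKM. Requires >= 3 usable points
    (with ``eps == 0`` zero-RPKM spikes are unusable) and non-constant
    concentrations.
    """
    conc, expr = [], []
    for _, row in spike_table.iterrows():
        r = gene_quants.get(row["spike_id"])
        if r is None:
            continue
        if r + eps <= 0:
            continue
        conc.append(row["concentration"])
        expr.append(r + eps)
    if len(conc) < 3:
        raise ValueError(f"need >= 3 usable spike-ins, have {len(conc)}")
    conc, expr = np.log2(conc), np.log2(expr)
    if np.allclose(conc, conc[0]):
        raise ValueError("spike-in concentrations are constant")
    r, p = sps.pearsonr(conc, expr)
    return SpikeInQC(float(r), len(conc), float(p))


def fold_change(hrpm_a: float, hrpm_b: float, m_a: int, m_b: int,
                pseudocount: float = 1.0, up_fold: float = 35.0,
                down_fold: float = 4.0, feature: str = "") -> DiffRecord:
    """Thresholded fold change of condition A over condition B.

    The pseudocount is expressed in reads and converted to HRPM units via
    each library's size, so it is depth-aware. sRNA categories follow the
    published bounds: ``up`` at >= ``up_fold`` more in A, ``down`` at
    >= ``down_fold`` less in A.
    """
    pa = pseudocount / (m_a / 1e6) if pseudocount else 0.0
    pb = pseudocount / (m_b / 1e6) if pseudocount else 0.0
    num, den = hrpm_a + pa, hrpm_b + pb
    if den == 0:
        raise ValueError("zero denominator; use a pseudocount")
    fc = num / den
    if fc >= up_fold:
        cat = "up"
    elif fc <= 1.0 / down_fold:
        cat = "down"
    else:
        cat = "none"
    return DiffRecord(feature, {"a": hrpm_a, "b": hrpm_b}, fc, cat)


def detect_switch(gene: str,
                  gtss_quants: Dict[str, Dict[int, float]],
                  min_delta: float = 0.3) -> DiffRecord:
    """Condition-dependent TSS selection for a multi-TSS gene.

    ``gtss_quants`` maps condition -> {tss position: HRPM}. Relative usage
    ``u_i = HRPM_i / sum_j HRPM_j`` is computed per condition; the gene
    switches iff the dominant TSS differs between conditions or any
    usage share moves by >= ``min_delta``. A condition with zero total
    HRPM leaves the call undefined (``switch=None``).
    """
    conditions = sorted(gtss_quants)
    if len(conditions) != 2:
        raise ValueError("exactly two conditions required")
    positions = sorted({p for c in conditions for p in gtss_quants[c]})
    if len(positions) < 2:
        raise ValueError(f"{gene}: needs >= 2 gTSSs")
    usage: Dict[str, Dict[int, float]] = {}
    undefined = False
    for c in conditions:
        vals = np.array([gtss_quants[c].get(p, 0.0) for p in positions])
        tot = vals.sum()
        if tot <= 0:
            undefined = True
            usage[c] = {p: float("nan") for p in positions}
        else:
            usage[c] = dict(zip(positions, vals / tot))
    rec = DiffRecord(gene, {}, float("nan"), usage=usage)
    if undefined:
        rec.switch = None
        return rec
    ca, cb = conditions
    argmax = {c: max(positions, key=lambda p: (usage[c][p], -p))
              for c in conditions}
    delta = max(abs(usage[ca][p] - usage[cb][p]) for p in positions)
    rec.switch = bool(argmax[ca] != argmax[cb] or delta >= min_delta)
    return rec
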