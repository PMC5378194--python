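"""End-to-end drivers: simulate -> call -> classify -> quantify -> operons.

These functions are the programmatic equivalent of the numbered analysis
scripts and are what the test suite and the acceptance script exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import CallerConfig
from .io_formats import AlignmentSet, Gene
from .operons import (Operon, candidate_operons, detect_suboperons,
                      refine_operons)
from .promoter_scan import extract_upstream, motif_position_summary
from .quantify import DiffRecord, detect_switch, fold_change, hrpm, rpkm, \
    spike_in_qc
from .synthetic import CHROM, Simulation, SimulationParams, simulate
from .tss_calling import (HeadCountTrack, MergedTss, TssCall, call_tss,
                          cluster_contigs, coverage_track, head_counts,
                          merge_conditions, refine_with_coverage)
from .tss_classify import (TssAnnotation, classify_all, multi_tss_genes,
                           utr_stats)


@dataclass
class ConditionCalls:
    condition: str
    calls: List[TssCall]
    plus_track: HeadCountTrack
    minus_track: HeadCountTrack
    whole_coverage: Dict[str, np.ndarray]


def call_condition(libs, genes: Sequence[Gene], genome_length: int,
                   condition: str, config: CallerConfig) -> ConditionCalls:
    """TSS calling + coverage refinement for one condition's libraries.

    ``libs`` maps (kind, condition) to an :class:`AlignmentSet`. Every
    call is checked against the continuity rule towards its nearest
    downstream same-strand start codon (within ``max_utr``) and the
    outcome recorded in ``call.refined``; the call itself is kept either
    way — a failed link only means the site cannot be the gene TSS of
    that ORF (classification re-applies the rule), it may still be an
    nTSS/aTSS/iTSS.
    """
    plus = libs[("plus", condition)]
    minus = libs[("minus", condition)]
    whole = libs[("whole", condition)]
    plus_track = head_counts(plus, genome_length)
    minus_track = head_counts(minus, genome_length)
    cov = coverage_track(whole, genome_length)
    contigs = cluster_contigs(plus)
    calls = call_tss(contigs, plus_track, minus_track, config,
                     condition=condition)
    for call in calls:
        target = _nearest_start(call, genes, config.max_utr)
        codon = None if target is None else target.start_codon_pos
        refine_with_coverage(call, cov, codon, config)
    return ConditionCalls(condition, calls, plus_track, minus_track, cov)


def _nearest_start(call: TssCall, genes: Sequence[Gene], max_utr: int
                   ) -> Optional[Gene]:
    best, best_d = None, None
    for g in genes:
        if g.strand != call.strand:
            continue
        d = (g.cds_start - call.position) if call.strand == "+" \
            else (call.position - (g.cds_end - 1))
        if 0 <= d <= max_utr and (best_d is None or d < best_d):
            best, best_d = g, d
    return best


@dataclass
class PipelineResult:
    """Everything the analysis computes from one simulated dataset."""

    sim: Simulation
    config: CallerConfig
    per_condition: Dict[str, ConditionCalls]
    merged: List[MergedTss]
    annotations: List[TssAnnotation]
    pooled_coverage: Dict[str, np.ndarray]
    hrpm_by_condition: Dict[str, Dict[Tuple[int, str], float]]
    switch_records: Dict[str, DiffRecord]
    srna_diff: Dict[Tuple[int, str], DiffRecord]
    operons: List[Operon]

    @property
    def gtss_by_gene(self) -> Dict[str, List[int]]:
        out: Dict[str, List[int]] = {}
        for a in self.annotations:
            if a.g_gene is not None:
                out.setdefault(a.g_gene, []).append(a.position)
        return out


def run_pipeline(params: SimulationParams,
                 config: Optional[CallerConfig] = None,
                 sim: Optional[Simulation] = None) -> PipelineResult:
    """Simulate a dataset (unless given) and run the full analysis."""
    config = config or CallerConfig()
    sim = sim or simulate(params)
    genome_length = len(sim.genome[CHROM])
    libs = sim.libraries.libs
    cond_a, cond_b = params.conditions

    per_condition = {c: call_condition(libs, sim.genes, genome_length, c,
                                       config)
                     for c in params.conditions}
    merged = merge_conditions(per_condition[cond_a].calls,
                              per_condition[cond_b].calls)
    pooled = {s: per_condition[cond_a].whole_coverage[s]
              + per_condition[cond_b].whole_coverage[s] for s in "+-"}
    annotations = classify_all(merged, sim.genes, genome_length, config,
                               whole_coverage=pooled)

    # HRPM per condition at every merged site
    hrpm_by_condition: Dict[str, Dict[Tuple[int, str], float]] = {}
    for c in params.conditions:
        cc = per_condition[c]
        M = cc.plus_track.total
        hrpm_by_condition[c] = {
            (m.position, m.strand): hrpm(m.position, m.strand,
                                         cc.plus_track, M, config).hrpm
            for m in merged}

    # switch detection over multi-TSS genes
    switch_records: Dict[str, DiffRecord] = {}
    for gene, positions in multi_tss_genes(annotations).items():
        strand = next(a.strand for a in annotations
                      if a.g_gene == gene)
        quants = {c: {p: hrpm_by_condition[c][(p, strand)]
                      for p in positions} for c in params.conditions}
        switch_records[gene] = detect_switch(gene, quants)

    # sRNA (nTSS) differential expression, cold (cond_a) vs warm (cond_b)
    srna_diff: Dict[Tuple[int, str], DiffRecord] = {}
    m_a = per_condition[cond_a].plus_track.total
    m_b = per_condition[cond_b].plus_track.total
    for a in annotations:
        if "n" not in a.categories:
            continue
        key = (a.position, a.strand)
        srna_diff[key] = fold_change(
            hrpm_by_condition[cond_a][key], hrpm_by_condition[cond_b][key],
            m_a, m_b, pseudocount=config.pseudocount,
            feature=f"nTSS@{a.position}{a.strand}")

    # operons, refined on the deeper whole-transcript library
    whole_sizes = {c: len(libs[("whole", c)]) for c in params.conditions}
    best_c = max(whole_sizes, key=whole_sizes.get)
    gtss_by_gene: Dict[str, List[int]] = {}
    for a in annotations:
        if a.g_gene is not None:
            gtss_by_gene.setdefault(a.g_gene, []).append(a.position)
    cands = candidate_operons(sim.genes)
    ops = refine_operons(cands, per_condition[best_c].whole_coverage,
                         gtss_by_gene, config)
    ops = [detect_suboperons(op, gtss_by_gene) for op in ops]

    return PipelineResult(sim, config, per_condition, merged, annotations,
                          pooled, hrpm_by_condition, switch_records,
                          srna_diff, ops)


def promoter_summary(result: PipelineResult, pattern: str = "TTTAWA",
                     width: int = 50) -> dict:
    """Motif positioning over all merged TSSs of a pipeline run."""
    genome = result.sim.genome[CHROM]
    regions = [extract_upstream(m.position, m.strand, genome, width)
               for m in result.merged]
    return motif_position_summary(regions, pattern)


def spike_qc_for_condition(result: PipelineResult, condition: str):
    """Spike-in RPKM vs concentration QC from the (w) library."""
    aln = result.sim.libraries.libs[("whole", condition)]
    table = result.sim.libraries.spike_table
    quants = {}
    for _, row in table.iterrows():
        g = Gene(row["spike_id"], row["spike_id"], 0, int(row["length"]),
                 "+")
        quants[row["spike_id"]] = rpkm(g, aln, len(aln)).rpkm
    return spike_in_qc(table, quants)


# ------------------------------------------------------ recovery metrics

def recovery_metrics(result: PipelineResult) -> dict:
    """Compare called TSSs with the simulator's planted truth."""
    truth_pos = {(u.tss_position, u.strand) for u in result.sim.truth
                 if u.unit_kind != "spikein"}
    called = {(m.position, m.strand) for m in result.merged}
    recovered = truth_pos & called
    spurious = called - truth_pos
    return {
        "n_truth": len(truth_pos),
        "n_called": len(called),
        "recovery": len(recovered) / len(truth_pos) if truth_pos else 1.0,
        "spurious_fraction": len(spurious) / len(called) if called else 0.0,
    }
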