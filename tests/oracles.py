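"""Brute-force reference implementations used only by the test suite.

These re-derive TSS calls and category assignments from first principles
(pairwise overlap graphs, per-position scans, per-base loops) with none of
the package's vectorised machinery, so agreement is a genuine two-route
check. Only usable at toy scale (genomes of a few kb).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from tss_atlas.config import CallerConfig
from tss_atlas.io_formats import Gene, ReadAlignment


def oracle_call_tss(reads: Sequence[ReadAlignment], genome_length: int,
                    config: CallerConfig,
                    minus_heads: Optional[Dict[Tuple[int, str], int]] = None
                    ) -> List[Tuple[int, str, str]]:
    """Literal re-derivation of TSS calls: (position, strand, rank) tuples.

    Contigs are connected components of the pairwise >= 1 bp overlap graph
    (networkx); head counts are dict tallies; the primary/secondary rules
    are applied position by position.
    """
    heads: Dict[Tuple[int, str], int] = {}
    for r in reads:
        h = r.start if r.strand == "+" else r.end - 1
        heads[(h, r.strand)] = heads.get((h, r.strand), 0) + 1

    calls: List[Tuple[int, str, str]] = []
    for strand in "+-":
        sreads = [r for r in reads if r.strand == strand]
        g = nx.Graph()
        g.add_nodes_from(range(len(sreads)))
        for i in range(len(sreads)):
            for j in range(i + 1, len(sreads)):
                a, b = sreads[i], sreads[j]
                if a.start < b.end and b.start < a.end:
                    g.add_edge(i, j)
        for comp in nx.connected_components(g):
            members = [sreads[i] for i in comp]
            lo = min(r.start for r in members)
            hi = max(r.end for r in members)
            positions = [p for p in range(lo, hi)
                         if heads.get((p, strand), 0) > 0]
            if not positions:
                continue
            peak = max(heads[(p, strand)] for p in positions)
            if peak < config.theta_primary:
                continue
            peak_pos = [p for p in positions if heads[(p, strand)] == peak]
            prim = min(peak_pos) if strand == "+" else max(peak_pos)
            if not _oracle_enriched(prim, strand, heads, minus_heads, config):
                continue
            accepted = [prim]
            calls.append((prim, strand, "primary"))
            cands = []
            for p in positions:
                if p == prim:
                    continue
                c = heads[(p, strand)]
                if c < config.theta_secondary:
                    continue
                local_ok = True
                for q in range(p - config.local_max_halfwidth,
                               p + config.local_max_halfwidth + 1):
                    if lo <= q < hi and heads.get((q, strand), 0) > c:
                        local_ok = False
                if local_ok:
                    cands.append(p)
            cands.sort(key=lambda p: (-heads[(p, strand)],
                                      p if strand == "+" else -p))
            for p in cands:
                if min(abs(p - q) for q in accepted) < config.min_tss_spacing:
                    continue
                if not _oracle_enriched(p, strand, heads, minus_heads,
                                        config):
                    continue
                accepted.append(p)
                calls.append((p, strand, "secondary"))
    return sorted(calls)


def _oracle_enriched(p, strand, heads, minus_heads, config) -> bool:
    if config.enrichment_ratio is None or minus_heads is None:
        return True
    return heads.get((p, strand), 0) >= \
        config.enrichment_ratio * minus_heads.get((p, strand), 0)


def oracle_classify(position: int, strand: str, genes: Sequence[Gene],
                    gtss_index: Dict[str, List[int]], config: CallerConfig,
                    coverage: Optional[Dict[str, Sequence[int]]] = None
                    ) -> dict:
    """Exhaustive per-(TSS, gene) category test, one base at a time."""
    cats = set()
    g_gene = None
    utr = None
    # g: walk downstream base by base until a same-strand start codon
    step = 1 if strand == "+" else -1
    for d in range(0, config.max_utr + 1):
        pos2 = position + step * d
        hit = None
        for g in genes:
            if g.strand == strand and g.start_codon_pos == pos2:
                hit = g
                break
        if hit is None:
            continue
        ok = True
        if coverage is not None:
            cov = coverage[strand]
            q = position + step * config.gap_allow
            # if the codon sits inside the exempt zone nothing is checked
            if (pos2 - q) * step > 0:
                while q != pos2:
                    if 0 <= q < len(cov) and cov[q] < config.min_cov:
                        ok = False
                    q += step
        if ok:
            cats.add("g")
            g_gene, utr = hit.locus_tag, d
        break
    for g in genes:
        if g.strand == strand and g.cds_start + 1 <= position <= g.cds_end - 2:
            cats.add("i")
    for g in genes:
        if g.strand == strand:
            continue
        longest = 0
        for p in gtss_index.get(g.locus_tag, []):
            longest = max(longest, abs(p - g.start_codon_pos))
        if g.strand == "+":
            lo, hi = g.cds_start - longest, g.cds_end + config.utr3_allowance
        else:
            lo, hi = g.cds_start - config.utr3_allowance, g.cds_end + longest
        if lo <= position < hi:
            cats.add("a")
    inside = any(g.cds_start <= position < g.cds_end for g in genes)
    if not inside and "g" not in cats:
        cats.add("n")
    return {"categories": frozenset(cats), "g_gene": g_gene,
            "utr_length": utr}


def oracle_classify_all(sites: Sequence[Tuple[int, str]],
                        genes: Sequence[Gene], config: CallerConfig,
                        coverage=None) -> List[dict]:
    """Two-pass oracle mirroring the production classifier's contract."""
    index: Dict[str, List[int]] = {}
    for pos, strand in sites:
        first = oracle_classify(pos, strand, genes, {}, config, coverage)
        if first["g_gene"] is not None:
            index.setdefault(first["g_gene"], []).append(pos)
    return [oracle_classify(pos, strand, genes, index, config, coverage)
            for pos, strand in sites]
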