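"""Ground-truthed simulator for differential RNA-seq of a small prokaryote.

The generator emulates the data layout of a TEX-based 5'-end sequencing
study of a single-chromosome archaeon grown at two temperatures:

* a toy genome with non-overlapping CDS features, some grouped into
  operons (small intergenic gaps) and the rest standalone;
* planted transcription units with known TSSs: mRNAs (leaderless or with
  log-normal 5' UTRs, a fraction with two alternative TSSs, a fraction of
  those with condition-flipped dominant usage), intergenic sRNAs (some
  strongly cold-induced, some cold-repressed), antisense units inside CDS
  on the opposite strand, and operon transcripts with optional internal
  suboperon TSSs;
* six simulated libraries — TEX-treated (+), untreated (-) and
  whole-transcript (w) at each condition. Head reads of the (-) library
  fall on planted TSSs (weight ``1 - processed_fraction``) and on planted
  processed (5'P) sites; the (+) library re-weights those heads by the TEX
  retention ``e_tex`` for primary 5' ends and the residual ``rho`` for
  processed ends. Whole-transcript fragments tile each unit uniformly but
  never start within the first ``fiveprime_loss`` nt, reproducing the
  5'-terminal under-representation of conventional RNA-seq;
* spike-in reference records on a 2-fold concentration ladder whose
  whole-library counts are Poisson around proportionality.

Everything is deterministic under ``SimulationParams.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import AlignmentSet, Gene, Library, write_fasta, write_gff3

CHROM = "chr"
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimulationParams:
    """Study-condition knobs of the simulator (lengths in nt)."""

    genome_length: int = 100_000
    n_genes: int = 50
    n_srnas: int = 10
    n_antisense: int = 5
    n_operons: int = 5
    leaderless_fraction: float = 0.16
    utr_len_mean: float = 55.0    #: median of the log-normal UTR length law
    utr_len_sd: float = 1.4       #: sigma of log(UTR length)
    multi_tss_fraction: float = 0.3
    switch_fraction: float = 0.5
    tex_retention: float = 0.9    #: e_tex — P(5'PPP head survives TEX)
    tex_residual: float = 0.05    #: rho — P(5'P head survives TEX)
    processed_fraction: float = 0.3
    depth: int = 4000             #: genome-derived reads per 5'-end library
    whole_depth: Optional[int] = None  #: reads per (w) library; default 5x depth
    read_len: int = 100
    fiveprime_loss: int = 25      #: 5'-terminal nt under-covered in (w)
    n_spikeins: int = 8
    seed: int = 0
    # secondary knobs
    jitter_p: float = 0.0         #: geometric head jitter; 0 disables
    tata_fraction: float = 0.8
    tata_offset: int = 21         #: planted TATA 3'-edge distance from TSS
    srna_up_fraction: float = 0.3
    srna_down_fraction: float = 0.3
    srna_up_fold: float = 100.0
    srna_down_fold: float = 8.0
    spike_depth_frac: float = 0.05
    conditions: Tuple[str, str] = ("8C", "18C")

    def validate(self) -> None:
        if not (0 < self.tex_retention <= 1):
            raise ValueError("tex_retention must be in (0, 1]")
        if not (0 <= self.tex_residual <= self.tex_retention):
            raise ValueError("tex_residual must be in [0, tex_retention]")
        for name in ("leaderless_fraction", "multi_tss_fraction",
                     "switch_fraction", "processed_fraction",
                     "jitter_p", "tata_fraction",
                     "srna_up_fraction", "srna_down_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.srna_up_fraction + self.srna_down_fraction > 1:
            raise ValueError("sRNA up+down fractions exceed 1")
        if min(self.genome_length, self.read_len) <= 0:
            raise ValueError("genome_length and read_len must be positive")
        if self.depth < 0 or self.n_genes < 0 or self.n_srnas < 0 \
                or self.n_antisense < 0 or self.n_operons < 0:
            raise ValueError("counts must be non-negative")
        if self.whole_depth is not None and self.whole_depth < 0:
            raise ValueError("whole_depth must be non-negative")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are supported")

    @property
    def effective_whole_depth(self) -> int:
        """Whole-transcript libraries are sequenced deeper than 5'-end
        ones (coverage continuity needs dense tiling)."""
        return self.whole_depth if self.whole_depth is not None \
            else 5 * self.depth


@dataclass
class TranscriptionUnitTruth:
    """Ground truth for one planted transcription unit."""

    unit_id: str
    unit_kind: str                      # mRNA | sRNA | antisense | spikein
    tss_position: int
    strand: str
    covered_gene_ids: List[str]
    utr_length: Optional[int]
    expression_level: Dict[str, float]  # condition -> relative abundance
    processed_sites: List[int]
    is_switch_gene: bool
    span_start: int                     # transcript genomic extent,
    span_end: int                       # 0-based half-open

    def __post_init__(self):
        if not any(v > 0 for v in self.expression_level.values()):
            raise ValueError(f"{self.unit_id}: no condition with expression")


# layout constants — upstream reserve leaves room for the longest UTR plus
# a promoter window; inter-entity gaps exceed the operon-candidate max_gap
# so candidate operons coincide with planted operons
_UPSTREAM_RESERVE = 545
_DOWNSTREAM_MARGIN = 50
_ENTITY_GAP = (300, 500)
_OPERON_GAP = (20, 80)
_GENE_CODONS = (100, 300)
_SRNA_LEN = (150, 250)
_MAX_UTR = 500
_SPIKE_LEN = 1000


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stream])


def _operon_sizes(params: SimulationParams,
                  rng: np.random.Generator) -> List[int]:
    sizes = []
    genes_left = params.n_genes
    for _ in range(params.n_operons):
        if genes_left < 2:
            break
        size = int(rng.integers(2, 4))
        size = min(size, genes_left)
        sizes.append(size)
        genes_left -= size
    return sizes


def generate_genome(params: SimulationParams
                    ) -> Tuple[Dict[str, str], List[Gene]]:
    """Build the toy genome (plus spike-in records) and its annotation.

    Genes are placed left to right; operon members are separated by small
    gaps (20-80 nt) and distinct transcription entities by large ones
    (300-500 nt), each entity keeping an upstream reserve so any UTR up to
    500 nt plus a promoter fits without touching a neighbour. Start/stop
    codons are written into the random sequence. Raises ``ValueError``
    naming the constraint when the layout does not fit ``genome_length``.
    """
    params.validate()
    rng = _rng(params, 0)
    sizes = _operon_sizes(params, rng)
    n_standalone = params.n_genes - sum(sizes)
    entity_sizes = sizes + [1] * n_standalone
    order = rng.permutation(len(entity_sizes))
    entity_sizes = [entity_sizes[i] for i in order]

    genes: List[Gene] = []
    cursor = int(rng.integers(*_ENTITY_GAP))
    gene_no = 0
    for size in entity_sizes:
        strand = "+" if rng.random() < 0.5 else "-"
        lengths = [int(rng.integers(*_GENE_CODONS)) * 3 for _ in range(size)]
        gaps = [int(rng.integers(*_OPERON_GAP)) for _ in range(size - 1)]
        span = sum(lengths) + sum(gaps)
        block = _UPSTREAM_RESERVE + span + _DOWNSTREAM_MARGIN
        b0, b1 = cursor, cursor + block
        if b1 > params.genome_length:
            raise ValueError(
                "genome_length too small to place all transcription units "
                f"without CDS overlap (needs > {b1} nt)")
        # forward-frame layout, then mirror for '-' entities
        ivs = []
        x = b0 + _UPSTREAM_RESERVE
        for L, g in zip(lengths, gaps + [0]):
            ivs.append((x, x + L))
            x += L + g
        if strand == "-":
            ivs = [(b0 + b1 - e, b0 + b1 - s) for s, e in ivs]
            ivs.sort()
        for s, e in ivs:
            gene_no += 1
            genes.append(Gene(f"g{gene_no:04d}", CHROM, s, e, strand,
                              product=f"synthetic protein {gene_no}"))
        cursor = b1 + int(rng.integers(*_ENTITY_GAP))

    seq = rng.choice(list("ACGT"), size=params.genome_length)
    for g in genes:
        if g.strand == "+":
            seq[g.cds_start:g.cds_start + 3] = list("ATG")
            seq[g.cds_end - 3:g.cds_end] = list("TAA")
        else:
            seq[g.cds_end - 3:g.cds_end] = list(revcomp("ATG"))
            seq[g.cds_start:g.cds_start + 3] = list(revcomp("TAA"))
    seqs = {CHROM: "".join(seq)}
    for i in range(params.n_spikeins):
        spike = rng.choice(list("ACGT"), size=_SPIKE_LEN)
        seqs[f"spike{i:02d}"] = "".join(spike)
    return seqs, genes


def spikein_concentrations(params: SimulationParams) -> pd.DataFrame:
    """Known concentrations: a 2-fold ladder in arbitrary attomol units."""
    ids = [f"spike{i:02d}" for i in range(params.n_spikeins)]
    return pd.DataFrame({"spike_id": ids,
                         "concentration": [2.0 ** i for i in range(len(ids))],
                         "length": _SPIKE_LEN})


def _group_entities(genes: Sequence[Gene]) -> List[List[Gene]]:
    """Recover transcription entities (operons/standalone) from gaps."""
    entities: List[List[Gene]] = []
    for g in sorted(genes, key=lambda x: x.cds_start):
        if entities and g.strand == entities[-1][-1].strand \
                and g.cds_start - entities[-1][-1].cds_end <= 100:
            entities[-1].append(g)
        else:
            entities.append([g])
    return entities


def _sample_utr(params, rng) -> int:
    """One non-leaderless UTR length: discretised log-normal in [10, 500]."""
    for _ in range(1000):
        u = int(round(rng.lognormal(np.log(params.utr_len_mean),
                                    params.utr_len_sd)))
        if 10 <= u <= _MAX_UTR:
            return u
    return 55


def _tss_from_utr(entity: List[Gene], utr: int) -> int:
    lead = entity[0] if entity[0].strand == "+" else entity[-1]
    if lead.strand == "+":
        return lead.cds_start - utr
    return lead.cds_end - 1 + utr


def _entity_span(entity: List[Gene], tss: int) -> Tuple[int, int]:
    strand = entity[0].strand
    if strand == "+":
        return tss, max(g.cds_end for g in entity)
    return min(g.cds_start for g in entity), tss + 1


def plant_transcription_units(annotation: Sequence[Gene],
                              params: SimulationParams
                              ) -> List[TranscriptionUnitTruth]:
    """Assign TSSs, UTRs, expression levels and processed sites.

    Every gene entity receives one lead TSS; a ``multi_tss_fraction`` of
    standalone genes get a second, farther TSS (alternative 5' UTR >= 60 nt
    longer), and a ``switch_fraction`` of those flip dominant usage between
    the two conditions (the long-UTR isoform dominating in the cold).
    Operons of >= 3 genes may carry an internal suboperon TSS. sRNAs are
    placed in intergenic gaps and antisense units inside CDSs on the
    opposite strand. Processed (5'P) sites are planted a short way into the
    first covered CDS of each mRNA unit.
    """
    params.validate()
    rng = _rng(params, 1)
    cond_a, cond_b = params.conditions  # cold, warm
    truth: List[TranscriptionUnitTruth] = []

    entities = _group_entities(annotation)
    if params.n_genes and not entities:
        raise ValueError("annotation non-empty required for mRNA units")
    standalone = [e for e in entities if len(e) == 1]
    n_multi = int(round(params.multi_tss_fraction * len(standalone)))
    if n_multi > len(standalone):
        raise ValueError("multi_tss_fraction inconsistent with n_genes")
    multi_idx = set(rng.choice(len(standalone), size=n_multi, replace=False)
                    ) if n_multi else set()
    multi_entities = [standalone[i] for i in sorted(multi_idx)]
    switch_mask = rng.random(len(multi_entities)) < params.switch_fraction

    def expr_pair():
        return {cond_a: float(np.exp(rng.uniform(np.log(0.5), np.log(2.0)))),
                cond_b: float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))}

    def processed(entity, tss, utr):
        first = entity[0] if entity[0].strand == "+" else entity[-1]
        off = int(rng.integers(10, 51))  # inside the first CDS
        if first.strand == "+":
            return [first.cds_start + off]
        return [first.cds_end - 1 - off]

    multi_lookup = {id(e): k for k, e in enumerate(multi_entities)}
    for ei, entity in enumerate(entities):
        strand = entity[0].strand
        order = entity if strand == "+" else entity[::-1]
        covered = [g.locus_tag for g in order]
        gene_expr = expr_pair()
        uid = f"u{ei:04d}"
        k = multi_lookup.get(id(entity))
        if k is None:
            leaderless = rng.random() < params.leaderless_fraction
            utr = int(rng.integers(0, 10)) if leaderless \
                else _sample_utr(params, rng)
            tss = _tss_from_utr(entity, utr)
            lo, hi = _entity_span(entity, tss)
            truth.append(TranscriptionUnitTruth(
                f"{uid}.tss1", "mRNA", tss, strand, covered, utr,
                gene_expr, processed(entity, tss, utr), False, lo, hi))
        else:
            # two alternative TSSs with well-separated UTRs
            utr_short = int(rng.integers(0, 10)) \
                if rng.random() < params.leaderless_fraction \
                else min(_sample_utr(params, rng), 240)
            utr_long = min(utr_short + 60 + _sample_utr(params, rng),
                           _MAX_UTR)
            is_switch = bool(switch_mask[k])
            if is_switch:
                usage = {"short": {cond_a: 0.2, cond_b: 0.8},
                         "long": {cond_a: 0.8, cond_b: 0.2}}
            else:
                usage = {"short": {cond_a: 0.7, cond_b: 0.7},
                         "long": {cond_a: 0.3, cond_b: 0.3}}
            for tag, utr in (("short", utr_short), ("long", utr_long)):
                tss = _tss_from_utr(entity, utr)
                lo, hi = _entity_span(entity, tss)
                expr = {c: gene_expr[c] * usage[tag][c]
                        for c in params.conditions}
                truth.append(TranscriptionUnitTruth(
                    f"{uid}.{tag}", "mRNA", tss, strand, covered, utr,
                    expr, processed(entity, tss, utr), is_switch, lo, hi))
        # suboperon TSS for larger operons
        if len(entity) >= 3 and rng.random() < 0.5:
            j = int(rng.integers(1, len(order)))
            member = order[j]
            utr_i = int(rng.integers(10, 61))
            sub_entity = order[j:] if strand == "+" else order[j:][::-1]
            tss = _tss_from_utr(sub_entity, utr_i)
            lo, hi = _entity_span(sub_entity, tss)
            truth.append(TranscriptionUnitTruth(
                f"{uid}.sub{j}", "mRNA", tss, strand,
                [g.locus_tag for g in order[j:]], utr_i,
                {c: 0.5 * v for c, v in expr_pair().items()},
                [], False, lo, hi))

    # --- sRNAs in intergenic gaps -------------------------------------
    # usable window per gap avoids the 5' UTR zone of any flanking gene
    # whose start codon faces the gap, so an sRNA can never show coverage
    # continuity into a neighbouring ORF (it must stay an nTSS)
    mrna_tss = [u for u in truth if u.unit_kind == "mRNA"]
    by_first_gene: Dict[str, List[int]] = {}
    for u in mrna_tss:
        if u.covered_gene_ids:
            by_first_gene.setdefault(u.covered_gene_ids[0], []).append(
                u.tss_position)
    sorted_genes = sorted(annotation, key=lambda g: g.cds_start)
    windows = []
    for g1, g2 in zip(sorted_genes, sorted_genes[1:]):
        lo_u, hi_u = g1.cds_end + 55, g2.cds_start - 55
        if g1.strand == "-" and g1.locus_tag in by_first_gene:
            lo_u = max(lo_u, max(by_first_gene[g1.locus_tag]) + 40)
        if g2.strand == "+" and g2.locus_tag in by_first_gene:
            hi_u = min(hi_u, min(by_first_gene[g2.locus_tag]) - 40)
        if hi_u - lo_u >= _SRNA_LEN[1] + 10:
            windows.append((lo_u, hi_u))
    n_pairs = min(2, params.n_srnas // 2) if params.n_srnas >= 4 else 0
    slots_needed = params.n_srnas - n_pairs
    if params.n_srnas and slots_needed > len(windows):
        raise ValueError(
            "not enough intergenic space for the requested sRNAs "
            f"(need {slots_needed} usable IGR windows, have {len(windows)})")
    slot_idx = rng.choice(len(windows), size=slots_needed, replace=False) \
        if slots_needed else np.array([], dtype=int)
    n_up = int(round(params.srna_up_fraction * params.n_srnas))
    n_down = int(round(params.srna_down_fraction * params.n_srnas))
    kinds = (["up"] * n_up + ["down"] * n_down
             + ["flat"] * (params.n_srnas - n_up - n_down))
    placed = 0
    for si, slot in enumerate(slot_idx):
        lo_g, hi_g = windows[slot]
        pair = si < n_pairs
        first_plus = rng.random() < 0.5
        for sub in range(2 if pair else 1):
            if placed >= params.n_srnas:
                break
            length = int(rng.integers(*_SRNA_LEN))
            strand = ("+" if first_plus else "-") if sub == 0 \
                else ("-" if first_plus else "+")
            right = hi_g - length
            pos = int(rng.integers(lo_g, max(lo_g + 1, right)))
            lo, hi = pos, pos + length
            tss = lo if strand == "+" else hi - 1
            kind = kinds[placed]
            if kind == "up":
                base = float(np.exp(rng.uniform(np.log(2.0), np.log(4.0))))
                expr = {cond_a: base, cond_b: base / params.srna_up_fold}
            elif kind == "down":
                base = float(np.exp(rng.uniform(np.log(1.0), np.log(2.0))))
                expr = {cond_a: base / params.srna_down_fold, cond_b: base}
            else:
                expr = expr_pair()
            truth.append(TranscriptionUnitTruth(
                f"s{placed:03d}", "sRNA", tss, strand, [], None,
                expr, [], False, lo, hi))
            placed += 1

    # --- antisense units inside CDSs ----------------------------------
    if params.n_antisense:
        wide = [g for g in annotation if g.length >= 450]
        if len(wide) < params.n_antisense:
            raise ValueError("not enough genes >= 450 nt to host antisense "
                             "units")
        hosts = rng.choice(len(wide), size=params.n_antisense, replace=False)
        for ai, hi_idx in enumerate(hosts):
            host = wide[hi_idx]
            strand = "-" if host.strand == "+" else "+"
            length = int(rng.integers(*_SRNA_LEN))
            # TSS at least 60 nt inside the host CDS
            if strand == "-":
                tss = int(rng.integers(host.cds_start + 60 + length,
                                       host.cds_end - 60))
                lo, hi = tss - length + 1, tss + 1
            else:
                tss = int(rng.integers(host.cds_start + 60,
                                       host.cds_end - 60 - length))
                lo, hi = tss, tss + length
            truth.append(TranscriptionUnitTruth(
                f"a{ai:03d}", "antisense", tss, strand, [host.locus_tag],
                None, expr_pair(), [], False, lo, hi))
    return truth


def plant_promoter_motifs(genome: Dict[str, str],
                          truth: Sequence[TranscriptionUnitTruth],
                          params: SimulationParams) -> Dict[str, str]:
    """Write a TATA box (TTTATA) upstream of a fraction of planted TSSs.

    The motif's 3' edge sits ``tata_offset`` nt upstream of the TSS on the
    TSS strand. Returns a new genome dict; input is not modified.
    """
    rng = _rng(params, 2)
    seq = list(genome[CHROM])
    motif = "TTTATA"
    for unit in truth:
        if rng.random() >= params.tata_fraction:
            continue
        if unit.strand == "+":
            start = unit.tss_position - params.tata_offset - len(motif) + 1
            if start < 0:
                continue
            seq[start:start + len(motif)] = list(motif)
        else:
            start = unit.tss_position + params.tata_offset
            if start + len(motif) > len(seq):
                continue
            seq[start:start + len(motif)] = list(revcomp(motif))
    out = dict(genome)
    out[CHROM] = "".join(seq)
    return out


# --------------------------------------------------------------- libraries

@dataclass
class SimulatedLibraries:
    """The six simulated libraries plus spike-in bookkeeping."""

    libs: Dict[Tuple[str, str], AlignmentSet]  # (kind, condition) -> set
    spike_table: pd.DataFrame

    def stats(self) -> pd.DataFrame:
        rows = []
        for (kind, cond), aln in sorted(self.libs.items()):
            genomic = int((aln.reference_ids == CHROM).sum())
            rows.append({"library_id": aln.library.library_id,
                         "kind": kind, "condition": cond,
                         "total_mapped": len(aln),
                         "genomic_reads": genomic})
        return pd.DataFrame(rows)


def _head_sites(truth, params, condition):
    """Site table: position, strand, unit index, (-) and (+) weights."""
    pos, strand, unit_ix, w_minus, w_plus = [], [], [], [], []
    pf = params.processed_fraction
    for ui, unit in enumerate(truth):
        expr = unit.expression_level.get(condition, 0.0)
        if expr <= 0:
            continue
        k = len(unit.processed_sites)
        tss_share = (1 - pf) if k else 1.0
        pos.append(unit.tss_position)
        strand.append(unit.strand)
        unit_ix.append(ui)
        w_minus.append(expr * tss_share)
        w_plus.append(expr * tss_share * params.tex_retention)
        for p in unit.processed_sites:
            pos.append(p)
            strand.append(unit.strand)
            unit_ix.append(ui)
            w_minus.append(expr * pf / k)
            w_plus.append(expr * pf / k * params.tex_residual)
    return (np.array(pos, dtype=np.int64), np.array(strand, dtype=object),
            np.array(unit_ix, dtype=np.int64),
            np.array(w_minus), np.array(w_plus))


def simulate_libraries(truth: Sequence[TranscriptionUnitTruth],
                       genome: Dict[str, str],
                       params: SimulationParams) -> SimulatedLibraries:
    """Draw the (+)/(-)/(w) libraries for both conditions.

    Each library carries exactly ``depth`` genome-derived alignments
    (multinomial over sites/units weighted by per-condition expression);
    whole-transcript libraries additionally carry Poisson spike-in reads
    proportional to the concentration ladder.
    """
    params.validate()
    rng = _rng(params, 3)
    glen = len(genome[CHROM])
    spikes = spikein_concentrations(params)
    libs: Dict[Tuple[str, str], AlignmentSet] = {}

    spans_lo = np.array([u.span_start for u in truth], dtype=np.int64)
    spans_hi = np.array([u.span_end for u in truth], dtype=np.int64)

    for cond in params.conditions:
        pos, strand, unit_ix, w_minus, w_plus = _head_sites(
            truth, params, cond)

        for kind, weights in (("minus", w_minus), ("plus", w_plus)):
            lib = Library(f"{kind}_{cond}", cond, kind)
            if params.depth == 0 or weights.sum() == 0:
                libs[(kind, cond)] = AlignmentSet(lib, [], [], [], [])
                continue
            counts = rng.multinomial(params.depth, weights / weights.sum())
            heads = np.repeat(pos, counts)
            hstr = np.repeat(strand, counts)
            hunit = np.repeat(unit_ix, counts)
            if params.jitter_p > 0:
                shift = rng.geometric(params.jitter_p, size=len(heads)) - 1
                heads = np.where(hstr == "+", heads + shift, heads - shift)
                heads = np.clip(heads, spans_lo[hunit], spans_hi[hunit] - 1)
            plus_m = hstr == "+"
            starts = np.where(plus_m, heads,
                              np.maximum(heads - params.read_len + 1,
                                         spans_lo[hunit]))
            ends = np.where(plus_m,
                            np.minimum(heads + params.read_len,
                                       spans_hi[hunit]),
                            heads + 1)
            libs[(kind, cond)] = AlignmentSet(
                lib, np.full(len(heads), CHROM, dtype=object),
                starts, ends, hstr)

        # whole-transcript library
        lib = Library(f"whole_{cond}", cond, "whole")
        expr = np.array([u.expression_level.get(cond, 0.0) for u in truth])
        lens = spans_hi - spans_lo
        uw = expr * lens
        refs, starts, ends, strands = [], [], [], []
        wdepth = params.effective_whole_depth
        if wdepth > 0 and uw.sum() > 0:
            counts = rng.multinomial(wdepth, uw / uw.sum())
            for ui, cnt in enumerate(counts):
                if cnt == 0:
                    continue
                u = truth[ui]
                L = int(lens[ui])
                s_lo = min(params.fiveprime_loss, max(0, L - params.read_len))
                s_hi = max(s_lo, L - params.read_len)
                # half-read-length tiling over [s_lo, s_hi]; surplus reads
                # land on random tiles. Coverage of the zone beyond the 5'
                # loss is gapless whenever cnt >= number of tiles.
                tiles = np.unique(np.append(
                    np.arange(s_lo, s_hi, max(1, params.read_len // 2)),
                    s_hi))
                reps = np.full(len(tiles), cnt // len(tiles))
                extra = cnt - int(reps.sum())
                if extra:
                    reps += np.bincount(
                        rng.integers(0, len(tiles), size=extra),
                        minlength=len(tiles))
                offs = np.repeat(tiles, reps)
                fr_end = np.minimum(offs + params.read_len, L)
                if u.strand == "+":
                    gs = u.span_start + offs
                    ge = u.span_start + fr_end
                else:
                    gs = u.span_end - fr_end
                    ge = u.span_end - offs
                refs.append(np.full(cnt, CHROM, dtype=object))
                starts.append(gs)
                ends.append(ge)
                strands.append(np.full(cnt, u.strand, dtype=object))
        # spike-ins (Poisson around proportionality)
        if params.n_spikeins and wdepth > 0:
            conc = spikes["concentration"].to_numpy()
            lam = wdepth * params.spike_depth_frac * conc / conc.sum()
            for sid, l in zip(spikes["spike_id"], lam):
                cnt = int(rng.poisson(l))
                if cnt == 0:
                    continue
                offs = rng.integers(0, _SPIKE_LEN - params.read_len + 1,
                                    size=cnt)
                refs.append(np.full(cnt, sid, dtype=object))
                starts.append(offs)
                ends.append(offs + params.read_len)
                strands.append(np.full(cnt, "+", dtype=object))
        if refs:
            libs[("whole", cond)] = AlignmentSet(
                lib, np.concatenate(refs), np.concatenate(starts),
                np.concatenate(ends), np.concatenate(strands))
        else:
            libs[("whole", cond)] = AlignmentSet(lib, [], [], [], [])
    return SimulatedLibraries(libs, spikes)


# ------------------------------------------------------------ truth tables

_TRUTH_COLUMNS = ["unit_id", "unit_kind", "tss_position", "strand",
                  "covered_gene_ids", "utr_length", "expression_level",
                  "processed_sites", "is_switch_gene", "span_start",
                  "span_end"]


def write_truth(truth: Sequence[TranscriptionUnitTruth], path) -> None:
    """Serialise truth records to TSV (lossless round-trip)."""
    rows = []
    for u in truth:
        rows.append({
            "unit_id": u.unit_id, "unit_kind": u.unit_kind,
            "tss_position": u.tss_position, "strand": u.strand,
            "covered_gene_ids": ",".join(u.covered_gene_ids),
            "utr_length": "" if u.utr_length is None else u.utr_length,
            "expression_level": json.dumps(u.expression_level,
                                           sort_keys=True),
            "processed_sites": ",".join(map(str, u.processed_sites)),
            "is_switch_gene": int(u.is_switch_gene),
            "span_start": u.span_start, "span_end": u.span_end,
        })
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(path, sep="\t",
                                                      index=False)


def read_truth(path) -> List[TranscriptionUnitTruth]:
    df = pd.read_csv(path, sep="\t", dtype={"covered_gene_ids": str,
                                            "processed_sites": str,
                                            "utr_length": str},
                     keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(TranscriptionUnitTruth(
            r["unit_id"], r["unit_kind"], int(r["tss_position"]),
            r["strand"],
            r["covered_gene_ids"].split(",") if r["covered_gene_ids"] else [],
            None if r["utr_length"] == "" else int(float(r["utr_length"])),
            json.loads(r["expression_level"]),
            [int(x) for x in r["processed_sites"].split(",")
             if x != ""],
            bool(int(r["is_switch_gene"])),
            int(r["span_start"]), int(r["span_end"])))
    return out


# ------------------------------------------------------------- one-shot

@dataclass
class Simulation:
    """Everything one simulator run produces."""

    params: SimulationParams
    genome: Dict[str, str]
    genes: List[Gene]
    truth: List[TranscriptionUnitTruth]
    libraries: SimulatedLibraries


def simulate(params: SimulationParams) -> Simulation:
    """Run the full generator: genome -> units -> promoters -> libraries."""
    genome, genes = generate_genome(params)
    truth = plant_transcription_units(genes, params)
    genome = plant_promoter_motifs(genome, truth, params)
    libraries = simulate_libraries(truth, genome, params)
    return Simulation(params, genome, genes, truth, libraries)


def write_simulation(sim: Simulation, outdir) -> None:
    """Dump a simulation as FASTA/GFF3/BED/TSV files under ``outdir``."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.genome, outdir / "genome.fasta")
    write_gff3(sim.genes, outdir / "annotation.gff3")
    write_truth(sim.truth, outdir / "truth_units.tsv")
    sim.libraries.spike_table.to_csv(outdir / "spikein_concentrations.tsv",
                                     sep="\t", index=False)
    for (kind, cond), aln in sim.libraries.libs.items():
        aln.to_bed(outdir / f"{kind}_{cond}.bed")
    manifest = [{"id": a.library.library_id, "kind": kind,
                 "condition": cond, "path": f"{kind}_{cond}.bed"}
                for (kind, cond), a in sorted(sim.libraries.libs.items())]
    import yaml
    with open(outdir / "libraries.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
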