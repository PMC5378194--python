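import hashlib

import numpy as np
import pytest
from scipy import stats as sps

from tss_atlas.synthetic import (CHROM, SimulationParams, generate_genome,
                                 plant_transcription_units,
                                 plant_promoter_motifs, simulate,
                                 simulate_libraries, write_simulation,
                                 write_truth, read_truth)
from tss_atlas.tss_calling import head_counts


def _tiny(seed=7, **kw):
    base = dict(genome_length=40_000, n_genes=15, n_srnas=4, n_antisense=2,
                n_operons=2, depth=3000, n_spikeins=4, seed=seed)
    base.update(kw)
    return SimulationParams(**base)


# ----------------------------------------------------------- determinism

def test_same_seed_gives_byte_identical_outputs(tmp_path):
    for d in ("a", "b"):
        write_simulation(simulate(_tiny(seed=7)), tmp_path / d)
    for name in ("genome.fasta", "annotation.gff3", "truth_units.tsv",
                 "plus_8C.bed", "whole_18C.bed"):
        ha = hashlib.sha256((tmp_path / "a" / name).read_bytes()).hexdigest()
        hb = hashlib.sha256((tmp_path / "b" / name).read_bytes()).hexdigest()
        assert ha == hb, name


def test_different_seeds_differ():
    ga, _ = generate_genome(_tiny(seed=1))
    gb, _ = generate_genome(_tiny(seed=2))
    assert ga[CHROM] != gb[CHROM]


# -------------------------------------------------------------- genome

def test_zero_genes_gives_empty_annotation_full_length_sequence():
    p = SimulationParams(genome_length=5_000, n_genes=0, n_srnas=0,
                        n_antisense=0, n_operons=0, n_spikeins=0, seed=3)
    seqs, genes = generate_genome(p)
    assert genes == []
    assert len(seqs[CHROM]) == 5_000


def test_cds_features_are_pairwise_nonoverlapping():
    """Brute-force interval sweep over all CDS pairs."""
    p = SimulationParams(n_genes=50, genome_length=100_000, seed=11)
    _, genes = generate_genome(p)
    assert len(genes) == 50
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            assert a.cds_end <= b.cds_start or b.cds_end <= a.cds_start


def test_placement_failure_names_the_constraint():
    with pytest.raises(ValueError, match="genome_length"):
        generate_genome(SimulationParams(genome_length=5_000, n_genes=50))


def test_start_codons_written():
    seqs, genes = generate_genome(_tiny())
    chrom = seqs[CHROM]
    for g in genes:
        if g.strand == "+":
            assert chrom[g.cds_start:g.cds_start + 3] == "ATG"
        else:
            assert chrom[g.cds_end - 3:g.cds_end] == "CAT"


# ---------------------------------------------------------------- truth

def test_leaderless_fraction_one_forces_short_utrs():
    p = _tiny(leaderless_fraction=1.0, multi_tss_fraction=0.0)
    _, genes = generate_genome(p)
    truth = plant_transcription_units(genes, p)
    mrna = [u for u in truth if u.unit_kind == "mRNA" and ".sub" not in u.unit_id]
    assert mrna and all(u.utr_length < 10 for u in mrna)


def test_multi_tss_fraction_zero_gives_single_tss_per_gene():
    p = _tiny(multi_tss_fraction=0.0)
    _, genes = generate_genome(p)
    truth = plant_transcription_units(genes, p)
    lead = {}
    for u in truth:
        if u.unit_kind == "mRNA" and ".sub" not in u.unit_id:
            lead.setdefault(u.covered_gene_ids[0], []).append(u)
    assert all(len(v) == 1 for v in lead.values())


@pytest.mark.parametrize("frac,expect", [(0.0, "none"), (1.0, "all")])
def test_switch_fraction_extremes(frac, expect):
    p = _tiny(multi_tss_fraction=0.5, switch_fraction=frac)
    _, genes = generate_genome(p)
    truth = plant_transcription_units(genes, p)
    multi = [u for u in truth if u.unit_id.endswith((".short", ".long"))]
    assert multi
    flags = {u.is_switch_gene for u in multi}
    assert flags == ({False} if expect == "none" else {True})


def test_tss_upstream_of_first_cds_for_mrna_units():
    p = _tiny()
    _, genes = generate_genome(p)
    by_tag = {g.locus_tag: g for g in genes}
    for u in plant_transcription_units(genes, p):
        if u.unit_kind != "mRNA":
            continue
        first = by_tag[u.covered_gene_ids[0]]
        if u.strand == "+":
            assert u.tss_position <= first.cds_start
        else:
            assert u.tss_position >= first.cds_end - 1


# ------------------------------------------------------------- libraries

def test_library_depth_conservation_without_spikeins():
    p = _tiny(n_spikeins=0)
    sim = simulate(p)
    for (kind, cond), aln in sim.libraries.libs.items():
        expected = p.depth if kind != "whole" else p.effective_whole_depth
        assert len(aln) == expected, (kind, cond)


def test_depth_zero_gives_empty_libraries():
    p = _tiny(depth=0, whole_depth=0, n_spikeins=0)
    sim = simulate(p)
    assert all(len(a) == 0 for a in sim.libraries.libs.values())


def test_zero_tex_residual_protects_processed_sites():
    """With rho=0 no (+) head read may fall on any processed site."""
    p = _tiny(tex_residual=0.0)
    sim = simulate(p)
    processed = {(pos, u.strand) for u in sim.truth
                 for pos in u.processed_sites}
    assert processed
    for cond in p.conditions:
        aln = sim.libraries.libs[("plus", cond)]
        for rec in aln:
            head = rec.start if rec.strand == "+" else rec.end - 1
            assert (head, rec.strand) not in processed


def test_equal_retention_makes_plus_match_minus():
    """With e_tex = rho = 1 the (+) and (-) head distributions agree
    within multinomial sampling error (chi-square on shared sites)."""
    p = _tiny(tex_retention=1.0, tex_residual=1.0, depth=20_000,
              n_spikeins=0)
    sim = simulate(p)
    glen = len(sim.genome[CHROM])
    plus = head_counts(sim.libraries.libs[("plus", "8C")], glen)
    minus = head_counts(sim.libraries.libs[("minus", "8C")], glen)
    a = np.concatenate([plus.plus, plus.minus])
    b = np.concatenate([minus.plus, minus.minus])
    keep = (a + b) >= 10
    table = np.vstack([a[keep], b[keep]])
    _, pval, _, _ = sps.chi2_contingency(table)
    assert pval > 1e-3


def test_minus_head_expectation_at_planted_tss():
    """Observed (-) heads at each planted TSS track the multinomial
    expectation depth * w_unit * (1 - processed_fraction) within sampling
    error, over seeded replicates."""
    from dataclasses import replace
    p = _tiny(n_genes=4, n_srnas=0, n_antisense=0, n_operons=0,
              multi_tss_fraction=0.0, genome_length=20_000, depth=2000,
              n_spikeins=0)
    pf = p.processed_fraction
    for seed in range(12):
        sim = simulate(replace(p, seed=seed))
        u = sim.truth[0]
        aln = sim.libraries.libs[("minus", "8C")]
        heads = np.where(aln.strands == "+", aln.starts, aln.ends - 1)
        obs = int(((heads == u.tss_position)
                   & (aln.strands == u.strand)).sum())
        expected = p.depth * u.expression_level["8C"] * (1 - pf) / \
            sum(x.expression_level["8C"] for x in sim.truth)
        se = np.sqrt(expected)
        assert abs(obs - expected) < 4 * se + 3


def test_whole_library_respects_fiveprime_loss():
    """No whole-transcript fragment may start inside a unit's 5'-loss
    zone: the proximal 5' terminus is under-represented by design.
    (Overlapping isoforms would legitimately cover each other's zones, so
    multi-TSS genes and operons are disabled here.)"""
    p = _tiny(n_spikeins=0, multi_tss_fraction=0.0, n_operons=0)
    sim = simulate(p)
    for cond in p.conditions:
        aln = sim.libraries.libs[("whole", cond)]
        heads = np.where(aln.strands == "+", aln.starts, aln.ends - 1)
        for u in sim.truth:
            L = u.span_end - u.span_start
            loss = min(p.fiveprime_loss, max(0, L - p.read_len))
            if u.strand == "+":
                zone = (aln.strands == "+") & (heads >= u.span_start) & \
                    (heads < u.span_start + loss)
            else:
                zone = (aln.strands == "-") & (heads > u.span_end - 1 - loss) \
                    & (heads <= u.span_end - 1)
            assert not zone.any(), (u.unit_id, cond)


def test_promoter_motif_planted_at_configured_offset():
    p = _tiny(tata_fraction=1.0)
    genome, genes = generate_genome(p)
    truth = plant_transcription_units(genes, p)
    genome = plant_promoter_motifs(genome, truth, p)
    chrom = genome[CHROM]
    hits = 0
    for u in truth:
        if u.strand == "+":
            s = u.tss_position - p.tata_offset - 5
            hits += chrom[s:s + 6] == "TTTATA"
        else:
            s = u.tss_position + p.tata_offset
            hits += chrom[s:s + 6] == "TATAAA"
    assert hits == len(truth)


# ------------------------------------------------------------ truth I/O

def test_truth_table_round_trip(tmp_path):
    p = _tiny()
    sim = simulate(p)
    write_truth(sim.truth, tmp_path / "t.tsv")
    assert read_truth(tmp_path / "t.tsv") == sim.truth


def test_truth_table_empty_and_counts(tmp_path):
    write_truth([], tmp_path / "e.tsv")
    text = (tmp_path / "e.tsv").read_text()
    assert len(text.splitlines()) == 1  # header only
    assert read_truth(tmp_path / "e.tsv") == []
    p = _tiny()
    sim = simulate(p)
    write_truth(sim.truth, tmp_path / "t.tsv")
    assert len((tmp_path / "t.tsv").read_text().splitlines()) \
        == len(sim.truth) + 1


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SimulationParams(tex_retention=0.0).validate()
    with pytest.raises(ValueError):
        SimulationParams(tex_residual=0.95, tex_retention=0.9).validate()
    with pytest.raises(ValueError):
        SimulationParams(leaderless_fraction=1.5).validate()
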