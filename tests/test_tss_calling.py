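import numpy as np
import pytest

from tests.conftest import make_alignment_set, random_read_set
from tests.oracles import oracle_call_tss
from tss_atlas.config import CallerConfig
from tss_atlas.tss_calling import (HeadCountTrack, TssCall, call_tss,
                                   cluster_contigs, coverage_track,
                                   head_counts, merge_conditions,
                                   refine_with_coverage)

GLEN = 2_000


def _track(heads, library_id="plus_8C", glen=GLEN):
    """Head track from {(pos, strand): count}."""
    plus = np.zeros(glen, dtype=np.int64)
    minus = np.zeros(glen, dtype=np.int64)
    for (p, s), c in heads.items():
        (plus if s == "+" else minus)[p] += c
    return HeadCountTrack(library_id, plus, minus)


def _contig(strand, start, end):
    from tss_atlas.tss_calling import Contig
    return Contig(strand, start, end, 0)


# ------------------------------------------------------------ head counts

def test_head_positions_follow_strand_convention():
    aln = make_alignment_set([(99, 199, "+"), (99, 199, "-")])
    track = head_counts(aln, GLEN)
    assert track.plus[99] == 1
    assert track.minus[198] == 1


def test_head_counts_conserve_reads():
    rng = np.random.default_rng(0)
    recs = random_read_set(rng, GLEN)
    track = head_counts(make_alignment_set(recs), GLEN)
    assert track.total == len(recs)


# --------------------------------------------------------------- contigs

def test_one_base_overlap_merges_reads_into_one_contig():
    aln = make_alignment_set([(0, 50, "+"), (49, 100, "+")])
    contigs = cluster_contigs(aln)
    assert [(c.start, c.end) for c in contigs] == [(0, 100)]
    assert contigs[0].n_reads == 2


def test_abutting_reads_stay_in_separate_contigs():
    aln = make_alignment_set([(0, 50, "+"), (50, 100, "+")])
    assert [(c.start, c.end) for c in cluster_contigs(aln)] \
        == [(0, 50), (50, 100)]


def test_strands_cluster_independently():
    aln = make_alignment_set([(0, 50, "+"), (0, 50, "-")])
    contigs = cluster_contigs(aln)
    assert len(contigs) == 2
    assert {c.strand for c in contigs} == {"+", "-"}


# --------------------------------------------------------------- calling

def test_single_peak_at_threshold_yields_primary(config):
    track = _track({(100, "+"): 12})
    calls = call_tss([_contig("+", 80, 160)], track, None, config)
    assert [(c.position, c.rank, c.head_plus) for c in calls] \
        == [(100, "primary", 12)]


def test_peak_below_primary_threshold_yields_nothing(config):
    track = _track({(100, "+"): 9})
    assert call_tss([_contig("+", 80, 160)], track, None, config) == []


def test_secondary_called_next_to_primary(config):
    track = _track({(100, "+"): 20, (140, "+"): 7})
    calls = call_tss([_contig("+", 80, 200)], track, None, config)
    assert [(c.position, c.rank) for c in calls] \
        == [(100, "primary"), (140, "secondary")]


def test_secondary_below_threshold_not_called(config):
    track = _track({(100, "+"): 20, (140, "+"): 4})
    calls = call_tss([_contig("+", 80, 200)], track, None, config)
    assert [(c.position, c.rank) for c in calls] == [(100, "primary")]


@pytest.mark.parametrize("strand,expected", [("+", 100), ("-", 101)])
def test_tie_breaks_to_fiveprime_most(config, strand, expected):
    track = _track({(100, strand): 15, (101, strand): 15})
    calls = call_tss([_contig(strand, 80, 160)], track, None, config)
    assert [c.position for c in calls if c.rank == "primary"] == [expected]


def test_shoulder_within_spacing_suppressed(config):
    """A >= 5-read shoulder 2 nt from the primary is not a separate TSS."""
    track = _track({(100, "+"): 20, (102, "+"): 6, (140, "+"): 6})
    calls = call_tss([_contig("+", 80, 200)], track, None, config)
    assert [c.position for c in calls] == [100, 140]


def test_enrichment_ratio_filter():
    cfg = CallerConfig(enrichment_ratio=2.0)
    plus = _track({(100, "+"): 12}, "plus_8C")
    minus_hi = _track({(100, "+"): 10}, "minus_8C")
    minus_lo = _track({(100, "+"): 3}, "minus_8C")
    assert call_tss([_contig("+", 80, 160)], plus, minus_hi, cfg) == []
    calls = call_tss([_contig("+", 80, 160)], plus, minus_lo, cfg)
    assert len(calls) == 1 and calls[0].head_minus == 3


def test_same_library_for_both_tracks_rejected(config):
    t = _track({(100, "+"): 12})
    with pytest.raises(ValueError):
        call_tss([_contig("+", 80, 160)], t, t, config)


def test_raising_primary_threshold_only_removes_calls():
    rng = np.random.default_rng(42)
    for _ in range(20):
        aln = make_alignment_set(random_read_set(rng, GLEN))
        track = head_counts(aln, GLEN)
        contigs = cluster_contigs(aln)
        loose = {(c.position, c.strand, c.rank)
                 for c in call_tss(contigs, track, None, CallerConfig())}
        strict = {(c.position, c.strand, c.rank)
                  for c in call_tss(contigs, track, None,
                                    CallerConfig(theta_primary=13))}
        assert strict <= loose


# ------------------------------------------------------------- refinement

def _cov(segments, glen=GLEN):
    cov = {"+": np.zeros(glen, dtype=np.int64),
           "-": np.zeros(glen, dtype=np.int64)}
    for s, lo, hi in segments:
        cov[s][lo:hi] += 1
    return cov


def test_refinement_tolerates_missing_fiveprime_terminus(config):
    """Coverage starting 30 nt into the transcript still passes."""
    call = TssCall(100, "+", "primary", 20, 0)
    cov = _cov([("+", 130, 400)])
    assert refine_with_coverage(call, cov, 200, config)
    assert call.refined is True


def test_refinement_rejects_interior_hole(config):
    call = TssCall(100, "+", "primary", 20, 0)
    cov = _cov([("+", 130, 160), ("+", 161, 400)])  # hole at 160
    assert not refine_with_coverage(call, cov, 200, config)
    assert call.refined is False


def test_refinement_minus_strand_mirror(config):
    call = TssCall(400, "-", "primary", 20, 0)
    cov = _cov([("-", 100, 371)])  # covers codon..tss-30
    assert refine_with_coverage(call, cov, 150, config)
    cov2 = _cov([("-", 100, 360)])
    assert not refine_with_coverage(call, cov2, 150, config)


def test_call_without_downstream_orf_passes_unrefined(config):
    call = TssCall(100, "+", "primary", 20, 0)
    assert refine_with_coverage(call, _cov([]), None, config)
    assert call.refined is False


def test_refinement_never_moves_a_call(config):
    call = TssCall(100, "+", "primary", 20, 0)
    refine_with_coverage(call, _cov([("+", 130, 400)]), 200, config)
    assert call.position == 100


# ---------------------------------------------------------------- merging

def test_merge_shared_and_private_sites():
    a = [TssCall(100, "+", "primary", 15, 0, condition="8C"),
         TssCall(300, "+", "primary", 11, 0, condition="8C")]
    b = [TssCall(100, "+", "primary", 22, 0, condition="18C")]
    merged = merge_conditions(a, b)
    assert len(merged) == 2
    shared = next(m for m in merged if m.position == 100)
    assert shared.present_in == ("18C", "8C")
    assert shared.head_plus("8C") == 15 and shared.head_plus("18C") == 22
    private = next(m for m in merged if m.position == 300)
    assert private.present_in == ("8C",)


def test_merge_disjoint_sets_is_union():
    a = [TssCall(i, "+", "primary", 10, 0, condition="8C")
         for i in (10, 20, 30)]
    b = [TssCall(i, "+", "primary", 10, 0, condition="18C")
         for i in (40, 50)]
    assert len(merge_conditions(a, b)) == 5


# ------------------------------------------------------ oracle spot-check

def test_caller_matches_bruteforce_oracle_spot():
    """Production caller vs the literal per-position oracle on a handful
    of random read sets (the full 50-genome sweep runs in acceptance)."""
    rng = np.random.default_rng(3)
    cfg = CallerConfig()
    for _ in range(5):
        recs = random_read_set(rng, GLEN)
        aln = make_alignment_set(recs)
        track = head_counts(aln, GLEN)
        calls = call_tss(cluster_contigs(aln), track, None, cfg)
        got = sorted((c.position, c.strand, c.rank) for c in calls)
        assert got == oracle_call_tss(list(aln), GLEN, cfg)
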