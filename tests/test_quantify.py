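import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tests.conftest import make_alignment_set
from tss_atlas.config import CallerConfig
from tss_atlas.io_formats import Gene
from tss_atlas.quantify import (detect_switch, fold_change, hrpm, rpkm,
                                spike_in_qc)
from tss_atlas.tss_calling import HeadCountTrack

GLEN = 2_000


def _track(heads):
    plus = np.zeros(GLEN, dtype=np.int64)
    minus = np.zeros(GLEN, dtype=np.int64)
    for (p, s), c in heads.items():
        (plus if s == "+" else minus)[p] += c
    return HeadCountTrack("plus_8C", plus, minus)


# -------------------------------------------------------------------- HRPM

def test_hrpm_printed_definition():
    """H=100 head reads in the window, M=2e6 -> HRPM = 50.0."""
    track = _track({(100, "+"): 100})
    q = hrpm(100, "+", track, 2_000_000, CallerConfig())
    assert q.head_window_sum == 100
    assert q.hrpm == 50.0


def test_hrpm_window_boundary():
    """Heads 51 nt downstream fall outside the 50-nt window."""
    cfg = CallerConfig()
    track = _track({(151, "+"): 30})
    assert hrpm(100, "+", track, 1_000_000, cfg).head_window_sum == 0
    track2 = _track({(149, "+"): 30})
    assert hrpm(100, "+", track2, 1_000_000, cfg).head_window_sum == 30


def test_hrpm_minus_strand_window_descends():
    cfg = CallerConfig()
    track = _track({(460, "-"): 10, (411, "-"): 5, (410, "-"): 7})
    q = hrpm(460, "-", track, 1_000_000, cfg)
    assert q.head_window_sum == 15  # 460 and 411 inside, 410 outside


def test_hrpm_requires_mapped_reads():
    with pytest.raises(ValueError):
        hrpm(100, "+", _track({}), 0, CallerConfig())


@settings(max_examples=200, derandomize=True)
@given(h=st.integers(0, 10_000), m=st.integers(1, 10 ** 8),
       k=st.integers(2, 50))
def test_hrpm_scale_invariance(h, m, k):
    """Scaling counts and library size together leaves HRPM unchanged."""
    track = _track({(100, "+"): h})
    scaled = _track({(100, "+"): h * k})
    cfg = CallerConfig()
    a = hrpm(100, "+", track, m, cfg).hrpm
    b = hrpm(100, "+", scaled, m * k, cfg).hrpm
    assert a == pytest.approx(b, rel=1e-12)


# -------------------------------------------------------------------- RPKM

def test_rpkm_printed_definition():
    """1-kb gene, 200 overlapping reads, M=2e6 -> RPKM = 100.0."""
    gene = Gene("gA", "chr", 500, 1500, "+")
    recs = [(600 + i, 700 + i, "+") for i in range(200)]
    aln = make_alignment_set(recs)
    assert rpkm(gene, aln, 2_000_000).rpkm == 100.0


def test_rpkm_zero_reads_and_inverse_scaling():
    gene = Gene("gA", "chr", 500, 1500, "+")
    empty = make_alignment_set([(1600, 1700, "+")])
    assert rpkm(gene, empty, 1_000_000).rpkm == 0.0
    some = make_alignment_set([(600, 700, "+")] * 10)
    assert rpkm(gene, some, 1_000_000).rpkm \
        == pytest.approx(rpkm(gene, some, 2_000_000).rpkm * 2)


def test_rpkm_counts_strand_and_one_base_overlap():
    gene = Gene("gA", "chr", 500, 1500, "+")
    aln = make_alignment_set([(400, 501, "+"),   # 1 bp overlap: counted
                              (400, 500, "+"),   # abuts: not counted
                              (600, 700, "-")])  # wrong strand
    assert rpkm(gene, aln, 1_000_000).count == 1


def test_rpkm_rejects_m_zero():
    gene = Gene("gA", "chr", 500, 1500, "+")
    with pytest.raises(ValueError):
        rpkm(gene, make_alignment_set([]), 0)


# ------------------------------------------------------------ spike-in QC

def _spike_table(n=6):
    return pd.DataFrame({"spike_id": [f"s{i}" for i in range(n)],
                         "concentration": [2.0 ** i for i in range(n)],
                         "length": 1000})


def test_perfect_proportionality_gives_r_one():
    table = _spike_table()
    quants = {f"s{i}": 3.5 * 2.0 ** i for i in range(6)}
    qc = spike_in_qc(table, quants)
    assert qc.r == pytest.approx(1.0)
    assert qc.n_used == 6


def test_constant_concentration_errors():
    table = _spike_table()
    table["concentration"] = 4.0
    with pytest.raises(ValueError, match="constant"):
        spike_in_qc(table, {f"s{i}": float(i + 1) for i in range(6)})


def test_too_few_usable_spikeins_errors():
    table = _spike_table()
    quants = {"s0": 1.0, "s1": 2.0, "s2": 0.0, "s3": 0.0, "s4": 0.0,
              "s5": 0.0}
    with pytest.raises(ValueError, match=">= 3"):
        spike_in_qc(table, quants)


def test_r_matches_independent_recomputation():
    rng = np.random.default_rng(0)
    table = _spike_table(8)
    quants = {f"s{i}": float(rng.poisson(50 * 2.0 ** i)) for i in range(8)}
    qc = spike_in_qc(table, quants)
    x = np.log2(table["concentration"].to_numpy())
    y = np.log2([quants[f"s{i}"] for i in range(8)])
    ref = np.corrcoef(x, y)[0, 1]
    assert abs(qc.r - ref) < 0.02


# ------------------------------------------------------------ fold change

def test_fold_change_bounds_and_categories():
    rec4 = fold_change(10, 40, 10 ** 6, 10 ** 6, pseudocount=0)
    assert rec4.fold_change == 0.25 and rec4.category == "down"
    rec35 = fold_change(350, 10, 10 ** 6, 10 ** 6, pseudocount=0)
    assert rec35.fold_change == 35.0 and rec35.category == "up"
    mid = fold_change(30, 10, 10 ** 6, 10 ** 6, pseudocount=0)
    assert mid.category == "none"


def test_fold_change_pseudocount_floor():
    rec = fold_change(0.0, 0.0, 10 ** 6, 10 ** 6, pseudocount=1)
    assert rec.fold_change == 1.0


@settings(max_examples=200, derandomize=True)
@given(a=st.floats(0.01, 1e4), b=st.floats(0.01, 1e4))
def test_fold_change_reciprocity(a, b):
    """FC(a,b) * FC(b,a) = 1 without a pseudocount."""
    fab = fold_change(a, b, 10 ** 6, 10 ** 6, pseudocount=0).fold_change
    fba = fold_change(b, a, 10 ** 6, 10 ** 6, pseudocount=0).fold_change
    assert fab * fba == pytest.approx(1.0, rel=1e-9)


# ---------------------------------------------------------------- switch

def test_dominant_flip_is_a_switch():
    rec = detect_switch("gX", {"8C": {100: 90.0, 250: 10.0},
                               "18C": {100: 10.0, 250: 90.0}})
    assert rec.switch is True


def test_equal_usage_is_not_a_switch():
    rec = detect_switch("gX", {"8C": {100: 50.0, 250: 50.0},
                               "18C": {100: 50.0, 250: 50.0}})
    assert rec.switch is False


def test_usage_shift_without_flip_triggers_on_min_delta():
    quants = {"8C": {100: 80.0, 250: 20.0}, "18C": {100: 52.0, 250: 48.0}}
    assert detect_switch("gX", quants, min_delta=0.3).switch is False
    quants2 = {"8C": {100: 85.0, 250: 15.0}, "18C": {100: 52.0, 250: 48.0}}
    assert detect_switch("gX", quants2, min_delta=0.3).switch is True


def test_zero_total_leaves_switch_undefined():
    rec = detect_switch("gX", {"8C": {100: 0.0, 250: 0.0},
                               "18C": {100: 10.0, 250: 90.0}})
    assert rec.switch is None


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.floats(0.01, 100), min_size=2, max_size=5),
       st.lists(st.floats(0.01, 100), min_size=2, max_size=5))
def test_usage_sums_to_one_and_permutes_with_labels(va, vb):
    n = min(len(va), len(vb))
    va, vb = va[:n], vb[:n]
    positions = list(range(100, 100 + 60 * n, 60))
    quants = {"8C": dict(zip(positions, va)), "18C": dict(zip(positions, vb))}
    rec = detect_switch("gX", quants)
    for c in ("8C", "18C"):
        assert sum(rec.usage[c].values()) == pytest.approx(1.0)
    # permuting TSS labels permutes usage identically
    perm = positions[::-1]
    quants_p = {"8C": dict(zip(perm, va)), "18C": dict(zip(perm, vb))}
    rec_p = detect_switch("gX", quants_p)
    for c in ("8C", "18C"):
        for p_old, p_new in zip(positions, perm):
            assert rec.usage[c][p_old] == pytest.approx(rec_p.usage[c][p_new])
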