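import numpy as np
import pytest

from tss_atlas import CallerConfig, SimulationParams
from tss_atlas.io_formats import AlignmentSet, Library
from tss_atlas.pipeline import run_pipeline


@pytest.fixture(scope="session")
def config():
    return CallerConfig()


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline on the default study conditions (seed 0)."""
    return run_pipeline(SimulationParams())


@pytest.fixture(scope="session")
def small_params():
    """A compact simulation for per-module tests."""
    return SimulationParams(genome_length=40_000, n_genes=15, n_srnas=4,
                            n_antisense=2, n_operons=2, depth=3000, seed=7)


@pytest.fixture(scope="session")
def small_result(small_params):
    return run_pipeline(small_params)


def make_alignment_set(records, library_id="libA", condition="8C",
                       kind="plus"):
    """Build an AlignmentSet from (start, end, strand) tuples."""
    lib = Library(library_id, condition, kind)
    if not records:
        return AlignmentSet(lib, [], [], [], [])
    starts, ends, strands = zip(*records)
    return AlignmentSet(lib, ["chr"] * len(records), list(starts),
                        list(ends), list(strands))


def random_read_set(rng, genome_length, n_clusters=6, read_len=40):
    """Random clustered reads producing head-count peaks of varied height.

    Returns (start, end, strand) tuples; peak heights straddle both
    calling thresholds so primary/secondary/no-call branches are all hit.
    """
    records = []
    for _ in range(n_clusters):
        strand = "+" if rng.random() < 0.5 else "-"
        center = int(rng.integers(read_len + 10, genome_length - read_len - 10))
        for _ in range(int(rng.integers(1, 4))):
            head = center + int(rng.integers(-8, 9))
            count = int(rng.integers(1, 18))
            for _ in range(count):
                if strand == "+":
                    s = head
                    e = min(genome_length, head + read_len)
                else:
                    e = head + 1
                    s = max(0, head + 1 - read_len)
                records.append((s, e, strand))
    return records
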