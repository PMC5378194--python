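"""Shared plumbing for the numbered analysis scripts."""

from pathlib import Path

from tss_atlas.config import CallerConfig
from tss_atlas.pipeline import run_pipeline
from tss_atlas.synthetic import SimulationParams

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SIM_DIR = RESULTS / "sim"

_cache = {}


def default_params(seed: int = 0) -> SimulationParams:
    return SimulationParams(seed=seed)


def get_result(seed: int = 0):
    """The full pipeline on the default study conditions (memoised)."""
    if seed not in _cache:
        _cache[seed] = run_pipeline(default_params(seed), CallerConfig())
    return _cache[seed]


def outdir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
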