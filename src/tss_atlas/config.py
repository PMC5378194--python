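"""Caller configuration.

Every threshold of the TSS-calling / refinement / classification procedure
lives here so that the whole pipeline is driven by one declarative object.
Defaults follow the dRNA-seq conventions used for archaeal primary
transcriptomes: a primary TSS needs >=10 head reads in the TEX-treated
(+) library, secondary TSSs >=5; whole-transcript coverage must be
continuous from the TSS to the start codon, allowing the first 20-30 nt of
the transcript to be missing; HRPM sums head reads over a 50-nt window
downstream of the TSS; 5' UTRs are capped at 500 nt (longest observed: 497
nt) and called leaderless below 10 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import yaml


@dataclass
class CallerConfig:
    #: minimum (+)-library head reads at the contig maximum for a primary TSS
    theta_primary: int = 10
    #: minimum (+)-library head reads for a secondary TSS
    theta_secondary: int = 5
    #: optional per-site (+)/(-) enrichment filter; ``None`` disables it
    enrichment_ratio: Optional[float] = None
    #: a secondary TSS must be a head-count local maximum within +/- this many nt
    local_max_halfwidth: int = 2
    #: minimum nt between two accepted calls in one contig
    min_tss_spacing: int = 5
    #: nt of 5'-terminal whole-transcript coverage allowed to be missing
    gap_allow: int = 30
    #: minimum whole-transcript coverage for the continuity rule
    min_cov: int = 1
    #: maximum 5' UTR length considered when linking a TSS to a downstream ORF
    max_utr: int = 500
    #: UTRs shorter than this are leaderless
    leaderless_cutoff: int = 10
    #: head reads are summed over this many nt downstream of a TSS for HRPM
    hrpm_window: int = 50
    #: assumed 3' UTR extent used only for antisense sub-classification
    utr3_allowance: int = 50
    #: pseudocount (in reads) for fold-change computation
    pseudocount: int = 1

    def __post_init__(self) -> None:
        if self.theta_secondary > self.theta_primary:
            raise ValueError("theta_secondary must not exceed theta_primary")
        for name in ("local_max_halfwidth", "min_tss_spacing", "gap_allow",
                     "max_utr", "leaderless_cutoff", "hrpm_window",
                     "utr3_allowance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.hrpm_window <= 0 or self.max_utr <= 0:
            raise ValueError("window lengths must be positive")

    @classmethod
    def from_yaml(cls, path) -> "CallerConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
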