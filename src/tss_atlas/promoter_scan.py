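"""Promoter-element scanning in fixed upstream windows of TSSs.

Archaeal core promoters carry a TATA box (and a BRE just 5' of it)
centred roughly 19-22 nt upstream of the TSS. This module extracts the
50-nt window upstream of each TSS on the TSS strand and locates the best
match to an IUPAC consensus (default ``TTTAWA``) or a PWM, reporting the
distance from the TSS to the motif's 3' edge. It is a deterministic
stand-in for de novo motif discovery: regions can be exported as FASTA
for external motif tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values

_COMP = str.maketrans("ACGT", "TGCA")
_BASES = "ACGT"
_BAND = (19, 22)  # canonical archaeal TATA offset band


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class PromoterRegion:
    """Upstream window of one TSS, oriented 5'->3' on the TSS strand.

    ``sequence[-1]`` is position -1 (the base immediately 5' of the TSS);
    the TSS base itself is excluded. Windows running off the reference
    edge are truncated.
    """

    tss_position: int
    strand: str
    sequence: str
    width: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MotifHit:
    pattern_id: str
    offset: int        # nt from the TSS to the motif's 3' edge (>= 1)
    matched: str
    score: float


def extract_upstream(tss_position: int, strand: str, genome: str,
                     width: int = 50) -> PromoterRegion:
    """Strand-aware upstream window, excluding the TSS base itself."""
    if strand == "+":
        lo = max(0, tss_position - width)
        seq = genome[lo:tss_position]
    else:
        hi = min(len(genome), tss_position + 1 + width)
        seq = _revcomp(genome[tss_position + 1:hi])
    return PromoterRegion(tss_position, strand, seq, width)


def _iupac_sets(pattern: str) -> List[frozenset]:
    try:
        return [frozenset(ambiguous_dna_values[b.upper()]) for b in pattern]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code in pattern {pattern!r}") from exc


def _iupac_match_score(window: str, sets: Sequence[frozenset]) -> int:
    """Number of positions matching the degenerate pattern."""
    return sum(b in s for b, s in zip(window, sets))


def pwm_log_odds(pwm: np.ndarray, window: str) -> float:
    """Log2-odds of ``window`` under a 4 x L PWM vs uniform background."""
    idx = [_BASES.index(b) if b in _BASES else -1 for b in window]
    score = 0.0
    for j, i in enumerate(idx):
        p = pwm[i, j] if i >= 0 else 0.25
        score += np.log2(max(p, 1e-9) / 0.25)
    return score


def scan_motif(region: PromoterRegion,
               pattern: Union[str, np.ndarray],
               min_score: Optional[float] = None,
               pattern_id: str = "TATA") -> Optional[MotifHit]:
    """Best motif placement in a promoter region, or ``None``.

    IUPAC patterns require an exact degenerate match (every position);
    PWMs (4 x L arrays, rows A/C/G/T) are scored by log2-odds against a
    uniform background and must reach ``min_score`` (default 0). Ties are
    broken towards the canonical 19-22 nt offset band, then 5'-most.
    """
    if isinstance(pattern, str):
        sets = _iupac_sets(pattern)
        L = len(sets)
        scorer = lambda w: float(_iupac_match_score(w, sets))
        threshold = float(L) if min_score is None else float(min_score)
    else:
        pwm = np.asarray(pattern, dtype=float)
        L = pwm.shape[1]
        scorer = lambda w: pwm_log_odds(pwm, w)
        threshold = 0.0 if min_score is None else float(min_score)
    seq = region.sequence
    n = len(seq)
    if L > n:
        return None
    best: Optional[Tuple[float, int, int, str]] = None
    for i in range(n - L + 1):
        window = seq[i:i + L]
        score = scorer(window)
        if score < threshold:
            continue
        offset = n - (i + L) + 1
        in_band = _BAND[0] <= offset <= _BAND[1]
        key = (score, in_band, offset)  # maximise all three
        if best is None or key > best[0]:
            best = (key, i, offset, window)
    if best is None:
        return None
    _, _, offset, window = best
    return MotifHit(pattern_id, offset, window, best[0][0])


def motif_position_summary(regions: Iterable[PromoterRegion],
                           pattern: Union[str, np.ndarray] = "TTTAWA",
                           min_score: Optional[float] = None,
                           band: Tuple[int, int] = _BAND) -> dict:
    """Hit fraction, offset histogram, and in-band fraction over regions."""
    regions = list(regions)
    if not regions:
        raise ValueError("no promoter regions supplied")
    offsets: List[int] = []
    for region in regions:
        hit = scan_motif(region, pattern, min_score)
        if hit is not None:
            offsets.append(hit.offset)
    hist: Dict[int, int] = {}
    for o in offsets:
        hist[o] = hist.get(o, 0) + 1
    n_hits = len(offsets)
    in_band = sum(band[0] <= o <= band[1] for o in offsets)
    return {
        "n_regions": len(regions),
        "n_hits": n_hits,
        "hit_fraction": n_hits / len(regions),
        "offset_histogram": dict(sorted(hist.items())),
        "fraction_in_band": (in_band / n_hits) if n_hits else float("nan"),
        "modal_offset": max(hist, key=hist.get) if hist else None,
    }


def write_regions_fasta(regions: Sequence[PromoterRegion], path) -> None:
    """Export promoter windows as FASTA (MEME-compatible input)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f">tss_{r.tss_position}{r.strand}\n{r.sequence}\n")
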