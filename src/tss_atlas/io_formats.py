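"""Readers/writers and coordinate conventions.

All internal coordinates are 0-based half-open on the forward genome
strand; GFF3 I/O converts to/from 1-based inclusive. Strand is ``'+'`` or
``'-'``. Alignments are consumed from BED6 (0-based half-open, strand in
column 6) or a minimal SAM dialect (mapped primary records only; no
CIGAR-aware clipping — simulated reads map end-to-end, a documented
limitation for real data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

STRANDS = ("+", "-")


@dataclass(frozen=True)
class ReadAlignment:
    """One mapped read (0-based half-open interval)."""

    read_id: str
    reference_id: str
    start: int
    end: int
    strand: str
    library_id: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start},{self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class Gene:
    """An annotated CDS (0-based half-open)."""

    locus_tag: str
    reference_id: str
    cds_start: int
    cds_end: int
    strand: str
    product: str = ""

    def __post_init__(self):
        if self.cds_start >= self.cds_end:
            raise ValueError(f"{self.locus_tag}: cds_start >= cds_end")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.locus_tag}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def start_codon_pos(self) -> int:
        """Genomic coordinate of the first base of the start codon."""
        return self.cds_start if self.strand == "+" else self.cds_end - 1


@dataclass
class Library:
    """Metadata for one sequencing library."""

    library_id: str
    condition: str  # e.g. "8C", "18C"
    kind: str  # "plus" (TEX+), "minus" (TEX-), "whole"
    total_mapped: int = 0


class AlignmentSet:
    """A library's alignments held as parallel numpy columns.

    Column storage keeps head counting and interval overlap vectorised;
    iteration yields :class:`ReadAlignment` records for code that wants
    objects.
    """

    def __init__(self, library: Library, reference_ids: Sequence[str],
                 starts: Sequence[int], ends: Sequence[int],
                 strands: Sequence[str],
                 read_ids: Optional[Sequence[str]] = None):
        self.library = library
        self.reference_ids = np.asarray(reference_ids, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.strands = np.asarray(strands, dtype=object)
        n = len(self.starts)
        if not (len(self.reference_ids) == len(self.ends) == len(self.strands) == n):
            raise ValueError("column length mismatch")
        if n and (self.starts < 0).any():
            raise ValueError("negative coordinates")
        if n and (self.starts >= self.ends).any():
            raise ValueError("empty or inverted interval")
        self._read_ids = None if read_ids is None else np.asarray(read_ids, dtype=object)
        self.library.total_mapped = n

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def read_ids(self) -> np.ndarray:
        if self._read_ids is None:
            self._read_ids = np.array(
                [f"{self.library.library_id}.r{i}" for i in range(len(self))],
                dtype=object)
        return self._read_ids

    def __iter__(self) -> Iterator[ReadAlignment]:
        rid = self.read_ids
        for i in range(len(self)):
            yield ReadAlignment(rid[i], self.reference_ids[i],
                                int(self.starts[i]), int(self.ends[i]),
                                self.strands[i], self.library.library_id)

    def subset_reference(self, reference_id: str) -> "AlignmentSet":
        m = self.reference_ids == reference_id
        sub = AlignmentSet(Library(self.library.library_id,
                                   self.library.condition,
                                   self.library.kind),
                           self.reference_ids[m], self.starts[m],
                           self.ends[m], self.strands[m],
                           self.read_ids[m])
        return sub

    # ------------------------------------------------------------------ I/O

    def to_bed(self, path) -> None:
        df = pd.DataFrame({
            "chrom": self.reference_ids,
            "start": self.starts,
            "end": self.ends,
            "name": self.read_ids,
            "score": np.zeros(len(self), dtype=int),
            "strand": self.strands,
        })
        df.to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path) -> Dict[str, str]:
    """Load FASTA records as an ``{id: sequence}`` dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gff3(path) -> List[Gene]:
    """Parse CDS features of a GFF3 file into :class:`Gene` records.

    GFF3 is 1-based inclusive; internal coordinates are 0-based half-open.
    Raises ``ValueError`` with the offending line number on malformed input
    or duplicate locus tags.
    """
    genes: List[Gene] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in STRANDS:
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            attr_d = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_d[k.strip()] = v.strip()
            tag = attr_d.get("locus_tag") or attr_d.get("ID")
            if tag is None:
                raise ValueError(f"{path}:{lineno}: CDS without locus_tag/ID")
            if tag in seen:
                raise ValueError(f"{path}:{lineno}: duplicate locus_tag {tag!r}")
            seen.add(tag)
            genes.append(Gene(tag, seqid, start_i - 1, end_i, strand,
                              attr_d.get("product", "")))
    return genes


def write_gff3(genes: Iterable[Gene], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.locus_tag};locus_tag={g.locus_tag}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write("\t".join([g.reference_id, "tss_atlas", "CDS",
                                str(g.cds_start + 1), str(g.cds_end), ".",
                                g.strand, "0", attrs]) + "\n")


def read_alignments(path, library: Library) -> AlignmentSet:
    """Load BED6 or minimal SAM alignments for one library.

    SAM records that are unmapped, secondary or supplementary are skipped
    with a logged tally; the remaining records must be plain end-to-end
    matches (no clipping adjustment is applied).
    """
    path = Path(path)
    if path.suffix.lower() == ".sam":
        return _read_sam(path, library)
    return _read_bed(path, library)


def _read_bed(path, library: Library) -> AlignmentSet:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "name", "score", "strand"],
                         dtype={"chrom": str, "name": str, "strand": str})
    except pd.errors.EmptyDataError:
        return AlignmentSet(library, [], [], [], [], [])
    if (df["start"] < 0).any():
        raise ValueError(f"{path}: negative coordinates")
    return AlignmentSet(library, df["chrom"].to_numpy(dtype=object),
                        df["start"].to_numpy(), df["end"].to_numpy(),
                        df["strand"].to_numpy(dtype=object),
                        df["name"].to_numpy(dtype=object))


def _read_sam(path, library: Library) -> AlignmentSet:
    refs, starts, ends, strands, names = [], [], [], [], []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            refs.append(rec.reference_name)
            starts.append(rec.reference_start)
            ends.append(rec.reference_end)
            strands.append("-" if rec.is_reverse else "+")
            names.append(rec.query_name)
    if skipped:
        log.info("%s: skipped %d unmapped/secondary records", path, skipped)
    return AlignmentSet(library, refs, starts, ends, strands, names)


def read_manifest(path) -> List[dict]:
    """Read a YAML library manifest: a list of {id, kind, condition, path}."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ValueError("manifest must be a list of library entries")
    for e in entries:
        missing = {"id", "kind", "condition", "path"} - set(e)
        if missing:
            raise ValueError(f"manifest entry missing keys: {sorted(missing)}")
    return entries


# ----------------------------------------------------------------- read QC

def filter_reads(fastq_records, max_n_frac: float = 0.10,
                 max_lowq_frac: float = 0.50, lowq_phred: int = 5,
                 min_len_frac: float = 1 / 3):
    """Apply the pre-processing QC filters to FASTQ records.

    A read is discarded iff it meets ANY of: fraction of uncalled bases
    (N) >= ``max_n_frac``; fraction of bases with PHRED <= ``lowq_phred``
    >= ``max_lowq_frac``; trimmed length <= ``min_len_frac`` of the
    original read length (the original length is taken from
    ``record.annotations['original_length']`` when present, else the
    current length).

    Returns ``(kept_records, tally)`` where ``tally`` counts discards per
    rule (a read failing several rules increments each) plus the total.
    """
    kept = []
    tally = {"n_frac": 0, "low_quality": 0, "truncated": 0, "discarded": 0}
    for rec in fastq_records:
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None:
            raise ValueError(f"{rec.id}: missing quality string")
        seq = str(rec.seq)
        n = len(seq)
        if n == 0:
            tally["truncated"] += 1
            tally["discarded"] += 1
            continue
        orig_len = rec.annotations.get("original_length", n)
        bad = False
        if seq.upper().count("N") / n >= max_n_frac:
            tally["n_frac"] += 1
            bad = True
        if sum(q <= lowq_phred for q in quals) / n >= max_lowq_frac:
            tally["low_quality"] += 1
            bad = True
        if n <= min_len_frac * orig_len:
            tally["truncated"] += 1
            bad = True
        if bad:
            tally["discarded"] += 1
        else:
            kept.append(rec)
    return kept, tally


# ------------------------------------------------------------- TSS output

TSS_TSV_COLUMNS = ["position", "strand", "rank", "head_plus", "head_minus",
                   "condition", "refined"]


def write_tss_outputs(calls, outdir, stem: str = "tss",
                      reference_id: str = "chr") -> Dict[str, Path]:
    """Write TSS calls as TSV + BED6 + GFF3 under ``outdir``.

    BED intervals are 1 nt at the TSS (0-based half-open); the GFF3 is
    1-based inclusive. The TSV round-trips through :func:`read_tss_tsv`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [{"position": c.position, "strand": c.strand, "rank": c.rank,
             "head_plus": c.head_plus, "head_minus": c.head_minus,
             "condition": c.condition, "refined": c.refined}
            for c in calls]
    df = pd.DataFrame(rows, columns=TSS_TSV_COLUMNS)
    paths = {"tsv": outdir / f"{stem}.tsv", "bed": outdir / f"{stem}.bed",
             "gff3": outdir / f"{stem}.gff3"}
    df.to_csv(paths["tsv"], sep="\t", index=False)
    with open(paths["bed"], "w") as fh:
        for c in calls:
            fh.write(f"{reference_id}\t{c.position}\t{c.position + 1}\t.\t"
                     f"{c.head_plus}\t{c.strand}\n")
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(calls):
            fh.write("\t".join([reference_id, "tss_atlas", "TSS",
                                str(c.position + 1), str(c.position + 1), ".",
                                c.strand, ".",
                                f"ID=TSS{i};rank={c.rank}"]) + "\n")
    return paths


def read_tss_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
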