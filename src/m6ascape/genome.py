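"""Genomic primitives shared by every stage of the pipeline.

Coordinates are 0-based half-open throughout ([start, end), BED convention).
GTF-style annotation is converted to this convention on read. All sequence
queries are strand-aware: a minus-strand fetch returns the reverse complement,
so the returned string always reads 5'->3' on the transcribed strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes -> the set of concrete bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Strand-aware half-open interval, the unit of all peak arithmetic."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", same_strand: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def union(self, other: "GenomicInterval") -> "GenomicInterval":
        if self.chrom != other.chrom:
            raise ValueError("cannot union intervals on different chromosomes")
        return replace(self, start=min(self.start, other.start), end=max(self.end, other.end))

    def shift(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class PeakCall:
    """One peak from one caller in one sample."""

    interval: GenomicInterval
    sample_id: str
    caller: str
    score: float = 0.0


@dataclass
class TranscriptModel:
    """One transcript of a gene; region logic uses the canonical one only."""

    gene_id: str
    transcript_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    cds_start: int | None = None
    cds_end: int | None = None
    is_canonical: bool = False

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"{self.transcript_id}: exon outside transcript span")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = ex.end
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: cds_start/cds_end must both be set")
        if self.cds_start is not None:
            if not self.cds_start < self.cds_end:
                raise ValueError(f"{self.transcript_id}: cds_start must precede cds_end")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def tss(self) -> int:
        """Genomic position of the first transcribed base (strand-aware)."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Map a genomic position into transcript coordinates (0 = TSS base).

        Returns None for intronic or out-of-transcript positions.
        """
        offset = 0
        for ex in self.exons:
            if ex.start <= pos < ex.end:
                t = offset + (pos - ex.start)
                if self.strand == "-":
                    t = self.exonic_length() - 1 - t
                return t
            offset += len(ex)
        return None

    def cds_transcript_bounds(self) -> tuple[int, int] | None:
        """CDS [start, end) in transcript coordinates, or None for noncoding."""
        if not self.is_coding:
            return None
        a = self.genomic_to_transcript(self.cds_start)
        b = self.genomic_to_transcript(self.cds_end - 1)
        if a is None or b is None:
            raise ValueError(f"{self.transcript_id}: CDS bounds not exonic")
        lo, hi = min(a, b), max(a, b)
        return lo, hi + 1


class GenomeSequence:
    """Per-chromosome uppercase nucleotide strings with strand-aware fetch."""

    def __init__(self, chroms: Mapping[str, str]):
        self._chroms = {name: seq.upper() for name, seq in chroms.items()}
        for name, seq in self._chroms.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"{name}: non-nucleotide characters {sorted(bad)}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def chrom_length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    @property
    def chroms(self) -> dict[str, str]:
        return dict(self._chroms)

    def fetch(self, interval: GenomicInterval) -> str:
        seq = self._chroms.get(interval.chrom)
        if seq is None:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > len(seq):
            raise IndexError(
                f"{interval.chrom}:{interval.start}-{interval.end} beyond "
                f"chromosome end ({len(seq)})"
            )
        sub = seq[interval.start:interval.end]
        return reverse_complement(sub) if interval.strand == "-" else sub

    def base(self, chrom: str, pos: int, strand: str = "+") -> str:
        return self.fetch(GenomicInterval(chrom, pos, pos + 1, strand))

    def reverse_complemented(self) -> "GenomeSequence":
        return GenomeSequence({c: reverse_complement(s) for c, s in self._chroms.items()})

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sorted(self._chroms.items())
        ]
        SeqIO.write(records, str(path), "fasta")


def iupac_regex(motif: str) -> re.Pattern[str]:
    """Compile an IUPAC nucleotide motif into a regex over ACGT."""
    parts = []
    for code in motif.upper():
        if code not in IUPAC:
            raise ValueError(f"invalid IUPAC code {code!r} in motif {motif!r}")
        bases = IUPAC[code]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


# ---------------------------------------------------------------------------
# Plain-text interchange: BED6 and a GTF-like annotation
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None,
              scores: Sequence[float] | None = None) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"feature_{i}"
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str, float]]:
    """Read a BED6 file; returns (interval, name, score) triples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "+"
            out.append((GenomicInterval(chrom, start, end, strand), name, score))
    return out


def read_peak_calls(path: str | Path) -> list[PeakCall]:
    """Peak calls as BED6 with name encoded ``sample:caller``."""
    calls = []
    for iv, name, score in read_bed(path):
        sample, _, caller = name.partition(":")
        calls.append(PeakCall(iv, sample_id=sample, caller=caller or "caller", score=score))
    return calls


def write_peak_calls(calls: Iterable[PeakCall], path: str | Path) -> None:
    calls = list(calls)
    write_bed(
        (c.interval for c in calls), path,
        names=[f"{c.sample_id}:{c.caller}" for c in calls],
        scores=[c.score for c in calls],
    )


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def _gtf_attrs(field: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(field))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read a GTF-like annotation into transcript models.

    Recognises ``transcript``, ``exon`` and ``CDS`` features; a transcript is
    canonical when it carries ``tag "canonical"`` or ``canonical "true"``.
    GTF 1-based inclusive coordinates become 0-based half-open here.
    """
    tx_rows: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, feature = f[0], f[2]
            start, end, strand = int(f[3]) - 1, int(f[4]), f[6]
            attrs = _gtf_attrs(f[8])
            tid = attrs.get("transcript_id")
            if tid is None:
                continue
            row = tx_rows.setdefault(tid, {
                "gene_id": attrs.get("gene_id", tid),
                "chrom": chrom, "strand": strand,
                "span": None, "exons": [], "cds": [],
                "canonical": False,
            })
            canonical = attrs.get("tag") == "canonical" or attrs.get("canonical") == "true"
            row["canonical"] = row["canonical"] or canonical
            if feature == "transcript":
                row["span"] = (start, end)
            elif feature == "exon":
                row["exons"].append((start, end))
            elif feature == "CDS":
                row["cds"].append((start, end))
    models = []
    for tid, row in tx_rows.items():
        exons = sorted(row["exons"])
        span = row["span"] or (exons[0][0], exons[-1][1])
        cds_start = cds_end = None
        if row["cds"]:
            cds_start = min(s for s, _ in row["cds"])
            cds_end = max(e for _, e in row["cds"])
        models.append(TranscriptModel(
            gene_id=row["gene_id"], transcript_id=tid,
            interval=GenomicInterval(row["chrom"], span[0], span[1], row["strand"]),
            exons=[GenomicInterval(row["chrom"], s, e, row["strand"]) for s, e in exons],
            cds_start=cds_start, cds_end=cds_end,
            is_canonical=row["canonical"],
        ))
    return models


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path,
              source: str = "m6ascape") -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            tag = ' tag "canonical";' if tx.is_canonical else ""
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";{tag}'
            iv = tx.interval
            fh.write(f"{iv.chrom}\t{source}\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t"
                     f"{iv.strand}\t.\t{attrs}\n")
            for ex in tx.exons:
                fh.write(f"{iv.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                         f"{iv.strand}\t.\t{attrs}\n")
            if tx.is_coding:
                for ex in tx.exons:
                    s = max(ex.start, tx.cds_start)
                    e = min(ex.end, tx.cds_end)
                    if s < e:
                        fh.write(f"{iv.chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t"
                                 f"{iv.strand}\t0\t{attrs}\n")


def canonical_by_gene(transcripts: Iterable[TranscriptModel]) -> dict[str, TranscriptModel]:
    """Index canonical transcripts by gene; duplicates are an input error."""
    out: dict[str, TranscriptModel] = {}
    for tx in transcripts:
        if not tx.is_canonical:
            continue
        if tx.gene_id in out:
            raise ValueError(f"gene {tx.gene_id} has two canonical transcripts")
        out[tx.gene_id] = tx
    return out
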