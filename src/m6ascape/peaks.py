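"""Consensus m6A peak catalogue construction.

Implements the catalogue funnel used for antibody-based m6A maps: per-sample
peaks from two independent callers are intersected (only regions supported by
both callers survive), per-sample consensus peaks are pooled into a catalogue,
peaks must recur in a minimum number of samples, probable m6Am signals at the
transcription start are flagged and removed, and the survivors are annotated
against the canonical transcript of each gene. Descriptive summaries (region
distribution, motif fraction, metagene profile) operate on the final catalogue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    GenomeSequence,
    GenomicInterval,
    PeakCall,
    TranscriptModel,
    canonical_by_gene,
    iupac_regex,
)

REGIONS = (
    "5UTR", "start_codon_vicinity", "CDS", "stop_codon_vicinity",
    "3UTR", "intron", "noncoding", "intergenic",
)

#: half-width (bp) of the start/stop-codon vicinity windows
CODON_VICINITY_BP = 100


@dataclass
class ConsensusPeak:
    """A catalogue peak with its annotation and sample recurrence."""

    peak_id: str
    interval: GenomicInterval
    gene_id: str | None
    region: str
    recurrence: int = 0
    is_m6am: bool = False
    in_known_db: bool = False


# ---------------------------------------------------------------------------
# Internal enrichment peak caller (stand-in for external callers)
# ---------------------------------------------------------------------------

def call_enrichment_peaks(
    ip_coverage: np.ndarray,
    input_coverage: np.ndarray,
    window: int = 50,
    p_cutoff: float = 1e-6,
    chrom: str = "chr1",
    strand: str = "+",
    sample_id: str = "sample",
    caller: str = "poisson",
) -> list[PeakCall]:
    """Call enrichment peaks from per-base IP vs input coverage.

    The input track is scaled to the IP library depth; each non-overlapping
    ``window``-bp tile is tested with a one-sided Poisson tail
    (P[X >= ip | mu = scaled input]) and maximal runs of adjacent significant
    tiles are merged into peaks. Deterministic for fixed input; the peak score
    is -log10 of the smallest window p-value in the run.
    """
    ip = np.asarray(ip_coverage, dtype=float)
    inp = np.asarray(input_coverage, dtype=float)
    if ip.shape != inp.shape:
        raise ValueError(f"coverage tracks differ in length: {ip.shape} vs {inp.shape}")
    if window < 10:
        raise ValueError(f"window must be >= 10 bp, got {window}")
    input_depth = inp.sum()
    if input_depth <= 0:
        raise ValueError("input track has zero total depth")
    scale = ip.sum() / input_depth

    n_win = len(ip) // window
    if n_win == 0:
        return []
    ip_w = ip[: n_win * window].reshape(n_win, window).sum(axis=1)
    exp_w = inp[: n_win * window].reshape(n_win, window).sum(axis=1) * scale
    pvals = stats.poisson.sf(ip_w - 1, np.maximum(exp_w, 1e-300))
    sig = pvals < p_cutoff

    peaks: list[PeakCall] = []
    i = 0
    while i < n_win:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_win and sig[j + 1]:
            j += 1
        iv = GenomicInterval(chrom, i * window, (j + 1) * window, strand)
        score = float(-np.log10(max(pvals[i : j + 1].min(), 1e-300)))
        peaks.append(PeakCall(iv, sample_id=sample_id, caller=caller, score=score))
        i = j + 1
    return peaks


# ---------------------------------------------------------------------------
# Two-caller consensus and catalogue assembly
# ---------------------------------------------------------------------------

def merge_overlapping(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse overlapping same-strand intervals into their unions."""
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    out: list[GenomicInterval] = []
    for group in by_key.values():
        group.sort(key=lambda iv: iv.start)
        cur = group[0]
        for iv in group[1:]:
            if iv.start < cur.end:
                cur = cur.union(iv)
            else:
                out.append(cur)
                cur = iv
        out.append(cur)
    return sorted(out)


def merge_consensus(
    calls_a: Sequence[PeakCall], calls_b: Sequence[PeakCall]
) -> list[GenomicInterval]:
    """Keep only peaks supported by both callers, merged to their union.

    Every A/B pair overlapping by >= 1 bp on the same strand contributes the
    union of the two intervals; peaks seen by a single caller are dropped, and
    overlapping unions are collapsed. Commutative and idempotent on A = B.
    """
    ivs_a = [c.interval for c in calls_a]
    ivs_b = [c.interval for c in calls_b]
    unions = [
        a.union(b)
        for a in ivs_a
        for b in ivs_b
        if a.overlaps(b, same_strand=True)
    ]
    return merge_overlapping(unions) if unions else []


def build_catalogue(
    per_sample: Mapping[str, Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Pool per-sample consensus peaks into one merged catalogue."""
    pooled = [iv for ivs in per_sample.values() for iv in ivs]
    return merge_overlapping(pooled) if pooled else []


def presence_table(
    catalogue: Sequence[GenomicInterval],
    per_sample: Mapping[str, Sequence[GenomicInterval]],
    peak_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Peaks x samples boolean table: >= 1 bp overlap marks presence."""
    ids = list(peak_ids) if peak_ids is not None else [
        f"peak_{i:05d}" for i in range(len(catalogue))
    ]
    data = {}
    for sample, ivs in per_sample.items():
        col = [any(p.overlaps(iv, same_strand=True) for iv in ivs) for p in catalogue]
        data[sample] = col
    return pd.DataFrame(data, index=ids)


def filter_recurrence(presence: pd.DataFrame, min_samples: int = 5) -> list[str]:
    """Retain peaks present in at least ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    if presence.isna().any().any():
        raise ValueError("presence table contains missing cells")
    keep = presence.sum(axis=1) >= min_samples
    return list(presence.index[keep])


# ---------------------------------------------------------------------------
# Annotation against canonical transcripts
# ---------------------------------------------------------------------------

def _utr_cds_spans(
    tx: TranscriptModel,
) -> tuple[list[GenomicInterval], list[GenomicInterval], list[GenomicInterval]]:
    """Exonic 5'UTR, CDS and 3'UTR genomic spans of a coding transcript."""
    assert tx.is_coding
    if tx.strand == "+":
        utr5_bounds = (tx.interval.start, tx.cds_start)
        utr3_bounds = (tx.cds_end, tx.interval.end)
    else:
        utr5_bounds = (tx.cds_end, tx.interval.end)
        utr3_bounds = (tx.interval.start, tx.cds_start)
    cds_bounds = (tx.cds_start, tx.cds_end)

    def clip(bounds: tuple[int, int]) -> list[GenomicInterval]:
        lo, hi = bounds
        out = []
        for ex in tx.exons:
            s, e = max(ex.start, lo), min(ex.end, hi)
            if s < e:
                out.append(GenomicInterval(tx.interval.chrom, s, e, tx.strand))
        return out

    return clip(utr5_bounds), clip(cds_bounds), clip(utr3_bounds)


def _codon_vicinity(tx: TranscriptModel, which: str) -> GenomicInterval:
    """Genomic window of +/- CODON_VICINITY_BP around the start or stop codon."""
    if (which == "start") == (tx.strand == "+"):
        codon = (tx.cds_start, tx.cds_start + 3)
    else:
        codon = (tx.cds_end - 3, tx.cds_end)
    return GenomicInterval(
        tx.interval.chrom,
        max(0, codon[0] - CODON_VICINITY_BP),
        codon[1] + CODON_VICINITY_BP,
        tx.strand,
    )


def assign_region(peak: GenomicInterval, tx: TranscriptModel) -> str:
    """Region of a peak on one transcript, resolved by the priority rule.

    Priority for peaks straddling boundaries: start/stop-codon vicinity
    (+/- CODON_VICINITY_BP around the codon) > 5'UTR / 3'UTR > CDS > intron.
    """
    exonic = any(peak.overlaps(ex) for ex in tx.exons)
    if not tx.is_coding:
        return "noncoding" if exonic else "intron"
    if not exonic:
        return "intron"
    if peak.overlaps(_codon_vicinity(tx, "start")):
        return "start_codon_vicinity"
    if peak.overlaps(_codon_vicinity(tx, "stop")):
        return "stop_codon_vicinity"
    utr5, cds, utr3 = _utr_cds_spans(tx)
    if any(peak.overlaps(iv) for iv in utr5):
        return "5UTR"
    if any(peak.overlaps(iv) for iv in utr3):
        return "3UTR"
    if any(peak.overlaps(iv) for iv in cds):
        return "CDS"
    return "intron"


def _best_transcript(
    peak: GenomicInterval, canonical: Mapping[str, TranscriptModel]
) -> TranscriptModel | None:
    best, best_ov = None, 0
    for tx in canonical.values():
        if tx.interval.strand != peak.strand or tx.interval.chrom != peak.chrom:
            continue
        ov = peak.overlap_len(tx.interval)
        if ov > best_ov:
            best, best_ov = tx, ov
    return best


def annotate_peaks(
    peaks: Sequence[GenomicInterval],
    transcripts: Sequence[TranscriptModel],
    peak_ids: Sequence[str] | None = None,
) -> list[ConsensusPeak]:
    """Assign gene and region from the canonical transcript of each gene.

    Peaks overlapping no canonical transcript on their strand are intergenic.
    Raises if any gene carries two canonical transcripts.
    """
    canonical = canonical_by_gene(transcripts)
    ids = list(peak_ids) if peak_ids is not None else [
        f"peak_{i:05d}" for i in range(len(peaks))
    ]
    out = []
    for pid, peak in zip(ids, peaks):
        tx = _best_transcript(peak, canonical)
        if tx is None:
            out.append(ConsensusPeak(pid, peak, None, "intergenic"))
        else:
            out.append(ConsensusPeak(pid, peak, tx.gene_id, assign_region(peak, tx)))
    return out


def flag_m6am(
    peaks: Sequence[GenomicInterval],
    transcripts: Sequence[TranscriptModel],
    genome: GenomeSequence,
) -> list[bool]:
    """Flag peaks that are probable m6Am rather than internal m6A.

    A peak is flagged when it overlaps the 5'UTR of its gene's canonical
    transcript, the first transcribed base of that transcript is A, and that
    TSS adenosine sits in a BCA context: the base immediately 5' of the A on
    the transcript strand is B (C, G or T), any base 3'. m6Am is a cap-adjacent
    modification that cross-reacts with the m6A antibody, so these peaks are
    removed from the internal-m6A catalogue.
    """
    canonical = canonical_by_gene(transcripts)
    flags = []
    for peak in peaks:
        tx = _best_transcript(peak, canonical)
        if tx is None or not tx.is_coding:
            flags.append(False)
            continue
        utr5, _, _ = _utr_cds_spans(tx)
        if not any(peak.overlaps(iv) for iv in utr5):
            flags.append(False)
            continue
        tss = tx.tss
        if not (0 <= tss < genome.chrom_length(tx.interval.chrom)):
            raise IndexError(f"{tx.transcript_id}: TSS outside genome bounds")
        if genome.base(tx.interval.chrom, tss, tx.strand) != "A":
            flags.append(False)
            continue
        up_pos = tss - 1 if tx.strand == "+" else tss + 1
        if not (0 <= up_pos < genome.chrom_length(tx.interval.chrom)):
            flags.append(False)  # no upstream context available
            continue
        upstream = genome.base(tx.interval.chrom, up_pos, tx.strand)
        flags.append(upstream in "CGT")
    return flags


def mark_known_sites(
    peaks: Sequence[GenomicInterval], known: Sequence[GenomicInterval]
) -> list[bool]:
    """Per-peak flag: overlaps any user-supplied known-m6A-site interval."""
    return [any(p.overlaps(k, same_strand=True) for k in known) for p in peaks]


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

def motif_fraction(
    peaks: Sequence[GenomicInterval],
    genome: GenomeSequence,
    motif: str = "GGACH",
) -> float:
    """Fraction of peaks whose strand-aware sequence contains the motif."""
    if not peaks:
        return 0.0
    pattern = iupac_regex(motif)
    hits = sum(bool(pattern.search(genome.fetch(p))) for p in peaks)
    return hits / len(peaks)


def metagene_profile(
    peaks: Sequence[GenomicInterval],
    transcripts: Sequence[TranscriptModel],
    bins_per_region: int = 30,
) -> tuple[np.ndarray, dict[str, int]]:
    """Peak-midpoint density over a normalised 5'UTR / CDS / 3'UTR axis.

    Each peak midpoint is mapped into transcript coordinates of its best
    canonical coding transcript, scaled within its region to [0, 1) and binned
    (``bins_per_region`` bins per region, 3 regions). Returns the density
    (sums to 1 when any peak maps) and a skip log with reasons.
    """
    canonical = {
        g: tx for g, tx in canonical_by_gene(transcripts).items() if tx.is_coding
    }
    density = np.zeros(3 * bins_per_region)
    skip = {"no_transcript": 0, "not_exonic": 0, "no_cds": 0, "empty_region": 0}
    if not peaks:
        warnings.warn("metagene_profile called with an empty peak list")
        return density, skip
    for peak in peaks:
        tx = _best_transcript(peak, canonical)
        if tx is None:
            skip["no_transcript"] += 1
            continue
        tpos = tx.genomic_to_transcript(peak.midpoint)
        if tpos is None:
            skip["not_exonic"] += 1
            continue
        bounds = tx.cds_transcript_bounds()
        if bounds is None:
            skip["no_cds"] += 1
            continue
        cds_lo, cds_hi = bounds
        tx_len = tx.exonic_length()
        if tpos < cds_lo:
            region, frac = 0, tpos / cds_lo if cds_lo else 0.0
        elif tpos < cds_hi:
            region, frac = 1, (tpos - cds_lo) / (cds_hi - cds_lo)
        else:
            if tx_len == cds_hi:
                skip["empty_region"] += 1
                continue
            region, frac = 2, (tpos - cds_hi) / (tx_len - cds_hi)
        b = min(int(frac * bins_per_region), bins_per_region - 1)
        density[region * bins_per_region + b] += 1
    total = density.sum()
    if total > 0:
        density /= total
    else:
        warnings.warn("no peak could be placed on the metagene axis")
    return density, skip


def region_distribution(annotated: Sequence[ConsensusPeak]) -> pd.Series:
    """Count of catalogue peaks per region class."""
    counts = pd.Series(0, index=list(REGIONS), dtype=int)
    for p in annotated:
        counts[p.region] += 1
    return counts
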