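"""Site co-localization statistics and CIMS-based m6A residue calling.

CIMS (crosslink-induced mutation site) analysis of miCLIP data: reverse
transcription past a UV-crosslinked antibody-RNA adduct introduces C-to-T
transitions one base 3' of the methylated adenosine, so filtered C>T positions
pinpoint m6A residues at single-nucleotide resolution. Co-localization between
site sets (CLIP binding vs m6A, DNA binding vs Pol II) is summarised by signed
nearest-neighbor distance profiles and interval-overlap Fisher tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genome import GenomeSequence, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CIMSRecord:
    """One mutation position with unique-tag coverage k and mutation count m."""

    position: GenomicInterval      # width-1 interval, strand = read strand
    ref_base: str
    alt_base: str
    k: int
    m: int
    is_known_snp: bool = False

    def __post_init__(self) -> None:
        if len(self.position) != 1:
            raise ValueError("CIMS position must be a width-1 interval")
        if not 0 <= self.m <= self.k:
            raise ValueError(f"require 0 <= m <= k, got m={self.m}, k={self.k}")
        for b in (self.ref_base, self.alt_base):
            if b not in "ACGT":
                raise ValueError(f"bases must be in ACGT, got {b!r}")


@dataclass
class DistanceProfile:
    """Histogram of signed distances from set-A anchors to nearest B anchor."""

    counts: np.ndarray
    bin_edges: np.ndarray
    window: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def call_cims_m6a(
    records: Sequence[CIMSRecord],
    genome: GenomeSequence,
    max_mutation_fraction: float = 0.5,
) -> list[GenomicInterval]:
    """Call m6A residues from CIMS mutation records.

    A record yields an m6A call when all four conditions hold: (i) it is not
    a known SNP, (ii) the substitution is C>T on the read strand, (iii) the
    mutation fraction m/k is at most ``max_mutation_fraction``, and (iv) the
    mutated C sits at the +1 position (immediately 3', transcript orientation)
    of an adenosine. The reported residue is that adenosine. Records with
    k = 0 are skipped and logged.
    """
    calls = []
    for rec in records:
        if rec.k == 0:
            logger.info("call_cims_m6a: zero-coverage record at %s skipped", rec.position)
            continue
        if rec.is_known_snp:
            continue
        if not (rec.ref_base == "C" and rec.alt_base == "T"):
            continue
        if rec.m / rec.k > max_mutation_fraction:
            continue
        pos = rec.position
        a_pos = pos.start - 1 if pos.strand == "+" else pos.start + 1
        if not (0 <= a_pos < genome.chrom_length(pos.chrom)):
            continue
        if genome.base(pos.chrom, a_pos, pos.strand) != "A":
            continue
        calls.append(GenomicInterval(pos.chrom, a_pos, a_pos + 1, pos.strand))
    return calls


def distance_profile(
    anchors_a: Sequence[GenomicInterval],
    anchors_b: Sequence[GenomicInterval],
    window: int = 2000,
    bin_width: int = 50,
) -> DistanceProfile:
    """Signed distance from each A anchor to its nearest B anchor.

    Distances are midpoint-to-midpoint, oriented by the A anchor's strand
    (positive = 3' of the anchor) and kept only within +/- ``window`` bp.
    Equidistant B anchors resolve toward the 3' side.
    """
    if not anchors_a or not anchors_b:
        raise ValueError("both anchor sets must be non-empty")
    b_by_chrom: dict[str, np.ndarray] = {}
    for iv in anchors_b:
        b_by_chrom.setdefault(iv.chrom, []).append(iv.midpoint)  # type: ignore[arg-type]
    b_by_chrom = {c: np.sort(np.asarray(v)) for c, v in b_by_chrom.items()}

    distances = []
    for a in anchors_a:
        mids = b_by_chrom.get(a.chrom)
        if mids is None:
            continue
        am = a.midpoint
        i = np.searchsorted(mids, am)
        candidates = []
        if i < len(mids):
            candidates.append(mids[i] - am)     # downstream in genome coords
        if i > 0:
            candidates.append(mids[i - 1] - am)
        # signed distance in transcript orientation
        signed = [d if a.strand == "+" else -d for d in candidates]
        in_win = [d for d in signed if abs(d) <= window]
        if not in_win:
            continue
        best = min(abs(d) for d in in_win)
        tied = [d for d in in_win if abs(d) == best]
        distances.append(max(tied))  # 3'-side (positive) wins ties
    edges = np.arange(-window, window + bin_width, bin_width)
    counts, edges = np.histogram(distances, bins=edges)
    return DistanceProfile(counts=counts, bin_edges=edges, window=window)


def overlap_fisher(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    universe: Sequence[GenomicInterval],
) -> dict:
    """Association of two site sets over a common peak universe.

    Each universe peak is marked as belonging to a set when it overlaps any
    of that set's intervals by >= 1 bp (same strand). One-sided Fisher's exact
    test for positive association.
    """
    if not universe:
        raise ValueError("universe is empty")

    def membership(site_set: Sequence[GenomicInterval]) -> np.ndarray:
        by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
        for iv in site_set:
            by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
        flags = np.zeros(len(universe), dtype=bool)
        for i, peak in enumerate(universe):
            group = by_key.get((peak.chrom, peak.strand), [])
            flags[i] = any(peak.overlaps(iv) for iv in group)
        return flags

    in_a = membership(set_a)
    in_b = membership(set_b)
    table = np.array([
        [int((in_a & in_b).sum()), int((in_a & ~in_b).sum())],
        [int((~in_a & in_b).sum()), int((~in_a & ~in_b).sum())],
    ])
    odds, p = stats.fisher_exact(table, alternative="greater")
    return {
        "table": table,
        "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
        "p": float(p),
        "n_a": int(in_a.sum()),
        "n_b": int(in_b.sum()),
        "n_both": int((in_a & in_b).sum()),
    }
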