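"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one data modality of an antibody-based m6A study of a
tumor/normal cohort: a toy annotated genome, IP/input MeRIP coverage with
planted enrichment peaks, a multi-sample methylation cohort with planted
tumor effects, two tumor subtypes and one driver RBP, DRB-release GRO-seq
wave profiles with known elongation rates, and CIMS mutation tables with
planted true m6A residues. All generators are deterministic under a fixed
seed and return machine-readable truth alongside the data.

Default cohort scalars mirror the emulated study design: 33 tumor/normal
pairs plus 32 unpaired tumors, ~2,000 catalogue peaks (scaled down from the
full catalogue for tractability) with a planted differential set split
195 hyper / 93 hypo, two tumor subtypes, and one driver RBP among 50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coloc import CIMSRecord
from .elongation import TssProfile
from .genome import GenomeSequence, GenomicInterval, TranscriptModel, reverse_complement
from .quant import CountTable

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Toy annotation
# ---------------------------------------------------------------------------

def make_toy_annotation(
    n_genes: int = 10,
    seed: int = 0,
    gene_length: int = 3000,
    spacing: int = 1000,
) -> tuple[list[TranscriptModel], GenomeSequence, dict]:
    """Non-overlapping multi-exon genes on both strands of one toy chromosome.

    Every gene has two exons with UTRs and a CDS; a GGACT motif is planted at
    the centre of a designated peak window inside each gene's CDS, and
    even-indexed genes get a BCA context at the TSS (TSS base A preceded by
    C on the transcript strand) for m6Am tests. Returns (transcripts, genome,
    truth) where truth carries the planted motif windows and m6Am gene ids.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chrom = "chrT"
    chrom_len = n_genes * (gene_length + spacing) + spacing
    seq = rng.choice(_BASES, size=chrom_len)

    transcripts: list[TranscriptModel] = []
    motif_windows: list[GenomicInterval] = []
    m6am_genes: list[str] = []

    for g in range(n_genes):
        start = spacing + g * (gene_length + spacing)
        end = start + gene_length
        strand = "+" if g % 2 == 0 else "-"
        gene_id = f"gene_{g:03d}"
        # two exons separated by an intron occupying the middle fifth
        intron_lo = start + 2 * gene_length // 5
        intron_hi = start + 3 * gene_length // 5
        exons = [
            GenomicInterval(chrom, start, intron_lo, strand),
            GenomicInterval(chrom, intron_hi, end, strand),
        ]
        # CDS leaves ~300 bp UTR at each end (genomic coordinates)
        cds_start, cds_end = start + 300, end - 300
        tx = TranscriptModel(
            gene_id=gene_id,
            transcript_id=f"{gene_id}.t1",
            interval=GenomicInterval(chrom, start, end, strand),
            exons=exons,
            cds_start=cds_start,
            cds_end=cds_end,
            is_canonical=True,
        )
        transcripts.append(tx)

        # plant GGACT in the centre of a 100-bp peak window in the first
        # coding exon portion
        win_lo = cds_start + 50
        win = GenomicInterval(chrom, win_lo, win_lo + 100, strand)
        motif = "GGACT"
        centre = win_lo + 48
        planted = motif if strand == "+" else reverse_complement(motif)
        seq[centre : centre + 5] = list(planted)
        motif_windows.append(win)

        tss = tx.tss
        if g % 2 == 0:
            up = tss - 1 if strand == "+" else tss + 1
            seq[tss] = "A" if strand == "+" else "T"
            seq[up] = "C" if strand == "+" else "G"
            m6am_genes.append(gene_id)
        else:
            # force a non-A TSS so the m6Am flag stays off
            seq[tss] = "G" if strand == "+" else "C"

    genome = GenomeSequence({chrom: "".join(seq)})
    truth = {"motif_windows": motif_windows, "m6am_genes": m6am_genes}
    return transcripts, genome, truth


# ---------------------------------------------------------------------------
# MeRIP IP/input coverage
# ---------------------------------------------------------------------------

def simulate_merip(
    transcripts: list[TranscriptModel],
    genome: GenomeSequence,
    planted_peaks: list[GenomicInterval],
    enrichment_fold: float = 10.0,
    depth: float = 2.0,
    seed: int = 0,
) -> dict:
    """IP/input coverage with planted enrichment over a toy annotation.

    Both tracks carry Poisson(depth) background on transcribed (exonic)
    positions; inside each planted peak the IP mean is multiplied by
    ``enrichment_fold``. Returns per-(chrom, strand) tracks, a CountTable
    over the planted peak regions, and the truth list.
    """
    if enrichment_fold < 1:
        raise ValueError("enrichment_fold must be >= 1")
    rng = np.random.default_rng(seed)
    keys = {(tx.interval.chrom, tx.strand) for tx in transcripts}
    tracks: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for chrom, strand in sorted(keys):
        n = genome.chrom_length(chrom)
        ip_mu = np.zeros(n)
        input_mu = np.zeros(n)
        for tx in transcripts:
            if (tx.interval.chrom, tx.strand) != (chrom, strand):
                continue
            for ex in tx.exons:
                ip_mu[ex.start:ex.end] = depth
                input_mu[ex.start:ex.end] = depth
        for peak in planted_peaks:
            if (peak.chrom, peak.strand) == (chrom, strand):
                ip_mu[peak.start:peak.end] *= enrichment_fold
        tracks[(chrom, strand)] = {
            "ip": rng.poisson(ip_mu).astype(float),
            "input": rng.poisson(input_mu).astype(float),
        }

    ids = [f"peak_{i:04d}" for i in range(len(planted_peaks))]
    ip_counts, input_counts, lengths = [], [], []
    for peak in planted_peaks:
        tr = tracks[(peak.chrom, peak.strand)]
        ip_counts.append(tr["ip"][peak.start:peak.end].sum())
        input_counts.append(tr["input"][peak.start:peak.end].sum())
        lengths.append(len(peak))
    ip_lib = sum(tr["ip"].sum() for tr in tracks.values())
    input_lib = sum(tr["input"].sum() for tr in tracks.values())
    counts = CountTable(
        ip=pd.DataFrame({"s1": ip_counts}, index=ids),
        input_=pd.DataFrame({"s1": input_counts}, index=ids),
        ip_lib=pd.Series({"s1": ip_lib}),
        input_lib=pd.Series({"s1": input_lib}),
        peak_lengths=pd.Series(lengths, index=ids),
    )
    return {"tracks": tracks, "counts": counts, "truth": list(planted_peaks)}


# ---------------------------------------------------------------------------
# Cohort: methylation matrix + expression + clinical + survival
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Design scalars of the synthetic tumor/normal methylation cohort."""

    n_tumor: int = 65
    n_normal_paired: int = 33
    n_peaks: int = 2000
    n_hyper_planted: int = 195
    n_hypo_planted: int = 93
    subtype_fraction: float = 0.5
    subtype_effect: float = 2.0
    tumor_effect: float = 2.0
    n_rbps: int = 50
    driver_effect: float = 0.5
    noise_sd: float = 0.3
    median_pfs_s1: float = 11.2
    median_pfs_s2: float = 6.6
    censor_time: float = 36.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.subtype_fraction <= 1 or not 0 <= self.driver_effect <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if min(self.n_tumor, self.n_peaks, self.n_rbps) < 1:
            raise ValueError("counts must be positive")
        if self.n_normal_paired > self.n_tumor:
            raise ValueError("cannot have more pairs than tumors")
        if self.n_hyper_planted + self.n_hypo_planted > self.n_peaks:
            raise ValueError("planted differential set exceeds the catalogue")


def simulate_cohort(spec: CohortSpec) -> dict:
    """Methylation cohort with planted tumor, subtype and driver structure.

    Log-normal baseline levels per peak; tumors receive a multiplicative
    effect on planted hyper peaks (inverse on hypo peaks); S2-subtype tumors
    receive an additional ``subtype_effect`` on the hyper set; the driver
    RBP's (log) expression is mixed into hyper-peak levels so that it explains
    ``driver_effect`` of their log-scale residual variance, and its expression
    is shifted up in S2 tumors (the driver is what distinguishes the
    subtypes). With ``driver_effect = 0`` the driver is exchangeable with
    every other RBP. Survival is exponential with a subtype-dependent median
    and administrative censoring.
    """
    rng = np.random.default_rng(spec.seed)
    peaks = [f"peak_{i:05d}" for i in range(spec.n_peaks)]
    tumors = [f"T{i:03d}" for i in range(spec.n_tumor)]
    normals = [f"N{i:03d}" for i in range(spec.n_normal_paired)]
    pairs = list(zip(tumors[: spec.n_normal_paired], normals))

    hyper = peaks[: spec.n_hyper_planted]
    hypo = peaks[spec.n_hyper_planted : spec.n_hyper_planted + spec.n_hypo_planted]

    n_s2 = int(round(spec.subtype_fraction * spec.n_tumor))
    is_s2 = np.zeros(spec.n_tumor, dtype=bool)
    is_s2[rng.choice(spec.n_tumor, size=n_s2, replace=False)] = True
    subtype = pd.Series(np.where(is_s2, "S2", "S1"), index=tumors, name="subtype")

    # RBP expression (log scale); one driver, shifted up in S2 when active
    rbps = [f"RBP_{i:03d}" for i in range(spec.n_rbps)]
    driver = rbps[int(rng.integers(spec.n_rbps))]
    log_expr = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(spec.n_tumor, spec.n_rbps)),
        index=tumors, columns=rbps,
    )
    if spec.driver_effect > 0:
        log_expr.loc[is_s2, driver] += np.log(spec.subtype_effect) * 2
    expression = np.exp(log_expr)

    base = np.exp(rng.normal(np.log(2.0), 0.5, size=spec.n_peaks))
    log_m = pd.DataFrame(
        np.add.outer(np.log(base), np.zeros(spec.n_tumor + spec.n_normal_paired)),
        index=peaks, columns=tumors + normals,
    )

    hyper_idx = log_m.index.isin(hyper)
    hypo_idx = log_m.index.isin(hypo)
    log_m.loc[hyper_idx, tumors] += np.log(spec.tumor_effect)
    log_m.loc[hypo_idx, tumors] -= np.log(spec.tumor_effect)
    log_m.loc[hyper_idx, subtype.index[is_s2]] += np.log(spec.subtype_effect)

    # driver mixing on hyper peaks: standardized driver log-expression takes
    # driver_effect of the noise variance, i.i.d. noise the rest
    z = log_expr[driver].to_numpy()
    z = (z - z.mean()) / z.std() if z.std() > 0 else z
    d = spec.driver_effect
    noise_t = rng.normal(0.0, 1.0, size=(int(hyper_idx.sum()), spec.n_tumor))
    mixed = np.sqrt(d) * z[None, :] + np.sqrt(1 - d) * noise_t
    log_m.loc[hyper_idx, tumors] += spec.noise_sd * mixed
    other = ~hyper_idx
    log_m.loc[other, tumors] += rng.normal(
        0.0, spec.noise_sd, size=(int(other.sum()), spec.n_tumor)
    )
    log_m[normals] += rng.normal(
        0.0, spec.noise_sd, size=(spec.n_peaks, spec.n_normal_paired)
    )
    m6a = np.exp(log_m)

    clinical = pd.DataFrame(
        {
            "sex": rng.choice(["male", "female"], size=spec.n_tumor),
            "age_group": rng.choice(["<60", ">=60"], size=spec.n_tumor),
            "smoking": rng.choice(["never", "ever"], size=spec.n_tumor),
            "drinking": rng.choice(["never", "ever"], size=spec.n_tumor),
            "stage": rng.choice(["I-II", "III-IV"], size=spec.n_tumor),
            "differentiation": rng.choice(["well", "moderate", "poor"], size=spec.n_tumor),
            "neural_invasion": rng.choice(["yes", "no"], size=spec.n_tumor),
            "vascular_invasion": rng.choice(["yes", "no"], size=spec.n_tumor),
            "lymph_node": rng.choice(["positive", "negative"], size=spec.n_tumor),
        },
        index=tumors,
    )

    scale = np.where(is_s2, spec.median_pfs_s2, spec.median_pfs_s1) / np.log(2)
    raw_t = rng.exponential(scale)
    time = np.minimum(raw_t, spec.censor_time)
    survival = pd.DataFrame(
        {
            "time": np.maximum(time, 1e-3),
            "event": (raw_t <= spec.censor_time).astype(int),
            "endpoint": "PFS",
        },
        index=tumors,
    )

    return {
        "m6a": m6a,
        "expression": expression,
        "clinical": clinical,
        "survival": survival,
        "pairs": pairs,
        "truth": {
            "hyper": hyper,
            "hypo": hypo,
            "subtype": subtype,
            "driver": driver,
        },
    }


# ---------------------------------------------------------------------------
# GRO-seq wave profiles
# ---------------------------------------------------------------------------

@dataclass
class WaveSpec:
    """Design of the DRB-release GRO-seq simulation."""

    n_genes: int = 50
    rate_range: tuple[float, float] = (0.5, 4.0)
    times: tuple[float, ...] = (10.0, 25.0)
    wave_width: float = 4000.0
    wave_amplitude: float = 20.0
    basal_depth: float = 0.5
    upstream: int = 10_000
    downstream: int = 120_000
    seed: int = 0
    rates: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if list(self.times) != sorted(set(self.times)):
            raise ValueError("times must be strictly increasing")
        if self.rates is not None and np.any(np.asarray(self.rates) <= 0):
            raise ValueError("rates must be positive")


def simulate_groseq(spec: WaveSpec) -> dict:
    """Per-time TSS profiles with a Gaussian wavefront at rate x time.

    Each gene's profile is a basal gradient decaying downstream of the TSS
    plus a Gaussian wave centred ``rate * time`` kb downstream, Poisson
    sampled per base. Returns profiles (one per gene and time) and the truth
    rates (kb/min).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.rates is not None:
        rates = np.asarray(spec.rates, dtype=float)
        if len(rates) != spec.n_genes:
            raise ValueError("rates length must equal n_genes")
    else:
        rates = rng.uniform(*spec.rate_range, size=spec.n_genes)

    pos = np.arange(-spec.upstream, spec.downstream + 1, dtype=float)
    profiles: list[TssProfile] = []
    for g in range(spec.n_genes):
        gene = f"gene_{g:03d}"
        for t in spec.times:
            centre = rates[g] * 1e3 * t
            body = pos >= 0
            mu = np.zeros_like(pos)
            # basal gradient: transcription behind the advancing front
            mu[body] = spec.basal_depth * np.clip(1.0 - pos[body] / (2 * spec.downstream), 0, None)
            mu += spec.wave_amplitude * np.exp(
                -0.5 * ((pos - centre) / spec.wave_width) ** 2
            )
            mu[~body] *= 0.05  # little signal upstream of the TSS
            depth = rng.poisson(mu).astype(float)
            profiles.append(TssProfile(gene, t, depth, spec.upstream, spec.downstream))
    truth = pd.Series(rates, index=[f"gene_{g:03d}" for g in range(spec.n_genes)],
                      name="rate_kb_per_min")
    return {"profiles": profiles, "truth": truth}


# ---------------------------------------------------------------------------
# CIMS mutation tables
# ---------------------------------------------------------------------------

def simulate_cims(
    n_sites: int = 100,
    n_decoys: int = 300,
    snp_rate: float = 0.2,
    seed: int = 0,
) -> dict:
    """CIMS records with planted true m6A residues and labelled decoys.

    True sites are C>T records one base 3' of an A with m/k <= 0.5 and no SNP
    flag. Decoys cycle through the four failure modes: SNP-flagged, mutation
    fraction above 0.5, wrong substitution class, and no adenosine anchor.
    Returns records, the truth list of m6A adenosine positions, and the
    genome.
    """
    if not 0 < snp_rate < 1:
        raise ValueError("snp_rate must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    total = n_sites + n_decoys
    chrom = "chrC"
    spacing = 10
    seq = rng.choice(_BASES, size=total * spacing + 2 * spacing)

    records: list[CIMSRecord] = []
    truth: list[GenomicInterval] = []
    for i in range(total):
        p = spacing + i * spacing  # mutation position
        strand = "+" if rng.random() < 0.5 else "-"
        a_pos = p - 1 if strand == "+" else p + 1
        k = int(rng.integers(5, 50))
        is_true = i < n_sites
        if is_true:
            m = max(1, int(rng.uniform(0.05, 0.5) * k))
            ref, alt, snp = "C", "T", False
            anchor = "A"
        else:
            mode = i % 4
            m = max(1, int(rng.uniform(0.05, 0.5) * k))
            ref, alt, snp = "C", "T", False
            anchor = "A"
            if mode == 0:
                snp = True
            elif mode == 1:
                m = int(np.ceil(0.6 * k))
            elif mode == 2:
                ref, alt = "G", "A"
            else:
                anchor = "G"
        # write the anchor and the mutated base into the genome (strand-aware)
        if strand == "+":
            seq[a_pos] = anchor
            seq[p] = ref
        else:
            seq[a_pos] = reverse_complement(anchor)
            seq[p] = reverse_complement(ref)
        records.append(CIMSRecord(
            position=GenomicInterval(chrom, p, p + 1, strand),
            ref_base=ref, alt_base=alt, k=k, m=m, is_known_snp=snp,
        ))
        if is_true:
            truth.append(GenomicInterval(chrom, a_pos, a_pos + 1, strand))

    genome = GenomeSequence({chrom: "".join(seq)})
    return {"records": records, "truth": truth, "genome": genome}
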