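"""Relative m6A quantification and differential methylation.

The relative m6A level of a peak in a sample is the ratio of IP RPKM to input
RPKM (reads per kilobase of peak per million mapped reads). Differential
methylation between paired tumor/normal samples uses the Wilcoxon signed-rank
test with Benjamini-Hochberg correction; a label-permutation null quantifies
how many calls the same procedure makes on randomised data. Two-condition
(e.g. knockdown vs control) comparisons use a plain fold-change rule on
condition means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: pair count below which a peak is reported non-significant untested
MIN_PAIRS = 5

#: exact signed-rank null up to this many pairs, normal approximation above
EXACT_MAX_N = 25


@dataclass
class CountTable:
    """Per-peak IP and input read counts with per-sample library sizes.

    ``ip`` and ``input_`` are peaks x samples integer frames sharing index and
    columns; library sizes are total mapped reads per sample (not restricted
    to peaks); ``peak_lengths`` is in bp.
    """

    ip: pd.DataFrame
    input_: pd.DataFrame
    ip_lib: pd.Series
    input_lib: pd.Series
    peak_lengths: pd.Series

    def __post_init__(self) -> None:
        if not self.ip.index.equals(self.input_.index):
            raise ValueError("IP and input tables disagree on peaks")
        if not self.ip.columns.equals(self.input_.columns):
            raise ValueError("IP and input tables disagree on samples")
        if (self.ip.values < 0).any() or (self.input_.values < 0).any():
            raise ValueError("negative read counts")
        if (self.peak_lengths <= 0).any():
            raise ValueError("peak lengths must be positive")


def rpkm(counts: pd.DataFrame, lib_sizes: pd.Series, lengths_bp: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of region per million mapped reads."""
    if (lib_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    per_million = counts.div(lib_sizes / 1e6, axis=1)
    return per_million.div(lengths_bp / 1e3, axis=0)


def relative_m6a_level(counts: CountTable) -> pd.DataFrame:
    """MethylationMatrix: IP RPKM / input RPKM per peak and sample.

    Undefined (NaN) where the input count is zero; the peak length cancels in
    the ratio but both RPKMs are computed explicitly.
    """
    ip_rpkm = rpkm(counts.ip, counts.ip_lib, counts.peak_lengths)
    input_rpkm = rpkm(counts.input_, counts.input_lib, counts.peak_lengths)
    level = ip_rpkm / input_rpkm
    return level.where(counts.input_ > 0)


def _signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p; zero differences are dropped.

    Uses the exact sign-flip null (dynamic programming over the rank sum,
    valid under ties) up to EXACT_MAX_N non-zero pairs, and the normal
    approximation with continuity and tie correction above.
    """
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        return 1.0
    if n > EXACT_MAX_N:
        return float(
            stats.wilcoxon(diffs, alternative="two-sided", method="approx",
                           correction=True).pvalue
        )
    # average ranks doubled so every achievable rank sum is an integer
    ranks2 = np.round(2 * stats.rankdata(np.abs(diffs))).astype(int)
    w2 = int(ranks2[diffs > 0].sum())
    total = int(ranks2.sum())
    # null distribution of the doubled positive-rank sum under random signs
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= 2.0**n
    lo = min(w2, total - w2)
    # the sign-flip null is symmetric about total/2, so the doubled lower
    # tail is the two-sided p
    p = dist[: lo + 1].sum() + dist[total - lo:].sum()
    return float(min(p, 1.0))


def differential_paired(
    m: pd.DataFrame,
    pairs: list[tuple[str, str]],
    fdr_cut: float = 0.1,
    min_pairs: int = MIN_PAIRS,
) -> pd.DataFrame:
    """Paired differential methylation over (tumor, normal) sample pairs.

    Per peak: two-sided Wilcoxon signed-rank on the paired differences across
    pairwise-complete pairs, BH adjustment across tested peaks, direction from
    the median paired difference at ``fdr_cut``. Peaks with fewer than
    ``min_pairs`` usable pairs are reported ``ns`` with reason ``too_few_pairs``.

    Returns a frame indexed by peak with columns log2fc, p, fdr, direction,
    n_pairs, reason.
    """
    tumor_cols = [t for t, _ in pairs]
    normal_cols = [n for _, n in pairs]
    t_vals = m[tumor_cols].to_numpy(dtype=float)
    n_vals = m[normal_cols].to_numpy(dtype=float)

    n_peaks = m.shape[0]
    pvals = np.full(n_peaks, np.nan)
    med_diff = np.full(n_peaks, np.nan)
    log2fc = np.full(n_peaks, np.nan)
    n_used = np.zeros(n_peaks, dtype=int)
    reason = np.array([""] * n_peaks, dtype=object)

    for i in range(n_peaks):
        ok = ~np.isnan(t_vals[i]) & ~np.isnan(n_vals[i])
        n_used[i] = int(ok.sum())
        if n_used[i] < min_pairs:
            reason[i] = "too_few_pairs"
            continue
        d = t_vals[i, ok] - n_vals[i, ok]
        med_diff[i] = np.median(d)
        mean_n = n_vals[i, ok].mean()
        if mean_n > 0 and t_vals[i, ok].mean() > 0:
            log2fc[i] = np.log2(t_vals[i, ok].mean() / mean_n)
        pvals[i] = _signed_rank_p(d)

    tested = ~np.isnan(pvals)
    fdr = np.full(n_peaks, np.nan)
    if tested.any():
        fdr[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    direction = np.array(["ns"] * n_peaks, dtype=object)
    sig = tested & (fdr < fdr_cut) & (med_diff != 0)
    direction[sig & (med_diff > 0)] = "hyper"
    direction[sig & (med_diff < 0)] = "hypo"

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "fdr": fdr,
            "direction": direction,
            "n_pairs": n_used,
            "reason": reason,
        },
        index=m.index,
    )


def _count_significant(
    diffs: np.ndarray, threshold: float, adjust: bool, min_pairs: int
) -> int:
    n_peaks = diffs.shape[0]
    pvals = np.full(n_peaks, np.nan)
    med = np.full(n_peaks, np.nan)
    for i in range(n_peaks):
        d = diffs[i][~np.isnan(diffs[i])]
        if len(d) < min_pairs:
            continue
        med[i] = np.median(d)
        pvals[i] = _signed_rank_p(d)
    tested = ~np.isnan(pvals)
    if not tested.any():
        return 0
    crit = multipletests(pvals[tested], method="fdr_bh")[1] if adjust else pvals[tested]
    return int(((crit < threshold) & (med[tested] != 0)).sum())


def permutation_null(
    m: pd.DataFrame,
    pairs: list[tuple[str, str]],
    n_perm: int = 1000,
    seed: int = 0,
    threshold: float = 0.1,
    adjust: bool = True,
    min_pairs: int = MIN_PAIRS,
) -> dict:
    """Significant-peak counts after random tumor/normal label swaps.

    Labels are permuted within each pair (a sign flip of the paired
    difference), preserving the pairing structure the signed-rank test
    assumes. ``adjust`` selects BH-FDR < threshold (the differential call)
    or raw p < threshold (the pre-correction stage, useful for calibration
    where FDR-level counts are almost always zero). Returns the observed
    count at the same criterion, the per-permutation count distribution and
    its mean.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    rng = np.random.default_rng(seed)
    tumor_cols = [t for t, _ in pairs]
    normal_cols = [n for _, n in pairs]
    diffs = m[tumor_cols].to_numpy(dtype=float) - m[normal_cols].to_numpy(dtype=float)

    observed = _count_significant(diffs, threshold, adjust, min_pairs)
    counts = np.zeros(n_perm, dtype=int)
    for b in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=diffs.shape[1])
        counts[b] = _count_significant(diffs * signs, threshold, adjust, min_pairs)
    return {"observed": observed, "counts": counts, "mean": float(counts.mean())}


def two_condition_fc(
    m_a: pd.DataFrame, m_b: pd.DataFrame, fc_cut: float = 1.2
) -> pd.DataFrame:
    """Fold-change calls between two conditions (B relative to A).

    Replicate columns are averaged per condition; a peak is hyper when
    mean_B/mean_A > fc_cut, hypo when mean_A/mean_B > fc_cut, ns otherwise.
    Peaks with a zero or undefined condition mean are reported missing.
    """
    if not m_a.index.equals(m_b.index):
        raise ValueError("the two conditions must share one peak catalogue")
    mean_a = m_a.mean(axis=1, skipna=True)
    mean_b = m_b.mean(axis=1, skipna=True)
    direction = pd.Series("ns", index=m_a.index, dtype=object)
    bad = (mean_a <= 0) | (mean_b <= 0) | mean_a.isna() | mean_b.isna()
    if bad.any():
        logger.info("two_condition_fc: %d peaks with zero/undefined mean", int(bad.sum()))
    direction[bad] = "missing"
    ok = ~bad
    direction[ok & (mean_b / mean_a > fc_cut)] = "hyper"
    direction[ok & (mean_a / mean_b > fc_cut)] = "hypo"
    fc = mean_b / mean_a
    fc[bad] = np.nan
    return pd.DataFrame(
        {"mean_a": mean_a, "mean_b": mean_b, "fc": fc, "direction": direction}
    )


def overlap_sets(set_x, set_y) -> dict:
    """Exact intersection counts and directional fractions of two id sets."""
    x, y = set(set_x), set(set_y)
    inter = x & y
    return {
        "n_x": len(x),
        "n_y": len(y),
        "n_intersection": len(inter),
        "fraction_of_x": len(inter) / len(x) if x else 0.0,
        "fraction_of_y": len(inter) / len(y) if y else 0.0,
    }


_CATEGORY = {
    ("hyper", "up"): "hyper-up",
    ("hypo", "down"): "hypo-down",
    ("hypo", "up"): "hypo-up",
    ("hyper", "down"): "hyper-down",
}


def integrate_rna_m6a(
    dm: pd.DataFrame, peak_to_gene: pd.Series, de: pd.Series
) -> pd.DataFrame:
    """Cross m6A direction with host-RNA direction per peak.

    ``dm`` is a differential frame with a ``direction`` column indexed by
    peak, ``peak_to_gene`` maps peak -> gene, ``de`` maps gene -> {up, down,
    ns}. Genes absent from ``de`` and peaks whose RNA direction is ns are
    categorised non-significant.
    """
    records = []
    for peak, m6a_dir in dm["direction"].items():
        gene = peak_to_gene.get(peak)
        rna_dir = de.get(gene, None) if gene is not None else None
        if rna_dir is None:
            logger.info("integrate_rna_m6a: gene for peak %s absent from DE table", peak)
            rna_dir = "ns"
        category = _CATEGORY.get((m6a_dir, rna_dir), "non-significant")
        records.append(
            {"peak_id": peak, "gene_id": gene, "m6a_direction": m6a_dir,
             "rna_direction": rna_dir, "category": category}
        )
    return pd.DataFrame(records).set_index("peak_id")
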