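"""Tumor subtyping from differential m6A levels.

Resampling consensus clustering: many times, draw a subsample of tumors,
cluster them, and record which pairs co-cluster. The consensus matrix (pairwise
co-clustering frequency among co-sampled draws) defines stable subtypes; final
labels come from hierarchical clustering of the consensus distance. Subtypes
are then characterised by unpaired differential methylation, categorical
clinical associations (Fisher/chi-square) and Kaplan-Meier survival with
log-rank tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests


@dataclass
class ConsensusResult:
    """Consensus matrices per k, final assignment and stability summaries."""

    consensus: dict[int, pd.DataFrame]
    labels: pd.Series          # sample -> "S1".."Sk" at the chosen k
    k: int
    silhouette: pd.Series      # per-sample silhouette on consensus distance
    pac: dict[int, float]      # proportion of ambiguous clustering per k
    resamples: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def _inner_cluster(x: np.ndarray, k: int, method: str, seed: int) -> np.ndarray:
    if method == "agglomerative":
        return AgglomerativeClustering(n_clusters=k, linkage="average").fit_predict(x)
    if method == "kmeans":
        return KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(x)
    raise ValueError(f"unknown inner clusterer {method!r}")


def consensus_cluster(
    m: pd.DataFrame,
    k: int = 2,
    k_range: tuple[int, ...] | None = None,
    n_boot: int = 1000,
    subsample: float = 0.8,
    seed: int = 0,
    standardize: bool = True,
    inner: str = "agglomerative",
    record_resamples: bool = False,
) -> ConsensusResult:
    """Consensus clustering of samples over resampled peak profiles.

    ``m`` is peaks x samples. Each of ``n_boot`` resamples draws
    ceil(subsample * n) samples without replacement and clusters them
    (agglomerative, average linkage on Euclidean distance by default); the
    consensus entry for a pair is co-clustered / co-sampled. Final labels at
    the chosen ``k`` come from average-linkage hierarchical clustering of
    1 - consensus, named S1..Sk in increasing order of mean m6A level (the
    high-methylation subtype gets the highest index).
    """
    samples = list(m.columns)
    n = len(samples)
    ks = tuple(k_range) if k_range else (k,)
    if any(kk > n for kk in ks):
        raise ValueError(f"k_range {ks} contains k beyond {n} samples")
    if not 0 < subsample <= 1:
        raise ValueError("subsample must be in (0, 1]")
    x = m.to_numpy(dtype=float).T  # samples x peaks
    if np.isnan(x).all(axis=1).any():
        raise ValueError("all-missing sample rows are not clusterable")
    x = np.nan_to_num(x, nan=np.nanmean(x))
    if standardize:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd

    rng = np.random.default_rng(seed)
    n_draw = math.ceil(subsample * n)
    consensus: dict[int, pd.DataFrame] = {}
    pac: dict[int, float] = {}
    resamples: list[tuple[np.ndarray, np.ndarray]] = []

    for kk in ks:
        co_cluster = np.zeros((n, n))
        co_sampled = np.zeros((n, n))
        rng_k = np.random.default_rng(rng.integers(2**31))
        for b in range(n_boot):
            idx = np.sort(rng_k.choice(n, size=n_draw, replace=False))
            labels = _inner_cluster(x[idx], kk, inner, seed=int(rng_k.integers(2**31)))
            co_sampled[np.ix_(idx, idx)] += 1
            for lab in range(kk):
                members = idx[labels == lab]
                co_cluster[np.ix_(members, members)] += 1
            if record_resamples and kk == ks[0]:
                resamples.append((idx, labels))
        with np.errstate(invalid="ignore"):
            cons = np.where(co_sampled > 0, co_cluster / np.maximum(co_sampled, 1), 0.0)
        np.fill_diagonal(cons, np.where(np.diag(co_sampled) > 0, 1.0, 0.0))
        consensus[kk] = pd.DataFrame(cons, index=samples, columns=samples)
        off = cons[np.triu_indices(n, 1)]
        pac[kk] = float(np.mean((off > 0.1) & (off < 0.9)))

    chosen_k = ks[0] if len(ks) == 1 else min(pac, key=lambda kk: (pac[kk], kk))
    cons = consensus[chosen_k].to_numpy()
    dist = 1.0 - cons
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    z = linkage(squareform(dist, checks=False), method="average")
    raw_labels = fcluster(z, t=chosen_k, criterion="maxclust")

    # order clusters by mean m6A level: S1 = lowest, Sk = highest
    sample_means = np.nanmean(m.to_numpy(dtype=float), axis=0)
    order = sorted(
        np.unique(raw_labels),
        key=lambda lab: float(np.mean(sample_means[raw_labels == lab])),
    )
    rename = {lab: f"S{i + 1}" for i, lab in enumerate(order)}
    labels = pd.Series([rename[lab] for lab in raw_labels], index=samples, name="subtype")

    sil = silhouette_samples(dist, raw_labels, metric="precomputed") if chosen_k > 1 else np.zeros(n)
    return ConsensusResult(
        consensus=consensus,
        labels=labels,
        k=chosen_k,
        silhouette=pd.Series(sil, index=samples, name="silhouette"),
        pac=pac,
        resamples=resamples,
    )


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for small tie-free samples."""
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 25 and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def subtype_differential(
    m: pd.DataFrame,
    labels: pd.Series,
    group_a: str = "S1",
    group_b: str = "S2",
    fdr_cut: float = 0.1,
    min_group: int = 5,
) -> pd.DataFrame:
    """Unpaired differential methylation, ``group_b`` relative to ``group_a``.

    Two-sided Wilcoxon rank-sum per peak with BH adjustment; direction from
    the difference of group medians at ``fdr_cut``.
    """
    cols_a = labels.index[labels == group_a]
    cols_b = labels.index[labels == group_b]
    for name, cols in ((group_a, cols_a), (group_b, cols_b)):
        if len(cols) < min_group:
            raise ValueError(f"group {name} has {len(cols)} samples (< {min_group})")
    va = m[cols_a].to_numpy(dtype=float)
    vb = m[cols_b].to_numpy(dtype=float)

    n_peaks = m.shape[0]
    pvals = np.full(n_peaks, np.nan)
    delta = np.full(n_peaks, np.nan)
    for i in range(n_peaks):
        a = va[i][~np.isnan(va[i])]
        b = vb[i][~np.isnan(vb[i])]
        if len(a) < min_group or len(b) < min_group:
            continue
        delta[i] = np.median(b) - np.median(a)
        pvals[i] = _rank_sum_p(b, a)

    tested = ~np.isnan(pvals)
    fdr = np.full(n_peaks, np.nan)
    if tested.any():
        fdr[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    direction = np.array(["ns"] * n_peaks, dtype=object)
    sig = tested & (fdr < fdr_cut) & (delta != 0)
    direction[sig & (delta > 0)] = "hyper"
    direction[sig & (delta < 0)] = "hypo"
    return pd.DataFrame(
        {"median_diff": delta, "p": pvals, "fdr": fdr, "direction": direction},
        index=m.index,
    )


def clinical_association(labels: pd.Series, clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-feature subtype association: Fisher's exact (2x2) or chi-square.

    Missing values are excluded per feature; a constant feature is reported
    with p = 1 and a note. Chi-square falls back to Fisher when any expected
    cell of a 2x2 table is < 5; larger sparse tables keep chi-square with a
    note (no exact r x c test is attempted).
    """
    rows = []
    for feature in clinical.columns:
        values = clinical[feature].dropna()
        common = values.index.intersection(labels.index)
        table = pd.crosstab(labels.loc[common], values.loc[common])
        note, odds = "", np.nan
        if table.shape[0] < 2 or table.shape[1] < 2:
            rows.append({"feature": feature, "test": "none", "p": 1.0,
                         "odds_ratio": np.nan, "note": "constant feature"})
            continue
        if table.shape == (2, 2):
            odds, p = stats.fisher_exact(table.to_numpy())
            test = "fisher"
        else:
            chi2, p, _, expected = stats.chi2_contingency(table.to_numpy())
            test = "chi-square"
            if (expected < 5).any():
                note = "expected cell < 5"
        rows.append({"feature": feature, "test": test, "p": float(p),
                     "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
                     "note": note})
    return pd.DataFrame(rows).set_index("feature")


def km_logrank(survival: pd.DataFrame, labels: pd.Series) -> dict:
    """Kaplan-Meier curves, median survival and log-rank test per group.

    ``survival`` needs ``time`` (months, > 0) and ``event`` (1 observed,
    0 censored) columns indexed by sample. The median is the smallest time
    with S(t) <= 0.5 (None when never reached).
    """
    common = survival.index.intersection(labels.index)
    surv = survival.loc[common]
    grp = labels.loc[common]
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if surv["event"].sum() == 0:
        raise ValueError("no events in any group")
    groups = sorted(grp.unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups for a log-rank comparison")

    curves, medians = {}, {}
    for g in groups:
        mask = grp == g
        kmf = KaplanMeierFitter()
        kmf.fit(surv.loc[mask, "time"], surv.loc[mask, "event"], label=str(g))
        sf = kmf.survival_function_.iloc[:, 0]
        curves[g] = sf
        med = kmf.median_survival_time_
        medians[g] = None if np.isinf(med) else float(med)

    if len(groups) == 2:
        a, b = groups
        res = logrank_test(
            surv.loc[grp == a, "time"], surv.loc[grp == b, "time"],
            surv.loc[grp == a, "event"], surv.loc[grp == b, "event"],
        )
    else:
        res = multivariate_logrank_test(surv["time"], grp, surv["event"])
    return {
        "curves": curves,
        "medians": medians,
        "statistic": float(res.test_statistic),
        "p": float(res.p_value),
    }
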