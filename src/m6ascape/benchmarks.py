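"""End-to-end reproducibility checks with planted ground truth.

Each function runs one pipeline stage on its synthetic study conditions and
returns the headline quantity (a recovery rate, a calibration fraction, an
error). They are shared by the acceptance tests and the reproduction script
so both report numbers computed by the same code path. Problem sizes are
scaled-down versions of the emulated study design (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .coloc import call_cims_m6a
from .elongation import WaveFit, estimate_rates, fit_rate
from .quant import differential_paired, overlap_sets, permutation_null
from .regulators import (
    aggregate_contributions, contribution_matrix, enrichment_fisher,
    fit_contribution_forest, rank_rbps, spearman_screen,
)
from .simulate import CohortSpec, WaveSpec, simulate_cims, simulate_cohort, simulate_groseq
from .subtypes import consensus_cluster

#: counts reported in the emulated study's text, used as worked-example inputs
PRINTED_COUNTS = {
    "hyper_fraction": (195, 195 + 93),
    "rmbase_overlap": (15_708, 17_996),
    "m6am_removed": (462, 26_684),
    "s2hyper_kd_hypo_overlap": (122, 188),
    "kd_oe_overlap": (6_411, 8_804),
    "mettl3_overlap": (1_850, 2_676),
}


def printed_ratio_examples() -> dict[str, float]:
    """Worked-example percentages from the published counts.

    Each pair (k, n) is materialised as two id sets with an intersection of
    size k and run through ``overlap_sets``; the reported number is the
    directional fraction as a percentage.
    """
    out = {}
    for name, (k, n) in PRINTED_COUNTS.items():
        x = {f"m{i}" for i in range(n)}
        y = {f"m{i}" for i in range(k)} | {f"other{i}" for i in range(n)}
        out[name] = 100.0 * overlap_sets(x, y)["fraction_of_x"]
    return out


def contribution_identity_residual(n_problems: int = 100, seed: int = 0) -> float:
    """Worst additive-identity residual over random regression forests."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_problems):
        n, p = 30, 6
        x = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"x{j}" for j in range(p)])
        beta = rng.normal(size=p)
        y = x.to_numpy() @ beta + rng.normal(scale=0.5, size=n)
        res = fit_contribution_forest(x, y, n_trees=10, seed=int(rng.integers(2**31)))
        worst = max(worst, res.max_identity_residual())
    return worst


def _rank_driver(spec: CohortSpec, n_trees: int, n_background: int) -> int:
    coh = simulate_cohort(spec)
    m, expr, truth = coh["m6a"], coh["expression"], coh["truth"]
    hyper, hypo = truth["hyper"], truth["hypo"]
    unchanged = [p for p in m.index
                 if p not in set(hyper) | set(hypo)][:n_background]
    cm = contribution_matrix(expr, m[expr.index], peaks=hyper,
                             n_trees=n_trees, seed=spec.seed)
    agg = aggregate_contributions(cm, hyper, rbp_cols=expr.columns)
    screen = spearman_screen(expr, m.loc[hyper + unchanged, expr.index])
    enr = enrichment_fisher(screen, hyper, unchanged)
    ranking = rank_rbps(agg, enr)
    return int(ranking.loc[truth["driver"], "rank"])


def driver_recovery(n_seeds: int = 20, seed: int = 0,
                    driver_effect: float = 0.6) -> dict:
    """How often the planted driver RBP ranks first across seeded cohorts."""
    top1 = 0
    for s in range(n_seeds):
        spec = CohortSpec(n_tumor=40, n_normal_paired=20, n_peaks=200,
                          n_hyper_planted=20, n_hypo_planted=10, n_rbps=15,
                          driver_effect=driver_effect, seed=seed + s)
        if _rank_driver(spec, n_trees=100, n_background=60) == 1:
            top1 += 1
    return {"top1": top1, "n_seeds": n_seeds}


def driver_null_uniformity(n_seeds: int = 200, seed: int = 0) -> dict:
    """Driver rank distribution with zero driver effect; GOF vs uniform."""
    ranks = []
    for s in range(n_seeds):
        spec = CohortSpec(n_tumor=30, n_normal_paired=15, n_peaks=60,
                          n_hyper_planted=6, n_hypo_planted=3, n_rbps=8,
                          driver_effect=0.0, seed=seed + s)
        ranks.append(_rank_driver(spec, n_trees=50, n_background=24))
    n_rbps = 8
    observed = np.bincount(ranks, minlength=n_rbps + 1)[1:]
    gof = stats.chisquare(observed)
    return {"ranks": ranks, "gof_p": float(gof.pvalue)}


def subtype_recovery(n_seeds: int = 5, seed: int = 0, n_boot: int = 1000) -> dict:
    """Adjusted Rand index of consensus clustering on separated cohorts."""
    aris = []
    for s in range(n_seeds):
        spec = CohortSpec(n_tumor=30, n_normal_paired=15, n_peaks=300,
                          n_hyper_planted=45, n_hypo_planted=20,
                          subtype_effect=2.0, driver_effect=0.0, seed=seed + s)
        coh = simulate_cohort(spec)
        truth = coh["truth"]
        diff = truth["hyper"] + truth["hypo"]
        res = consensus_cluster(coh["m6a"].loc[diff, truth["subtype"].index],
                                k=2, n_boot=n_boot, subsample=0.8, seed=seed + s)
        aris.append(adjusted_rand_score(truth["subtype"].values, res.labels.values))
    return {"aris": aris, "min": float(min(aris)), "mean": float(np.mean(aris))}


def null_calibration(n_seeds: int = 20, seed: int = 0,
                     n_peaks: int = 500, n_perm: int = 3) -> dict:
    """Type-I error and permutation-vs-observed agreement on null cohorts.

    Pure-null paired cohorts (33 pairs, no planted effects): the pooled
    fraction of peaks with p < 0.05 should sit near 0.05, and the observed
    count of peaks at p < 0.05 should match the mean count after random
    within-pair label swaps.
    """
    fracs, observed, perm_means = [], [], []
    for s in range(n_seeds):
        spec = CohortSpec(n_tumor=33, n_normal_paired=33, n_peaks=n_peaks,
                          n_hyper_planted=0, n_hypo_planted=0,
                          tumor_effect=1.0, subtype_effect=1.0,
                          driver_effect=0.0, seed=seed + s)
        coh = simulate_cohort(spec)
        res = differential_paired(coh["m6a"], coh["pairs"])
        fracs.append(float((res.p < 0.05).mean()))
        pm = permutation_null(coh["m6a"], coh["pairs"], n_perm=n_perm,
                              seed=seed + s, threshold=0.05, adjust=False)
        observed.append(pm["observed"])
        perm_means.append(pm["mean"])
    ratio = float(np.mean(observed) / max(np.mean(perm_means), 1e-12))
    return {
        "typeI_fraction": float(np.mean(fracs)),
        "n_tests": n_seeds * n_peaks,
        "observed_mean": float(np.mean(observed)),
        "permutation_mean": float(np.mean(perm_means)),
        "ratio": ratio,
    }


def cims_oracle_agreement(n_records: int = 10_000, seed: int = 0) -> dict:
    """Agreement of the CIMS caller with the explicit four-condition filter."""
    n_sites = n_records // 4
    sim = simulate_cims(n_sites=n_sites, n_decoys=n_records - n_sites, seed=seed)
    genome = sim["genome"]
    calls = call_cims_m6a(sim["records"], genome)
    brute = []
    for r in sim["records"]:
        if r.k == 0 or r.is_known_snp:
            continue
        if not (r.ref_base == "C" and r.alt_base == "T"):
            continue
        if r.m / r.k > 0.5:
            continue
        a = r.position.start - 1 if r.position.strand == "+" else r.position.start + 1
        if not (0 <= a < genome.chrom_length(r.position.chrom)):
            continue
        if genome.base(r.position.chrom, a, r.position.strand) != "A":
            continue
        brute.append((r.position.chrom, a, r.position.strand))
    impl = [(c.chrom, c.start, c.strand) for c in calls]
    recall = len(set(impl) & {(t.chrom, t.start, t.strand) for t in sim["truth"]})
    return {
        "agreement": float(impl == brute),
        "n_records": n_records,
        "n_calls": len(calls),
        "recall": recall / max(n_sites, 1),
    }


def elongation_recovery(n_genes: int = 50, seed: int = 0) -> dict:
    """Median relative error of recovered elongation rates, and the exact
    two-point slope on noiseless wave-peak positions."""
    sim = simulate_groseq(WaveSpec(n_genes=n_genes, rate_range=(0.5, 4.0),
                                   seed=seed))
    rates = estimate_rates(sim["profiles"], expression_threshold=0.0)
    ok = rates[rates.pass_filters]
    rel_err = ((ok.rate_kb_per_min - sim["truth"][ok.index]).abs()
               / sim["truth"][ok.index])
    wf = fit_rate(WaveFit("noiseless", {10.0: 20_000, 25.0: 50_000}))
    return {
        "median_rel_err": float(rel_err.median()),
        "n_pass": int(len(ok)),
        "n_genes": n_genes,
        "two_point_slope": wf.rate_kb_per_min,
    }
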