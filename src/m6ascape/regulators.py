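"""Ranking candidate regulator RBPs against hypermethylated m6As.

Two complementary screens are combined. A random-forest regression of each
peak's m6A level on RBP expression (plus encoded clinical covariates) is
decomposed per prediction path: every split attributes the change in node mean
to the split feature, so each prediction equals the root value plus the sum of
feature contributions, exactly. Separately, a Spearman correlation screen
(|rho| > 0.25, P < 0.05) counts significant RBP-peak pairs, and Fisher's exact
test asks whether an RBP's significant pairs are over-represented among
hypermethylated peaks relative to background. The final ranking combines the
mean contribution over hypermethylated peaks with the enrichment FDR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class ContributionResult:
    """Path-decomposed forest fit for one response (one peak)."""

    contributions: pd.Series        # per-predictor mean over samples and trees
    per_sample: pd.DataFrame        # samples x predictors, mean over trees
    root_value: float               # mean root-node value over trees
    predictions: np.ndarray         # forest predictions on the training rows

    def max_identity_residual(self) -> float:
        """max_i |prediction_i - c - sum_j contrib_ij|; 0 up to float error."""
        recon = self.root_value + self.per_sample.to_numpy().sum(axis=1)
        return float(np.max(np.abs(self.predictions - recon)))

    @property
    def contribution_magnitude(self) -> pd.Series:
        """Mean |per-sample contribution| per predictor.

        The signed per-sample contributions of any predictor average to ~0
        over the fitted cohort (the decomposition is centred on the root
        mean), so magnitude, not the signed mean, measures how much a
        predictor moves predictions and is the default ranking score.
        """
        return self.per_sample.abs().mean(axis=0)


def _tree_contributions(tree, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Per-sample feature contributions of one fitted CART tree.

    Walks every decision path, attributing child-mean minus parent-mean to the
    parent's split feature, so that for each sample
    prediction = root_value + sum of contributions.
    """
    t = tree.tree_
    values = t.value.reshape(-1)          # node means for single-output regression
    n_nodes = t.node_count
    p = x.shape[1]

    # node -> (parent feature, delta value) for every non-root node
    delta_feature = np.zeros(n_nodes, dtype=int)
    delta_value = np.zeros(n_nodes)
    for parent in range(n_nodes):
        for child in (t.children_left[parent], t.children_right[parent]):
            if child != -1:
                delta_feature[child] = t.feature[parent]
                delta_value[child] = values[child] - values[parent]

    indicator = tree.decision_path(x)     # samples x nodes, CSR
    # scatter each node's delta onto its feature column
    onehot = np.zeros((n_nodes, p))
    nonroot = np.arange(1, n_nodes)
    onehot[nonroot, delta_feature[nonroot]] = delta_value[nonroot]
    contrib = indicator @ onehot
    return float(values[0]), np.asarray(contrib)


def fit_contribution_forest(
    x: pd.DataFrame,
    y: pd.Series | np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
    max_features: int | None = None,
) -> ContributionResult:
    """Regression forest for one peak with exact path contributions.

    Defaults follow the regression-forest convention: bootstrap resampling,
    ceil(p/3) candidate features per split, unlimited depth. The additive
    identity prediction = c + sum(contrib) holds to float tolerance for every
    tree and sample.
    """
    y = np.asarray(y, dtype=float)
    if x.shape[0] < 10:
        raise ValueError(f"need >= 10 samples, got {x.shape[0]}")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    keep = x.columns[x.nunique() > 1]
    if len(keep) < x.shape[1]:
        logger.warning("dropping %d constant predictor columns", x.shape[1] - len(keep))
    if len(keep) == 0:
        raise ValueError("no non-constant predictors")
    xk = x[keep]
    mf = max_features if max_features is not None else math.ceil(len(keep) / 3)

    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=mf, bootstrap=True, random_state=seed
    )
    forest.fit(xk.to_numpy(), y)

    xmat = xk.to_numpy()
    total = np.zeros((xk.shape[0], len(keep)))
    roots = []
    for est in forest.estimators_:
        root, contrib = _tree_contributions(est, xmat)
        roots.append(root)
        total += contrib
    per_sample = pd.DataFrame(total / n_trees, index=x.index, columns=keep)
    return ContributionResult(
        contributions=per_sample.mean(axis=0),
        per_sample=per_sample,
        root_value=float(np.mean(roots)),
        predictions=forest.predict(xmat),
    )


def contribution_matrix(
    x: pd.DataFrame,
    m: pd.DataFrame,
    peaks=None,
    n_trees: int = 500,
    seed: int = 0,
    mode: str = "magnitude",
) -> pd.DataFrame:
    """Per-peak, per-predictor contribution scores over a set of peaks.

    Fits one contribution forest per peak (response = that peak's m6A level
    across the samples of ``x``) with a seed derived per peak for
    reproducibility. ``mode`` selects the magnitude score (default; see
    ``ContributionResult.contribution_magnitude``) or the signed mean.
    """
    if mode not in ("magnitude", "signed"):
        raise ValueError(f"unknown mode {mode!r}")
    peak_list = list(peaks) if peaks is not None else list(m.index)
    rows = {}
    for i, peak in enumerate(peak_list):
        y = m.loc[peak, x.index]
        res = fit_contribution_forest(x, y, n_trees=n_trees, seed=seed + i)
        rows[peak] = (
            res.contribution_magnitude if mode == "magnitude" else res.contributions
        )
    return pd.DataFrame(rows).T


def aggregate_contributions(
    contribs: pd.DataFrame,
    hyper_set,
    rbp_cols=None,
) -> pd.Series:
    """Mean per-RBP contribution restricted to hypermethylated peaks.

    ``contribs`` is peaks x predictors (one row per scored peak). Clinical
    covariate columns are excluded from the ranking via ``rbp_cols``. Ties are
    left intact; downstream ordering is name-stable.
    """
    hyper = [p for p in hyper_set]
    if not hyper:
        raise ValueError("hyper_set is empty")
    missing = set(hyper) - set(contribs.index)
    if missing:
        raise ValueError(f"hyper_set contains unscored peaks: {sorted(missing)[:5]}")
    sub = contribs.loc[hyper]
    if rbp_cols is not None:
        sub = sub[[c for c in rbp_cols if c in sub.columns]]
    agg = sub.mean(axis=0)
    return agg.sort_values(ascending=False, kind="stable")


def spearman_screen(
    rbp_expr: pd.DataFrame,
    m: pd.DataFrame,
    strata: pd.Series | None = None,
    r_min: float = 0.25,
    p_max: float = 0.05,
    min_obs: int = 5,
) -> pd.DataFrame:
    """Spearman screen of every RBP x peak pair, stratified by peak class.

    ``rbp_expr`` is samples x RBPs, ``m`` is peaks x samples, ``strata`` maps
    peak -> {hyper, hypo, unchanged}. A pair is significant when
    |rho| > r_min and p < p_max (tie-corrected t approximation, the Spearman
    convention for these sample sizes). Constant vectors and pairs with fewer
    than ``min_obs`` complete observations are skipped and logged.
    """
    samples = rbp_expr.index.intersection(m.columns)
    expr = rbp_expr.loc[samples]
    rows = []
    for peak in m.index:
        y = m.loc[peak, samples].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < min_obs or len(np.unique(y[ok])) == 1:
            logger.info("spearman_screen: peak %s skipped (constant or sparse)", peak)
            continue
        stratum = strata.get(peak, "unchanged") if strata is not None else "all"
        yr = stats.rankdata(y[ok])
        n = len(yr)
        for rbp in expr.columns:
            xv = expr.loc[samples[ok], rbp].to_numpy(dtype=float)
            if len(np.unique(xv)) == 1:
                logger.info("spearman_screen: RBP %s constant, pair skipped", rbp)
                continue
            xr = stats.rankdata(xv)
            rho = np.corrcoef(xr, yr)[0, 1]
            if abs(rho) >= 1.0:
                p = 0.0
            else:
                t = rho * math.sqrt((n - 2) / (1 - rho * rho))
                p = 2 * stats.t.sf(abs(t), df=n - 2)
            rows.append({
                "rbp": rbp, "peak": peak, "stratum": stratum,
                "rho": float(rho), "p": float(p),
                "significant": bool(abs(rho) > r_min and p < p_max),
            })
    return pd.DataFrame(rows)


def enrichment_fisher(
    sig_pairs: pd.DataFrame,
    hyper_set,
    background_set,
) -> pd.DataFrame:
    """Per-RBP over-representation of significant pairs among hyper peaks.

    For each RBP, a 2x2 table of (peak in hyper vs background) x (pair
    significant vs not) is tested one-sided (greater) with Fisher's exact
    test; BH adjustment across RBPs.
    """
    hyper = set(hyper_set)
    background = set(background_set)
    if hyper & background:
        raise ValueError("hyper_set and background_set must be disjoint")
    if not background:
        raise ValueError("background_set is empty")
    rows = []
    for rbp, grp in sig_pairs.groupby("rbp", sort=True):
        in_hyper = grp["peak"].isin(hyper)
        in_bg = grp["peak"].isin(background)
        a = int((in_hyper & grp["significant"]).sum())
        b = int((in_hyper & ~grp["significant"]).sum())
        c = int((in_bg & grp["significant"]).sum())
        d = int((in_bg & ~grp["significant"]).sum())
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({
            "rbp": rbp, "n_sig_hyper": a, "n_hyper_pairs": a + b,
            "n_sig_background": c, "n_background_pairs": c + d,
            "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
            "p": float(p),
        })
    out = pd.DataFrame(rows).set_index("rbp")
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def _minmax(s: pd.Series) -> pd.Series:
    rng = s.max() - s.min()
    if rng == 0:
        return pd.Series(0.5, index=s.index)
    return (s - s.min()) / rng


def rank_rbps(aggregates: pd.Series, enrichments: pd.DataFrame) -> pd.DataFrame:
    """Combine contribution scores with enrichment FDR into a ranking.

    Emits the scatter coordinates (-log10 FDR, contribution) plus a combined
    score: the product of the two min-max standardized axes. Ties order by
    RBP name for stability.
    """
    rbps = aggregates.index.intersection(enrichments.index)
    neg_log_fdr = -np.log10(np.maximum(enrichments.loc[rbps, "fdr"], 1e-300))
    out = pd.DataFrame({
        "contribution": aggregates.loc[rbps],
        "fdr": enrichments.loc[rbps, "fdr"],
        "neg_log10_fdr": neg_log_fdr,
        "odds_ratio": enrichments.loc[rbps, "odds_ratio"],
    })
    out["combined_score"] = _minmax(out["contribution"]) * _minmax(out["neg_log10_fdr"])
    out = (
        out.rename_axis("rbp")
        .sort_values(
            ["combined_score", "contribution", "rbp"],
            ascending=[False, False, True],
            kind="stable",
        )
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out
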