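"""Elongation rates from simulated DRB-release GRO-seq waves.

Tracks the wave peak of each gene at 10 and 25 min after release, fits the
per-gene elongation rate, checks recovery against the simulated truth, and
compares a wild-type rate distribution against a faster knockdown-like
condition with the Kolmogorov-Smirnov test.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from m6ascape.elongation import compare_rates, estimate_rates
from m6ascape.simulate import WaveSpec, simulate_groseq

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

wt = simulate_groseq(WaveSpec(n_genes=60, rate_range=(0.5, 3.0), seed=51))
rates_wt = estimate_rates(wt["profiles"])
ok = rates_wt[rates_wt.pass_filters]
rel_err = ((ok.rate_kb_per_min - wt["truth"][ok.index]).abs() / wt["truth"][ok.index])
print(f"WT: {len(ok)}/{len(rates_wt)} genes pass filters; median |relative error| "
      f"of recovered rates = {rel_err.median():.1%}.")

# knockdown-like condition: the same genes elongate ~30% faster
kd = simulate_groseq(WaveSpec(n_genes=60, seed=52,
                              rates=np.asarray(wt["truth"]) * 1.3))
rates_kd = estimate_rates(kd["profiles"])
ok_kd = rates_kd[rates_kd.pass_filters]

ks = compare_rates(ok.rate_kb_per_min, ok_kd.rate_kb_per_min)
print(f"KD vs WT rates: KS statistic {ks['statistic']:.2f}, p = {ks['p']:.2e} "
      f"(KD planted 1.3x faster).")

rates_wt.assign(condition="WT").to_csv(OUT / "07_rates_wt.tsv", sep="\t")
rates_kd.assign(condition="KD").to_csv(OUT / "07_rates_kd.tsv", sep="\t")
pd.DataFrame({"stat": ["ks_statistic", "p", "median_rel_err_wt"],
              "value": [ks["statistic"], ks["p"], rel_err.median()]}).to_csv(
    OUT / "07_summary.tsv", sep="\t", index=False)
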