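"""Cross-tissue / cross-array concordance of per-probe effect sizes.

Two checks on a pair of per-probe association result tables (e.g. blood vs
buccal EWAS of the same exposure):

* Pearson correlation of effect sizes over dataset A's top-k probes
  (selection by A's p-value, correlation computed symmetrically);
* directional consistency — the fraction of A's sub-threshold probes whose
  effect has the same sign in B, tested against 0.5 with an exact binomial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    pairs: pd.DataFrame  # probe_id, effect_a, effect_b, p_a, p_b


@dataclass
class ConsistencyResult:
    n_selected: int     # probes below threshold in A
    n_common: int       # ... with a sign-defined effect in both datasets
    n_concordant: int
    p_one_sided: float
    p_two_sided: float


def _merge(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    cols = ["probe_id", "effect", "p"]
    merged = a[cols].merge(b[cols], on="probe_id", suffixes=("_a", "_b"))
    return merged


def effect_correlation(
    results_a: pd.DataFrame, results_b: pd.DataFrame, top_k: int = 100
) -> CorrelationResult:
    """Correlate effect sizes of A's top-k probes (by p) with dataset B.

    The two-sided p-value comes from t = r·√((n−2)/(1−r²)) on n−2 df.
    """
    a = results_a.dropna(subset=["p"]).sort_values(
        ["p", "probe_id"], kind="mergesort"
    ).head(top_k)
    merged = _merge(a, results_b.dropna(subset=["effect"]))
    n = len(merged)
    if n < 3:
        raise ValueError(f"need at least 3 shared probes, got {n}")
    x = merged["effect_a"].to_numpy(dtype=float)
    y = merged["effect_b"].to_numpy(dtype=float)
    r, _ = stats.pearsonr(x, y)
    r = float(r)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, p=p, n=n, pairs=merged)


def directional_consistency_test(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    selection_p_threshold: float = 5e-05,
) -> ConsistencyResult:
    """Exact binomial test of sign agreement between two result tables.

    Probes below ``selection_p_threshold`` in A are intersected with B;
    probes with an exactly zero effect in either dataset are excluded
    (undefined sign).  One-sided p (concordance > 0.5) is primary; the
    two-sided value is also reported.
    """
    sel = results_a[results_a["p"] < selection_p_threshold]
    merged = _merge(sel, results_b)
    n_selected = len(merged)
    merged = merged[(merged["effect_a"] != 0) & (merged["effect_b"] != 0)]
    n_common = len(merged)
    if n_common == 0:
        raise ValueError("no common probes with sign-defined effects")
    concordant = int((np.sign(merged["effect_a"]) == np.sign(merged["effect_b"])).sum())
    one = stats.binomtest(concordant, n_common, 0.5, alternative="greater")
    two = stats.binomtest(concordant, n_common, 0.5, alternative="two-sided")
    return ConsistencyResult(
        n_selected=n_selected,
        n_common=n_common,
        n_concordant=concordant,
        p_one_sided=float(one.pvalue),
        p_two_sided=float(two.pvalue),
    )
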