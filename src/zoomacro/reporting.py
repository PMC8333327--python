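"""Cross-model statistics and recovery evaluation.

Kruskal-Wallis rank tests (reported with their Chi-square reference df, the
field convention) compare model explanatory power across nets or covariate
variants; Dunn's test with Bonferroni adjustment resolves which pairs
differ.  Synthetic-truth evaluation uses the adjusted Rand index between
recovered and planted response-family partitions, and the rate at which the
sign of the planted temperature effect is read back off the fitted
temperature curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .gam import GAMFit, term_significance
from .screening import CorrelationResult, spearman


@dataclass
class RankTestResult:
    statistic: float              # Kruskal-Wallis H (Chi-square scale)
    df: int
    p: float
    groups: dict[str, int]        # label -> sample size


def kruskal_wallis(samples: dict[str, np.ndarray]) -> RankTestResult:
    """Kruskal-Wallis H with the standard tie correction."""
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(v, float) for v in samples.values()]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if sum(len(a) for a in arrays) < 3:
        raise ValueError("need at least 3 values in total")
    if np.ptp(np.concatenate(arrays)) == 0:
        h, p = 0.0, 1.0      # all values tied: H degenerates to zero
    else:
        h, p = stats.kruskal(*arrays)
    return RankTestResult(statistic=float(h), df=len(arrays) - 1,
                          p=float(p),
                          groups={k: len(a) for k, a in zip(samples, arrays)})


def dunn_posthoc(samples: dict[str, np.ndarray],
                 adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise z tests on rank means with tie-corrected variance.

    Returns one row per pair: z, raw two-sided p, Bonferroni-adjusted p
    (capped at 1; the factor is the number of pairs).
    """
    labels = list(samples)
    arrays = [np.asarray(samples[g], float) for g in labels]
    arrays = [a[np.isfinite(a)] for a in arrays]
    pooled = np.concatenate(arrays)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    rank_means, sizes = {}, {}
    pos = 0
    for g, a in zip(labels, arrays):
        rank_means[g] = ranks[pos:pos + len(a)].mean()
        sizes[g] = len(a)
        pos += len(a)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term

    pairs = list(combinations(labels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (rank_means[a] - rank_means[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * m) if adjust == "bonferroni" else p_raw
        rows.append((a, b, float(z), float(p_raw), float(p_adj)))
    return pd.DataFrame(rows, columns=["group1", "group2", "z", "p_raw",
                                       "p_adjusted"])


def compare_dev(models: pd.DataFrame, grouping: str = "net_id",
                ) -> dict | None:
    """Kruskal-Wallis + Dunn on %Dev across nets or covariate variants.

    ``models`` needs columns ``pct_dev`` and the grouping column
    (``net_id`` or ``variant``).  Reports per-group medians +- IQR.
    """
    samples = {str(g): sub["pct_dev"].to_numpy(float)
               for g, sub in models.groupby(grouping, sort=True)
               if len(sub) >= 2}
    if len(samples) < 2:
        return None
    kw = kruskal_wallis(samples)
    posthoc = dunn_posthoc(samples)
    summary = {g: {"median": float(np.median(v)),
                   "iqr": float(np.subtract(*np.percentile(v, [75, 25]))),
                   "n": len(v)}
               for g, v in samples.items()}
    return {"kruskal_wallis": kw, "dunn": posthoc, "summary": summary}


def cross_net_correlation(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame,
                          value: str = "abundance", min_overlap: int = 3,
                          ) -> dict[str, CorrelationResult]:
    """Spearman rho between two nets' station-matched series, per group."""
    out: dict[str, CorrelationResult] = {}
    for group in sorted(set(metrics_a["group"]) & set(metrics_b["group"])):
        a = metrics_a[metrics_a["group"] == group].set_index("station_id")[value]
        b = metrics_b[metrics_b["group"] == group].set_index("station_id")[value]
        shared = a.index.intersection(b.index)
        if len(shared) < min_overlap:
            continue
        out[group] = spearman(a.loc[shared].to_numpy(float),
                              b.loc[shared].to_numpy(float))
    return out


def adjusted_rand_index(partition_a: dict[str, int],
                        partition_b: dict[str, int]) -> float:
    """Standard pair-counting ARI with expected-index correction."""
    if set(partition_a) != set(partition_b):
        raise ValueError("partitions must cover the same items")
    items = sorted(partition_a)
    return float(adjusted_rand_score([partition_a[i] for i in items],
                                     [partition_b[i] for i in items]))


def summarize_models(fits: list[GAMFit],
                     cluster_assignment: dict[str, int] | None = None,
                     dev_threshold: float = 0.40) -> pd.DataFrame:
    """One row per model: first-ranked term, %Dev, ranked significant terms,
    cluster id (dash below the clustering threshold)."""
    cluster_assignment = cluster_assignment or {}
    rows = []
    for fit in fits:
        sig = term_significance(fit)
        sig_terms = sig[(sig["p"] < 0.05) & (~sig["dropped"])]
        ranked = ", ".join(sig_terms["covariate"])
        first = sig_terms["covariate"].iloc[0] if len(sig_terms) else "-"
        cluster = cluster_assignment.get(fit.model_id, None)
        cluster_txt = (str(cluster) if cluster is not None
                       and fit.pct_dev > dev_threshold else "-")
        rows.append({"model_id": fit.model_id, "response": fit.response,
                     "variant": fit.variant, "first_term": first,
                     "pct_dev": round(fit.pct_dev, 4),
                     "adj_r2": round(fit.adj_r2, 4), "n_obs": fit.n_obs,
                     "significant_terms_ranked": ranked,
                     "cluster": cluster_txt})
    return pd.DataFrame(rows)


def sign_recovery_rate(fits: list[GAMFit], truth_signs: dict[str, int],
                       covariate: str = "temperature") -> float | None:
    """Share of models whose fitted temperature-curve endpoint difference
    matches the planted sign (models with null/unimodal truth excluded)."""
    from .gam import extract_curves

    hits, total = 0, 0
    for fit in fits:
        sign = truth_signs.get(fit.response, 0)
        if sign == 0:
            continue
        curves = extract_curves(fit)
        if covariate not in curves.curves:
            continue
        v = curves.curves[covariate]["value"].to_numpy(float)
        fitted_sign = np.sign(v[-1] - v[0])
        total += 1
        if fitted_sign == sign:
            hits += 1
    return hits / total if total else None
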