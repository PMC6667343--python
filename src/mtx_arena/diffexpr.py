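"""Two-group negative-binomial differential expression.

Median-of-ratios size factors normalise sequencing depth; per-feature
dispersions come from a method-of-moments fit on normalised counts pooled
within groups; a Wald test on the log2 fold change (group B over reference
group A) uses a delta-method standard error under the NB mean-variance
relation sigma^2 = mu + alpha * mu^2; p-values are Benjamini-Hochberg
adjusted. This is deliberately a plain parametric mean-variance engine,
without dispersion shrinkage or outlier handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import CountTable

__all__ = ["DEResult", "size_factors", "nb_test", "bh_adjust", "call_de"]

logger = logging.getLogger(__name__)

_DISPERSION_FLOOR = 1e-8


@dataclass
class DEResult:
    feature_id: str
    base_mean: float
    log2fc: float
    p_value: float
    p_adj: float
    call: str  # up / down / ns
    zero_in_one_group: bool = False


def size_factors(table: CountTable | pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors, rescaled to geometric
    mean 1.

    Features with a zero in any sample are excluded from the reference
    geometric means; if no all-positive feature exists, each sample's median
    ratio is taken over its own positive features (with a warning).
    """
    df = table.df if isinstance(table, CountTable) else table
    if df.shape[1] < 2:
        raise ValueError("need at least two samples")
    counts = df.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if all_positive.any():
        sub = counts[all_positive]
        log_gm = np.mean(np.log(sub), axis=1)
        ratios = np.log(sub) - log_gm[:, None]
        log_sf = np.median(ratios, axis=0)
    else:
        logger.warning("size_factors: no all-positive feature; using per-sample positive subsets")
        log_sf = np.zeros(df.shape[1])
        for j in range(df.shape[1]):
            pos = counts[:, j] > 0
            if not pos.any():
                raise ValueError(f"sample {df.columns[j]} has no positive counts")
            sub = counts[pos]
            with np.errstate(divide="ignore"):
                log_gm = np.mean(np.log(np.maximum(sub, 0.5)), axis=1)
            log_sf[j] = np.median(np.log(counts[pos, j]) - log_gm)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=df.columns)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_test(
    table: CountTable | pd.DataFrame,
    groups: dict[str, str],
    alpha: float = 0.05,
) -> list[DEResult]:
    """Wald test of group B vs reference group A on an NB count table.

    Features that are all-zero in both groups are excluded from testing
    (knockouts are never tested). Features zero in exactly one group get a
    0.5 pseudo-count for the reported fold change only and are flagged.
    """
    df = table.df if isinstance(table, CountTable) else table
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    a_samples = [s for s in df.columns if groups[s] == "A"]
    b_samples = [s for s in df.columns if groups[s] == "B"]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("each group needs at least two samples")

    sf = size_factors(df)
    norm = df.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    a_idx = [df.columns.get_loc(s) for s in a_samples]
    b_idx = [df.columns.get_loc(s) for s in b_samples]
    na, nb = len(a_idx), len(b_idx)

    norm_a = norm[:, a_idx]
    norm_b = norm[:, b_idx]
    mu_a = norm_a.mean(axis=1)
    mu_b = norm_b.mean(axis=1)
    tested = (mu_a > 0) | (mu_b > 0)

    # moment dispersion from within-group variability, floored
    ss = ((norm_a - mu_a[:, None]) ** 2).sum(axis=1) + ((norm_b - mu_b[:, None]) ** 2).sum(axis=1)
    pooled_var = ss / max(na + nb - 2, 1)
    mu_bar = (mu_a + mu_b) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (pooled_var - mu_bar) / np.square(mu_bar)
    disp = np.where(np.isfinite(disp), disp, _DISPERSION_FLOOR)
    disp = np.maximum(disp, _DISPERSION_FLOOR)

    zero_one = tested & ((mu_a == 0) | (mu_b == 0))
    # display fold change uses a 0.5 pseudo-count when one group is empty
    mu_a_fc = np.where(zero_one, mu_a + 0.5, mu_a)
    mu_b_fc = np.where(zero_one, mu_b + 0.5, mu_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mu_b_fc / mu_a_fc)

    # Wald statistic: delta-method SE of log2(mu_b/mu_a) under NB variance;
    # empty-group means are floored at a half-count continuity level
    mu_a_t = np.maximum(mu_a, 0.5 / na)
    mu_b_t = np.maximum(mu_b, 0.5 / nb)
    var_a = (mu_a_t + disp * mu_a_t**2) / na
    var_b = (mu_b_t + disp * mu_b_t**2) / nb
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt((var_a / mu_a_t**2 + var_b / mu_b_t**2) / ln2sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, np.log2(mu_b_t / mu_a_t) / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    features = list(df.index)
    tested_idx = np.nonzero(tested)[0]
    p_adj_sub = bh_adjust(p[tested_idx])
    p_adj = np.full(len(features), np.nan)
    p_adj[tested_idx] = p_adj_sub

    results: list[DEResult] = []
    base_mean = norm.mean(axis=1)
    for i in tested_idx:
        padj = float(p_adj[i])
        if padj <= alpha and log2fc[i] > 0:
            call = "up"
        elif padj <= alpha and log2fc[i] < 0:
            call = "down"
        else:
            call = "ns"
        results.append(
            DEResult(
                feature_id=features[i],
                base_mean=float(base_mean[i]),
                log2fc=float(log2fc[i]),
                p_value=float(p[i]),
                p_adj=padj,
                call=call,
                zero_in_one_group=bool(zero_one[i]),
            )
        )
    return results


def call_de(results: list[DEResult], alpha: float = 0.05) -> tuple[set[str], set[str]]:
    """(up set, down set) at the given adjusted-p threshold."""
    up = {r.feature_id for r in results if r.p_adj <= alpha and r.log2fc > 0}
    down = {r.feature_id for r in results if r.p_adj <= alpha and r.log2fc < 0}
    return up, down


def results_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "base_mean": [r.base_mean for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_value": [r.p_value for r in results],
            "p_adj": [r.p_adj for r in results],
            "call": [r.call for r in results],
        }
    )
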