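"""Desk-scale two-group negative-binomial differential expression on counts.

Normalisation uses the median-of-ratios size-factor estimator; the test is a
Wald test (normal approximation) on the difference of log group means under a
negative-binomial model with a method-of-moments gene-wise dispersion, and
multiplicity is handled by Benjamini-Hochberg.  This is a defined, testable
equivalent of the standard NB DE machinery at desk scale; exact numeric
agreement with shrinkage-based packages is not claimed or required.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import CountMatrix
from .specificity import SetReport, intersect_sets

log = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
LFC_PSEUDOCOUNT = 0.5


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, s_j is the median over genes (restricted to genes with
    a positive count in every sample, i.e. positive geometric mean) of
    k_gj / (prod_j k_gj)^(1/m).
    """
    counts = cm.counts.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; size factors are "
            "undefined — filter samples or supply factors explicitly"
        )
    logc = np.log(counts[positive])
    log_geomean = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - log_geomean, axis=0))
    return pd.Series(sf, index=cm.counts.columns, name="size_factor")


def _dispersion_mom(q: np.ndarray, groups: np.ndarray, inv_s_mean: float) -> np.ndarray:
    """Method-of-moments NB dispersion per gene from normalised counts.

    Uses the pooled within-group variance so planted group differences do not
    inflate the estimate: alpha = (var_w - m * mean(1/s)) / m^2, floored.
    """
    n = q.shape[1]
    parts = []
    dof = 0
    for g in np.unique(groups):
        sub = q[:, groups == g]
        if sub.shape[1] >= 2:
            parts.append(sub.var(axis=1, ddof=1) * (sub.shape[1] - 1))
            dof += sub.shape[1] - 1
    var_w = sum(parts) / dof
    m = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_w - m * inv_s_mean) / np.square(m)
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return np.maximum(alpha, DISPERSION_FLOOR)


def nb_two_group_test(
    cm: CountMatrix,
    group: Mapping[str, str],
    sf: pd.Series | None = None,
    group_a: str = "adipose",
) -> pd.DataFrame:
    """Wald test of equal group means on normalised counts, per gene.

    ``group`` maps each sample to one of two labels; ``group_a`` names the
    numerator group (log2 fold changes are group_a over the other group, with
    a pseudo-count of 0.5 on the normalised means).  Returns a data frame
    with columns gene_id, base_mean, log2_fold_change, p_value.  All-zero
    genes get p = 1 and log2FC = 0.
    """
    labels = pd.Series({s: group[s] for s in cm.sample_ids})
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two group labels required, got {uniq}")
    if group_a not in uniq:
        raise ValueError(f"group_a={group_a!r} not among labels {uniq}")
    in_a = (labels == group_a).to_numpy()
    if in_a.sum() < 2 or (~in_a).sum() < 2:
        raise ValueError("each group needs >= 2 samples")

    if sf is None:
        sf = size_factors(cm)
    s = sf.loc[cm.sample_ids].to_numpy(dtype=float)
    if (s <= 0).any():
        raise ValueError("size factors must be positive")

    q = cm.counts.to_numpy(dtype=float) / s[None, :]
    groups = in_a.astype(int)
    alpha = _dispersion_mom(q, groups, inv_s_mean=float(np.mean(1.0 / s)))

    mu_a = q[:, in_a].mean(axis=1) + LFC_PSEUDOCOUNT
    mu_b = q[:, ~in_a].mean(axis=1) + LFC_PSEUDOCOUNT
    n_a, n_b = int(in_a.sum()), int((~in_a).sum())

    # Var(mean of normalised counts) under NB: (1/n^2) sum_j (mu/s_j + alpha mu^2);
    # delta method gives se(log mu)^2 = Var(mean)/mu^2.
    inv_s_a = np.sum(1.0 / s[in_a])
    inv_s_b = np.sum(1.0 / s[~in_a])
    se2_a = (inv_s_a / mu_a + n_a * alpha) / n_a**2
    se2_b = (inv_s_b / mu_b + n_b * alpha) / n_b**2

    delta = np.log(mu_a) - np.log(mu_b)
    z = delta / np.sqrt(se2_a + se2_b)
    # the dispersion is estimated with n_a + n_b - 2 residual df, so the Wald
    # statistic is referred to a t distribution on that df rather than the
    # normal; with plug-in method-of-moments dispersions the normal reference
    # is anti-conservative at small n while the t reference is calibrated
    p = 2.0 * stats.t.sf(np.abs(z), df=n_a + n_b - 2)

    all_zero = (cm.counts.to_numpy() == 0).all(axis=1)
    lfc = delta / np.log(2.0)
    lfc[all_zero] = 0.0
    p[all_zero] = 1.0

    return pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "base_mean": q.mean(axis=1),
            "log2_fold_change": lfc,
            "p_value": p,
        }
    )


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    arr = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    if arr.size == 0:
        return arr
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def differential_expression(
    cm: CountMatrix,
    adipose_labels: Iterable[str],
    alpha: float = 0.05,
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Adipose-vs-rest DE table with BH adjustment and direction calls.

    Samples whose tissue is in ``adipose_labels`` form the adipose group; all
    other samples form the non-adipose group.  ``direction`` is 'higher' /
    'lower' for significant genes (padj < alpha) by fold-change sign, else 'ns'.
    """
    adipose = set(adipose_labels)
    group = {
        s: ("adipose" if cm.sample_tissue[s] in adipose else "other")
        for s in cm.sample_ids
    }
    res = nb_two_group_test(cm, group, sf=sf, group_a="adipose")
    res["p_adjusted"] = bh_adjust(res["p_value"].to_numpy())
    sig = res["p_adjusted"] < alpha
    res["direction"] = np.where(
        sig & (res["log2_fold_change"] > 0),
        "higher",
        np.where(sig & (res["log2_fold_change"] < 0), "lower", "ns"),
    )
    log.info(
        "differential expression: %d higher, %d lower of %d genes (padj < %g)",
        int((res["direction"] == "higher").sum()),
        int((res["direction"] == "lower").sum()),
        len(res),
        alpha,
    )
    return res


def call_heg(results: pd.DataFrame, alpha: float = 0.05) -> tuple[set[str], set[str]]:
    """Split a DE table into (higher, lower) significant gene sets."""
    sig = results["p_adjusted"] < alpha
    higher = set(results.loc[sig & (results["log2_fold_change"] > 0), "gene_id"])
    lower = set(results.loc[sig & (results["log2_fold_change"] < 0), "gene_id"])
    return higher, lower


def intersect_tsg_heg(tsg: Mapping[str, set[str]], heg: set[str]) -> SetReport:
    """Region/intersection cardinalities of per-tissue TSG sets against the HEG set."""
    named = dict(tsg)
    named["HEG"] = set(heg)
    return intersect_sets(named)
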