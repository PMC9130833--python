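"""Population-genetic diversity of a biallelic indel and genotype-trait association.

Diversity statistics follow the classical allele-frequency formulas: with
p = freq(D) and q = 1 - p,

    homozygosity        sum p_i^2 = p^2 + q^2
    expected heterozygosity 1 - sum p_i^2
    effective allele number 1 / sum p_i^2
    PIC (biallelic)     1 - sum p_i^2 - 2 p^2 q^2

Published diversity tables for this marker class often label the homozygosity
column "Ho" and the effective allele number "Ne"; fields here are named by
their formulas, and :func:`diversity_table` emits columns in the conventional
(Ho, Ne, PIC) order for comparison with such tables.

Association uses an independent-sample t-test per genotype pair, with groups
of fewer than ``min_n`` individuals excluded and the pooled/Welch variant
gated by a mean-centred Levene test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GENOTYPES, GenotypeTable, TraitTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def counts_from_frequencies(freqs: Sequence[float], n: int) -> tuple[int, int, int]:
    """Reconstruct integer genotype counts from printed frequencies and n.

    Rounds freq*n per class; a unit discrepancy in the total is absorbed by
    the class with the largest rounding remainder (largest-remainder rule).
    Frequencies off by more than one count after adjustment are rejected.
    """
    freqs = np.asarray(freqs, dtype=float)
    if (freqs < 0).any():
        raise ValueError("genotype frequencies must be non-negative")
    if abs(freqs.sum() - 1.0) > 0.01:
        raise ValueError(f"genotype frequencies sum to {freqs.sum():.4f}, not ~1")
    if n < 1:
        raise ValueError("n must be >= 1")
    raw = freqs * n
    counts = np.rint(raw)
    diff = n - counts.sum()
    if abs(diff) > 1:
        raise ValueError(
            f"frequencies irreconcilable with n={n}: rounded counts off by {diff:+.0f}"
        )
    if diff != 0:
        counts[np.argmax(diff * (raw - counts))] += diff
    return tuple(int(c) for c in counts)


def genotype_table_from_frequencies(
    population: str, freqs: Sequence[float], n: int
) -> GenotypeTable:
    return GenotypeTable(population, counts_from_frequencies(freqs, n))


def allele_frequencies(gt: GenotypeTable) -> tuple[float, float]:
    """(p_D, p_I) from genotype counts: p_D = (2 n_DD + n_ID) / 2n."""
    n_dd, n_id, _ = gt.counts
    p_d = (2 * n_dd + n_id) / (2 * gt.n)
    return p_d, 1.0 - p_d


def hwe_chi_square(gt: GenotypeTable) -> tuple[float, int, float, bool]:
    """Chi-square goodness-of-fit against Hardy-Weinberg proportions.

    Expected counts (n p^2, 2 n p q, n q^2) use the observed allele
    frequencies; df = 1 (three classes, one estimated frequency).  Returns
    (chi2, df, p, low_expected_warning) where the flag marks an expected
    class below 1 (the approximation is then unreliable).
    """
    p, q = allele_frequencies(gt)
    expected = np.array([gt.n * p * p, 2 * gt.n * p * q, gt.n * q * q])
    observed = np.asarray(gt.counts, dtype=float)
    mask = expected > 0
    chi2 = float((np.square(observed[mask] - expected[mask]) / expected[mask]).sum())
    pval = float(stats.chi2.sf(chi2, df=1))
    low = bool((expected[mask] < 1).any())
    if low:
        log.warning("%s: an expected genotype class is < 1; chi-square p is unreliable",
                    gt.population)
    return chi2, 1, pval, low


@dataclass
class DiversityStats:
    """Allele-frequency diversity summary for one population."""

    population: str
    n: int
    p_d: float
    p_i: float
    homozygosity: float            # sum p_i^2 ("Ho" column of marker tables)
    expected_heterozygosity: float  # 1 - sum p_i^2
    effective_alleles: float       # 1 / sum p_i^2 ("Ne" column)
    pic: float
    hwe_chi2: float
    hwe_df: int
    hwe_p: float
    hwe_low_expected: bool


def diversity_stats(gt: GenotypeTable) -> DiversityStats:
    """Homozygosity, heterozygosity, effective allele number, PIC and HWE.

    All quantities derive from allele frequencies computed on the integer
    genotype counts.  A monomorphic table is degenerate but defined:
    homozygosity 1, effective alleles 1, PIC 0.
    """
    p, q = allele_frequencies(gt)
    hom = p * p + q * q
    pic = 1.0 - hom - 2.0 * p * p * q * q
    chi2, df, hwe_p, low = hwe_chi_square(gt)
    return DiversityStats(
        population=gt.population,
        n=gt.n,
        p_d=p,
        p_i=q,
        homozygosity=hom,
        expected_heterozygosity=1.0 - hom,
        effective_alleles=1.0 / hom,
        pic=pic,
        hwe_chi2=chi2,
        hwe_df=df,
        hwe_p=hwe_p,
        hwe_low_expected=low,
    )


def diversity_table(tables: Iterable[GenotypeTable], decimals: int = 3) -> pd.DataFrame:
    """Per-population diversity summary in conventional column order.

    ``Ho``/``Ne`` follow the marker-table convention (homozygosity and
    effective allele number respectively; see the module docstring).
    """
    rows = []
    for gt in tables:
        d = diversity_stats(gt)
        rows.append(
            {
                "population": d.population,
                "n": d.n,
                "freq_DD": round(gt.counts[0] / gt.n, decimals),
                "freq_ID": round(gt.counts[1] / gt.n, decimals),
                "freq_II": round(gt.counts[2] / gt.n, decimals),
                "p_D": round(d.p_d, decimals),
                "p_I": round(d.p_i, decimals),
                "Ho": round(d.homozygosity, decimals),
                "Ne": round(d.effective_alleles, decimals),
                "PIC": round(d.pic, decimals),
                "HWE_chi2": round(d.hwe_chi2, decimals),
                "HWE_p": round(d.hwe_p, decimals),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------

def levene_center_mean(groups: Sequence[np.ndarray | Sequence[float]]) -> float:
    """Mean-centred Levene test p-value for equality of group variances.

    One-way ANOVA on absolute deviations from group means; if every group has
    zero within-group variance the test is vacuous and p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("Levene test needs >= 2 groups of >= 2 values")
    if all(a.var() == 0 for a in arrays):
        return 1.0
    stat, p = stats.levene(*arrays, center="mean")
    return 1.0 if np.isnan(p) else float(p)


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    variant: str


def ttest_from_summary(
    mean1: float, se1: float, n1: int,
    mean2: float, se2: float, n2: int,
    variant: str = "pooled",
) -> TTestResult:
    """Independent two-sample t-test from (mean, SE, n) summaries.

    ``pooled`` uses the classical equal-variance statistic with
    df = n1 + n2 - 2; ``welch`` uses t = dmean / sqrt(se1^2 + se2^2) with
    Welch-Satterthwaite df.  SD is recovered as SE * sqrt(n).
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be > 0")
    sd1, sd2 = se1 * np.sqrt(n1), se2 * np.sqrt(n2)
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = n1 + n2 - 2.0
    else:
        v1, v2 = se1**2, se2**2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TTestResult(float(t), float(df), float(p), variant)


def associate(
    traits: TraitTable,
    min_n: int = 3,
    stratify_by_sex: bool = True,
    levene_alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise genotype-trait association within each (sex, trait) stratum.

    Genotype groups with fewer than ``min_n`` individuals are excluded; for
    each remaining genotype pair a mean-centred Levene test selects the
    pooled (levene_p >= levene_alpha) or Welch variant, and both per-group
    summaries and the test are reported.  Strata with fewer than two eligible
    groups are skipped with a log entry.
    """
    df = traits.records
    strata = ["sex", "trait"] if stratify_by_sex else ["trait"]
    rows = []
    for keys, sub in df.groupby(strata, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        groups = {
            g: sub.loc[sub["genotype"] == g, "value"].to_numpy(dtype=float)
            for g in GENOTYPES
            if (sub["genotype"] == g).sum() >= min_n
        }
        if len(groups) < 2:
            log.info("stratum %s: fewer than two genotype groups with n >= %d; skipped",
                     keys, min_n)
            continue
        names = [g for g in GENOTYPES if g in groups]
        for i, g1 in enumerate(names):
            for g2 in names[i + 1 :]:
                a, b = groups[g1], groups[g2]
                lev_p = levene_center_mean([a, b])
                variant = "pooled" if lev_p >= levene_alpha else "welch"
                t, p = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
                if variant == "pooled":
                    dof = len(a) + len(b) - 2.0
                else:
                    v1, v2 = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
                    dof = (v1 + v2) ** 2 / (v1**2 / (len(a) - 1) + v2**2 / (len(b) - 1))
                row = {
                    "trait": keys[-1],
                    "sex": keys[0] if stratify_by_sex else "all",
                    "genotype_1": g1,
                    "genotype_2": g2,
                    "levene_p": lev_p,
                    "variance_rule": variant,
                    "t": float(t),
                    "df": float(dof),
                    "p": float(p),
                }
                for tag, arr in (("1", a), ("2", b)):
                    row[f"mean_{tag}"] = arr.mean()
                    row[f"se_{tag}"] = arr.std(ddof=1) / np.sqrt(len(arr))
                    row[f"n_{tag}"] = len(arr)
                rows.append(row)
    return pd.DataFrame(rows)
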