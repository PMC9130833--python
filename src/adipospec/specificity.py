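"""The tau tissue-specificity index and the three-rule tissue-specific-gene caller.

tau for a gene with per-tissue mean expression x_1..x_N is

    tau = sum_i (1 - x_i / max_j x_j) / (N - 1)

so tau = 0 for a perfectly uniform profile and tau = 1 when expression is
confined to a single tissue.  Candidates are the top fraction of genes by
tau (default 20%); a candidate is then called specific to a tissue when its
mean FPKM there exceeds ``fpkm_min`` (default 1, strict) AND that tissue
ranks within the top ``rank_k`` (default 3) of the gene's profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data_model import AnnotationTable, BIOTYPE_CLASSES, TissueProfileMatrix
from .synthetic_data import TruthLabels


@dataclass
class TsgCall:
    """Per-gene specificity call: tau, candidate flag, called tissues."""

    gene_id: str
    tau: float
    candidate: bool
    specific_tissues: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.specific_tissues and not self.candidate:
            raise ValueError("a non-candidate gene cannot carry specific tissues")
        if not math.isnan(self.tau) and not 0 <= self.tau <= 1 + 1e-12:
            raise ValueError(f"tau out of [0, 1]: {self.tau}")


def tau(profile: np.ndarray | Iterable[float]) -> float:
    """Tissue-specificity index of a per-tissue mean expression vector.

    Permutation- and scale-invariant; returns NaN for an all-zero profile
    (such genes cannot be candidates and are excluded upstream by the
    expression filter anyway).
    """
    x = np.asarray(list(profile) if not isinstance(profile, np.ndarray) else profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a 1-D vector over >= 2 tissues")
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    m = x.max()
    if m == 0:
        return float("nan")
    return float((1.0 - x / m).sum() / (x.size - 1))


def tau_table(tp: TissueProfileMatrix, log2p1: bool = False) -> pd.Series:
    """tau per gene over the tissue-mean matrix.

    ``log2p1`` applies log2(x+1) before the index (off by default: the index
    is computed on raw tissue-mean FPKM).
    """
    vals = tp.means.to_numpy(dtype=float)
    if log2p1:
        vals = np.log2(vals + 1.0)
    m = vals.max(axis=1)
    out = np.full(vals.shape[0], np.nan)
    ok = m > 0
    out[ok] = (1.0 - vals[ok] / m[ok, None]).sum(axis=1) / (vals.shape[1] - 1)
    return pd.Series(out, index=tp.means.index, name="tau")


def candidates_by_tau(tp: TissueProfileMatrix, top_fraction: float = 0.20,
                      log2p1: bool = False) -> set[str]:
    """The ceil(top_fraction * G) genes of highest tau.

    Boundary ties are resolved deterministically: genes with tau strictly above
    the boundary value are all included, remaining slots filled in lexicographic
    gene-id order among boundary-tied genes (achieved by sorting on
    (-tau, gene_id)).  All-zero-profile genes (tau undefined) are excluded.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    taus = tau_table(tp, log2p1=log2p1).dropna()
    k = math.ceil(top_fraction * len(taus))
    order = sorted(taus.items(), key=lambda kv: (-kv[1], kv[0]))
    return {g for g, _ in order[:k]}


def call_tissue_specific(
    candidates: set[str],
    tp: TissueProfileMatrix,
    fpkm_min: float = 1.0,
    rank_k: int = 3,
    log2p1_tau: bool = False,
) -> list[TsgCall]:
    """Apply the FPKM > fpkm_min AND top-``rank_k`` rule to candidate genes.

    Ranks are dense and descending, so tissues tied at rank ``rank_k`` are all
    admitted; "more than" is strict.  Non-candidate genes are returned with an
    empty call set.  A gene may be specific to up to ``rank_k`` tissues (more
    only under ties).
    """
    unknown = candidates - set(tp.gene_ids)
    if unknown:
        raise ValueError(f"candidate genes absent from the profile matrix: {sorted(unknown)[:5]}")
    taus = tau_table(tp, log2p1=log2p1_tau)
    ranks = tp.means.rank(axis=1, method="dense", ascending=False)
    passing = (tp.means > fpkm_min) & (ranks <= rank_k)
    calls: list[TsgCall] = []
    for gene in tp.gene_ids:
        is_cand = gene in candidates
        tissues = frozenset(tp.means.columns[passing.loc[gene]]) if is_cand else frozenset()
        calls.append(TsgCall(gene, float(taus[gene]), is_cand, tissues))
    return calls


def per_tissue_sets(calls: Iterable[TsgCall]) -> dict[str, set[str]]:
    """Tissue label -> set of genes called specific to that tissue."""
    sets: dict[str, set[str]] = {}
    for c in calls:
        for t in c.specific_tissues:
            sets.setdefault(t, set()).add(c.gene_id)
    return sets


def biotype_composition(genes: set[str], ann: AnnotationTable) -> dict[str, float]:
    """Proportion of each biotype class within a gene set (sums to 1)."""
    if not genes:
        raise ValueError("biotype composition of an empty gene set is undefined")
    missing = [g for g in genes if g not in ann]
    if missing:
        raise ValueError(f"genes without annotation: {sorted(missing)[:5]}")
    counts = {b: 0 for b in BIOTYPE_CLASSES}
    for g in genes:
        counts[ann[g]] += 1
    n = len(genes)
    return {b: counts[b] / n for b in BIOTYPE_CLASSES}


@dataclass
class SetReport:
    """Exclusive-region and intersection cardinalities over named gene sets."""

    sets: dict[str, set[str]]
    regions: dict[frozenset[str], int] = field(init=False)
    intersections: dict[frozenset[str], int] = field(init=False)
    union_size: int = field(init=False)

    def __post_init__(self) -> None:
        names = list(self.sets)
        if len(names) < 2:
            raise ValueError("a set report needs >= 2 named sets")
        universe = set().union(*self.sets.values())
        membership = {e: frozenset(n for n in names if e in self.sets[n]) for e in universe}
        self.regions = {}
        self.intersections = {}
        # all 2^k - 1 non-empty name subsets
        from itertools import combinations

        for r in range(1, len(names) + 1):
            for combo in combinations(names, r):
                key = frozenset(combo)
                self.regions[key] = sum(1 for m in membership.values() if m == key)
                inter = set.intersection(*(self.sets[n] for n in combo))
                self.intersections[key] = len(inter)
        self.union_size = len(universe)

    def region(self, *names: str) -> int:
        """Elements in exactly these sets and no others."""
        return self.regions[frozenset(names)]

    def intersection(self, *names: str) -> int:
        """Elements in all of these sets (regardless of others)."""
        return self.intersections[frozenset(names)]

    def biotype_breakdown(self, ann: AnnotationTable) -> dict[str, dict[str, float]]:
        return {
            name: biotype_composition(s, ann) for name, s in self.sets.items() if s
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sets": "&".join(sorted(k)),
                "exclusive_region": self.regions[k],
                "intersection": self.intersections[k],
            }
            for k in sorted(self.regions, key=lambda k: (len(k), "&".join(sorted(k))))
        ]
        return pd.DataFrame(rows)


def intersect_sets(named_sets: Mapping[str, set[str]]) -> SetReport:
    """Region and intersection cardinalities for >= 2 named gene sets."""
    return SetReport(dict(named_sets))


def evaluate_tsg_recovery(calls: Iterable[TsgCall], truth: TruthLabels) -> dict[str, float]:
    """Score the caller's tissue assignments against planted ground truth.

    Precision and recall are computed over the planted genes' (gene, tissue)
    assignments: recall is the fraction of planted pairs recovered, precision
    the fraction of calls made on planted genes that hit a planted pair (i.e.
    how accurately the caller localises genuinely specific genes).  Calls on
    non-planted genes are reported separately as ``background_genes_called``
    and ``background_pairs_called``: the top-fraction candidate rule admits a
    fixed share of the filtered panel, so some background genes are always
    screened and a whole-call-set precision is governed by that fraction
    rather than by the caller's accuracy.
    """
    true_pairs = truth.specific_pairs
    planted_genes = truth.specific_genes
    called_pairs = {(c.gene_id, t) for c in calls for t in c.specific_tissues}
    planted_calls = {(g, t) for g, t in called_pairs if g in planted_genes}
    background_calls = called_pairs - planted_calls
    tp = len(planted_calls & true_pairs)
    precision = tp / len(planted_calls) if planted_calls else float("nan")
    recall = tp / len(true_pairs) if true_pairs else float("nan")
    overall_precision = tp / len(called_pairs) if called_pairs else float("nan")
    return {
        "precision": precision,
        "recall": recall,
        "n_true_pairs": len(true_pairs),
        "n_planted_calls": len(planted_calls),
        "background_genes_called": len({g for g, _ in background_calls}),
        "background_pairs_called": len(background_calls),
        "overall_pair_precision": overall_precision,
    }
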