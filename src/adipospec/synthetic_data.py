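"""Seeded generators for every input the pipeline consumes.

The generators emulate the structure of a 14-tissue bovine expression study
(three adipose depots plus eleven other tissues, 2-11 replicates each), a
matched read-count matrix for the adipose-vs-rest differential-expression
stage, biallelic indel genotype tables, genotype-dependent carcass traits,
and a small qPCR Ct table.  Every generator is a pure function of its
configuration and seed; planted structure is recorded in :class:`TruthLabels`
so downstream callers can be validated against ground truth.

Planting scheme
---------------
A configurable fraction of genes is planted tissue-specific: near-silent in
every tissue except one home tissue, where expression is multiplied by
``specific_boost`` (tissue-specific genes in real atlases are exactly this
pattern: strong in their home tissue, trace elsewhere).  A further
``n_shared_adipose`` genes are planted specific in all three adipose depots
simultaneously, mimicking a shared adipose expression program; in the counts
simulation the same genes carry the planted adipose fold change, so the
"specific AND higher-expressed in adipose" core is a known gene set.
Background genes follow a log-normal expression distribution in which the
majority of the panel sits below the FPKM=1 screening filter, as in
whole-annotation screens where pseudogenes and most non-coding classes are
not captured by poly(A) libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    BIOTYPE_CLASSES,
    GENOTYPES,
    AnnotationTable,
    CountMatrix,
    CtTable,
    ExpressionMatrix,
    GenotypeTable,
    TraitTable,
)

DEFAULT_TISSUES = (
    "visceral_adipose",
    "subcutaneous_adipose",
    "intramuscular_adipose",
    "muscle",
    "heart",
    "liver",
    "spleen",
    "lung",
    "kidney",
    "skin",
    "brain",
    "cerebellum",
    "pituitary",
    "small_intestine",
)

ADIPOSE_TISSUES = DEFAULT_TISSUES[:3]

# RNG sub-stream tags, so each generator draws from an independent stream of
# the same seed and the planted truth is shared between expression and counts.
_STREAM_TRUTH = 0
_STREAM_EXPR = 1
_STREAM_COUNTS = 2
_STREAM_LAYOUT = 3


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generators.

    Expression parameters are on the natural-log FPKM scale.  Defaults mirror
    the screened study design: 14 tissues with 2-11 replicates, ~5% planted
    tissue-specific genes at a 50x home-tissue boost, a 23-gene core shared
    across the three adipose depots (16 protein-coding + 7 lncRNA), a
    genome-wide biotype mix of roughly 59/15/2/24% (protein-coding / lncRNA /
    miRNA / other), negative-binomial counts with dispersion 0.1 and a planted
    4-fold adipose change.
    """

    n_genes: int = 2000
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    adipose_tissues: tuple[str, ...] = ADIPOSE_TISSUES
    replicates_range: tuple[int, int] = (2, 11)
    fraction_specific: float = 0.05
    n_shared_adipose: int = 23
    biotype_mix: tuple[float, float, float, float] = (0.589, 0.147, 0.023, 0.241)
    # planted tissue-specific genes are lncRNA-enriched (non-coding genes show
    # higher tissue specificity in expression atlases)
    specific_biotype_mix: tuple[float, float, float, float] = (0.55, 0.30, 0.02, 0.13)
    baseline_log_fpkm_mean: float = -1.1  # median background FPKM ~ 0.33
    baseline_log_fpkm_sd: float = 1.5
    tissue_effect_sd: float = 0.35
    replicate_noise_sd: float = 0.25
    specific_boost: float = 50.0
    off_tissue_log_mean: float = -2.3  # planted genes ~ FPKM 0.1 outside home
    off_tissue_log_sd: float = 0.5
    nb_dispersion: float = 0.1
    de_fold_change: float = 4.0
    n_de_background: int = 77  # planted DE genes beyond the shared adipose core
    count_base_log_mean: float = 4.6  # median base count ~ 100
    count_base_log_sd: float = 1.0
    library_size_log_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_specific <= 1:
            raise ValueError("fraction_specific must be in [0, 1]")
        if abs(sum(self.biotype_mix) - 1) > 0.05 or abs(sum(self.specific_biotype_mix) - 1) > 0.05:
            raise ValueError("biotype mixes must sum to ~1")
        if self.specific_boost <= 1 or (self.de_fold_change < 1):
            raise ValueError("specific_boost must be > 1 and de_fold_change >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        lo, hi = self.replicates_range
        if not (1 <= lo <= hi):
            raise ValueError("replicates_range must satisfy 1 <= lo <= hi")
        n_planted = self.n_shared_adipose + int(round(self.fraction_specific * self.n_genes))
        if n_planted + self.n_de_background > self.n_genes:
            raise ValueError(
                f"infeasible config: {n_planted} planted-specific plus "
                f"{self.n_de_background} background-DE genes exceed n_genes={self.n_genes}"
            )
        if not set(self.adipose_tissues) <= set(self.tissues):
            raise ValueError("adipose_tissues must be a subset of tissues")

    @property
    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]


@dataclass
class TruthLabels:
    """Planted ground truth, reconciled exactly with the emitted matrices."""

    table: pd.DataFrame  # gene_id, biotype, specific_tissues (tuple), is_de, true_log2fc

    @property
    def specific_pairs(self) -> set[tuple[str, str]]:
        """All planted (gene, home tissue) assignments."""
        pairs: set[tuple[str, str]] = set()
        for gene, tissues in zip(self.table["gene_id"], self.table["specific_tissues"]):
            pairs.update((gene, t) for t in tissues)
        return pairs

    @property
    def specific_genes(self) -> set[str]:
        return {g for g, t in zip(self.table["gene_id"], self.table["specific_tissues"]) if t}

    @property
    def shared_adipose_genes(self) -> set[str]:
        return {
            g
            for g, t in zip(self.table["gene_id"], self.table["specific_tissues"])
            if len(t) >= 3
        }

    @property
    def de_genes(self) -> set[str]:
        return set(self.table.loc[self.table["is_de"], "gene_id"])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["specific_tissues"] = [";".join(t) for t in out["specific_tissues"]]
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def plant_truth(cfg: SimConfig) -> TruthLabels:
    """Assign planted roles and biotypes; shared between generators.

    Gene order of planted roles is drawn from a dedicated RNG stream so that
    :func:`simulate_expression` and :func:`simulate_counts` agree on which
    genes carry which planted structure for the same config.
    """
    rng = _rng(cfg, _STREAM_TRUTH)
    genes = cfg.gene_ids
    n_single = int(round(cfg.fraction_specific * cfg.n_genes))
    order = rng.permutation(cfg.n_genes)
    shared_idx = order[: cfg.n_shared_adipose]
    single_idx = order[cfg.n_shared_adipose : cfg.n_shared_adipose + n_single]
    de_bg_idx = order[
        cfg.n_shared_adipose + n_single : cfg.n_shared_adipose + n_single + cfg.n_de_background
    ]

    specific: list[tuple[str, ...]] = [() for _ in range(cfg.n_genes)]
    for i in shared_idx:
        specific[i] = tuple(cfg.adipose_tissues)
    # single-tissue planted genes rotate round-robin over all tissues
    for k, i in enumerate(single_idx):
        specific[i] = (cfg.tissues[k % len(cfg.tissues)],)

    is_de = np.zeros(cfg.n_genes, dtype=bool)
    lfc = np.zeros(cfg.n_genes)
    if cfg.de_fold_change > 1:
        is_de[shared_idx] = True
        lfc[shared_idx] = np.log2(cfg.de_fold_change)
        is_de[de_bg_idx] = True
        # background DE genes split between higher and lower in adipose
        signs = np.where(np.arange(len(de_bg_idx)) % 2 == 0, 1.0, -1.0)
        lfc[de_bg_idx] = signs * np.log2(cfg.de_fold_change)

    mix = np.asarray(cfg.biotype_mix, dtype=float)
    mix /= mix.sum()
    biotype = rng.choice(BIOTYPE_CLASSES, size=cfg.n_genes, p=mix).astype(object)
    smix = np.asarray(cfg.specific_biotype_mix, dtype=float)
    smix /= smix.sum()
    biotype[single_idx] = rng.choice(BIOTYPE_CLASSES, size=len(single_idx), p=smix)
    # the shared adipose core mirrors the screened composition:
    # 16 protein-coding + 7 lncRNA at the default size, proportional otherwise
    n_pc = int(round(len(shared_idx) * 16 / 23))
    for k, i in enumerate(shared_idx):
        biotype[i] = "protein_coding" if k < n_pc else "lncRNA"

    table = pd.DataFrame(
        {
            "gene_id": genes,
            "biotype": biotype,
            "specific_tissues": specific,
            "is_de": is_de,
            "true_log2fc": lfc,
        }
    )
    return TruthLabels(table)


def _sample_layout(cfg: SimConfig) -> tuple[list[str], dict[str, str]]:
    """Draw replicate counts per tissue and build sample ids + tissue map."""
    rng = _rng(cfg, _STREAM_LAYOUT)
    lo, hi = cfg.replicates_range
    reps = rng.integers(lo, hi + 1, size=len(cfg.tissues))
    sample_ids: list[str] = []
    sample_tissue: dict[str, str] = {}
    for tissue, r in zip(cfg.tissues, reps):
        for i in range(int(r)):
            sid = f"{tissue}_r{i + 1}"
            sample_ids.append(sid)
            sample_tissue[sid] = tissue
    return sample_ids, sample_tissue


def simulate_expression(cfg: SimConfig) -> tuple[ExpressionMatrix, AnnotationTable, TruthLabels]:
    """Simulate the FPKM matrix with planted tissue-specific genes.

    Background genes: log-normal baseline per gene, log-normal tissue effect,
    log-normal replicate noise.  Planted genes: a low off-tissue level times
    ``specific_boost`` in the home tissue(s).  Deterministic for a fixed
    config (which includes the seed).
    """
    truth = plant_truth(cfg)
    rng = _rng(cfg, _STREAM_EXPR)
    sample_ids, sample_tissue = _sample_layout(cfg)
    tissue_index = {t: k for k, t in enumerate(cfg.tissues)}
    G, T = cfg.n_genes, len(cfg.tissues)

    baseline = rng.normal(cfg.baseline_log_fpkm_mean, cfg.baseline_log_fpkm_sd, size=G)
    off_level = rng.normal(cfg.off_tissue_log_mean, cfg.off_tissue_log_sd, size=G)
    tissue_effect = rng.normal(0.0, cfg.tissue_effect_sd, size=(G, T))

    log_level = baseline[:, None] + tissue_effect
    planted_rows = truth.table["specific_tissues"].to_numpy()
    for g in range(G):
        homes = planted_rows[g]
        if homes:
            log_level[g, :] = off_level[g] + tissue_effect[g, :]
            for t in homes:
                log_level[g, tissue_index[t]] += np.log(cfg.specific_boost)

    col_tissue = np.array([tissue_index[sample_tissue[s]] for s in sample_ids])
    noise = rng.normal(0.0, cfg.replicate_noise_sd, size=(G, len(sample_ids)))
    values = np.exp(log_level[:, col_tissue] + noise)

    em = ExpressionMatrix(
        pd.DataFrame(values, index=cfg.gene_ids, columns=sample_ids),
        dict(sample_tissue),
    )
    ann = AnnotationTable(dict(zip(truth.table["gene_id"], truth.table["biotype"])))
    return em, ann, truth


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, TruthLabels]:
    """Simulate NB read counts with a planted adipose-vs-rest fold change.

    Gene-level base means are log-normal; each sample carries a log-normal
    library-size factor; genes flagged DE in the truth labels have their mean
    multiplied by ``de_fold_change ** sign`` in the adipose samples.  With
    ``de_fold_change == 1`` the truth has no DE genes.
    """
    truth = plant_truth(cfg)
    rng = _rng(cfg, _STREAM_COUNTS)
    sample_ids, sample_tissue = _sample_layout(cfg)
    G = cfg.n_genes
    n_samples = len(sample_ids)
    adipose = np.array([sample_tissue[s] in cfg.adipose_tissues for s in sample_ids])

    base = np.exp(rng.normal(cfg.count_base_log_mean, cfg.count_base_log_sd, size=G))
    size_factor = np.exp(rng.normal(0.0, cfg.library_size_log_sd, size=n_samples))
    fold = np.exp2(truth.table["true_log2fc"].to_numpy())  # 1 for non-DE genes

    mu = base[:, None] * size_factor[None, :]
    mu = np.where(adipose[None, :], mu * fold[:, None], mu)

    r = 1.0 / cfg.nb_dispersion  # NB number-of-successes parameterisation
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    cm = CountMatrix(
        pd.DataFrame(counts, index=cfg.gene_ids, columns=sample_ids),
        dict(sample_tissue),
    )
    return cm, truth


def simulate_genotypes(
    p: float,
    n: int,
    f: float = 0.0,
    seed: int = 0,
    population: str = "synthetic",
) -> GenotypeTable:
    """Draw genotype counts for a biallelic indel.

    ``p`` is the D (deletion) allele frequency; ``f`` is an inbreeding-like
    deviation from Hardy-Weinberg proportions: genotype probabilities are
    (p^2 + f p q, 2 p q (1 - f), q^2 + f p q), truncated at zero and
    renormalised, then drawn from a multinomial.
    """
    if not 0 < p < 1:
        raise ValueError("allele frequency p must be in (0, 1)")
    if not -1 <= f <= 1:
        raise ValueError("deviation f must be in [-1, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    q = 1 - p
    probs = np.array([p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q])
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs)
    return GenotypeTable(population, tuple(int(c) for c in counts))


def expand_genotypes(gt: GenotypeTable) -> list[str]:
    """Per-individual genotype labels from a count table (DD..., ID..., II...)."""
    labels: list[str] = []
    for g, c in zip(GENOTYPES, gt.counts):
        labels.extend([g] * c)
    return labels


def simulate_traits(
    genotypes: Sequence[str],
    effects: dict[str, float],
    sd: float,
    seed: int = 0,
    base: float = 10.0,
    trait_name: str = "trait",
    sexes: Sequence[str] | None = None,
) -> TraitTable:
    """Simulate trait values ``base + effect[genotype] + N(0, sd)``.

    Raises if a genotype label is missing from the effects map.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    missing = sorted(set(genotypes) - set(effects))
    if missing:
        raise ValueError(f"genotypes without an effect entry: {missing}")
    rng = np.random.default_rng(seed)
    n = len(genotypes)
    values = base + np.array([effects[g] for g in genotypes]) + rng.normal(0.0, sd, size=n)
    if sexes is None:
        sexes = ["unknown"] * n
    df = pd.DataFrame(
        {
            "individual_id": [f"ind{i + 1:04d}" for i in range(n)],
            "sex": list(sexes),
            "genotype": list(genotypes),
            "trait": trait_name,
            "value": values,
        }
    )
    return TraitTable(df)


def simulate_ct_table(
    genes: Sequence[str],
    tissues: Sequence[str],
    relative_log2: np.ndarray,
    reference_gene: str = "GAPDH",
    n_replicates: int = 3,
    noise_sd: float = 0.1,
    target_base_ct: float = 26.0,
    reference_ct: float = 16.0,
    seed: int = 0,
) -> CtTable:
    """Simulate a long-format qPCR Ct table.

    ``relative_log2[i, j]`` is the true log2 expression of gene i in tissue j
    relative to the first tissue; a one-unit increase lowers the target Ct by
    one cycle.  The reference gene is emitted for every (sample, tissue).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for j, tissue in enumerate(tissues):
        sample = f"{tissue}_pool"
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample": sample,
                    "tissue": tissue,
                    "gene": reference_gene,
                    "replicate": rep,
                    "ct": reference_ct + rng.normal(0, noise_sd),
                }
            )
            for i, gene in enumerate(genes):
                rows.append(
                    {
                        "sample": sample,
                        "tissue": tissue,
                        "gene": gene,
                        "replicate": rep,
                        "ct": target_base_ct - relative_log2[i, j] + rng.normal(0, noise_sd),
                    }
                )
    return CtTable(pd.DataFrame(rows), reference_gene=reference_gene,
                   calibrator_tissue=tissues[0])
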