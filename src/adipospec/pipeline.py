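"""End-to-end orchestration: simulate -> tsg -> de -> profiles -> qpcr -> popgen.

Every stage reads and writes plain TSV under one output directory, logs its
parameter values and in/out gene counts (so the screening funnel is
auditable), and the run ends with a JSON manifest listing parameters, the
seed, and a SHA-256 checksum of every output file.  Identical config + seed
produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_model as dm
from . import diffexpr, popgen, profiles, qpcr, specificity
from .synthetic_data import (
    SimConfig,
    expand_genotypes,
    simulate_counts,
    simulate_ct_table,
    simulate_expression,
    simulate_genotypes,
    simulate_traits,
)

log = logging.getLogger(__name__)

STAGES = ("simulate", "tsg", "de", "profiles", "qpcr", "popgen")

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """All paths, stage toggles and thresholds for one pipeline run."""

    out_dir: str = "adipospec_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # analysis thresholds (defaults are the screening pipeline's conventions)
    fpkm_min: float = 1.0
    top_fraction: float = 0.20
    rank_k: int = 3
    alpha: float = 0.05
    min_n: int = 3
    k_mads: float = 3.0
    # synthetic-data design; keys override SimConfig fields
    sim: dict = field(default_factory=dict)
    # synthetic genotype populations: name -> {p, n, f}
    populations: dict = field(
        default_factory=lambda: {
            "pop_large": {"p": 0.9, "n": 516, "f": 0.0},
            "pop_small": {"p": 0.65, "n": 59, "f": 0.0},
        }
    )
    trait_effects: dict = field(
        default_factory=lambda: {"DD": 0.0, "ID": 1.0, "II": 2.0}
    )
    trait_sd: float = 1.0
    qpcr_target: str = "target_gene"
    # input paths used when the simulate stage is disabled
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fpkm_min <= 0 or self.rank_k < 1 or self.min_n < 1 or self.k_mads < 0:
            raise ValueError("threshold out of documented range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_df(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, **kw)


def _require(out: Path, names: list[str], stage: str) -> None:
    missing = [n for n in names if not (out / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"stage '{stage}' needs upstream outputs {missing}; enable the "
            "producing stage or point 'inputs' at existing files"
        )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; return the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "parameters": {
            "fpkm_min": cfg.fpkm_min,
            "top_fraction": cfg.top_fraction,
            "rank_k": cfg.rank_k,
            "alpha": cfg.alpha,
            "min_n": cfg.min_n,
            "k_mads": cfg.k_mads,
        },
        "outputs": {},
    }

    def register(stage: str, *paths: Path) -> None:
        manifest["outputs"].setdefault(stage, {})
        for p in paths:
            manifest["outputs"][stage][p.name] = _sha256(p)

    # resolve external inputs for disabled-simulate runs
    for name, src in cfg.inputs.items():
        dest = out / name
        if not dest.exists():
            dest.write_bytes(Path(src).read_bytes())

    sim_cfg = cfg.sim_config()

    if "simulate" in cfg.stages:
        em, ann, truth = simulate_expression(sim_cfg)
        cm, _ = simulate_counts(sim_cfg)
        dm.write_expression_matrix(em, out / "fpkm.tsv", out / "sample_map.tsv")
        dm.write_count_matrix(cm, out / "counts.tsv")
        dm.write_gene_annotation_gff3(ann.biotypes, out / "annotation.gff3")
        truth.to_tsv(out / "truth.tsv")

        tables = [
            simulate_genotypes(spec["p"], spec["n"], spec.get("f", 0.0),
                               seed=cfg.seed + 11, population=name)
            for name, spec in cfg.populations.items()
        ]
        dm.write_genotype_tables(tables, out / "genotypes.tsv")
        first = tables[0]
        tt = simulate_traits(
            expand_genotypes(first), cfg.trait_effects, cfg.trait_sd,
            seed=cfg.seed + 13, trait_name="carcass_weight",
        )
        dm.write_trait_table(tt, out / "traits.tsv")

        tissues = list(sim_cfg.tissues[:4])
        rel = np.vstack([np.arange(len(tissues), dtype=float)])  # 2x per tissue step
        ct = simulate_ct_table([cfg.qpcr_target], tissues, rel, seed=cfg.seed + 17)
        dm.write_ct_table(ct, out / "ct.tsv")
        register("simulate", *(out / n for n in (
            "fpkm.tsv", "sample_map.tsv", "counts.tsv", "annotation.gff3",
            "truth.tsv", "genotypes.tsv", "traits.tsv", "ct.tsv")))
        log.info("simulate: %d genes x %d samples", *em.values.shape)

    if "tsg" in cfg.stages:
        _require(out, ["fpkm.tsv", "sample_map.tsv", "annotation.gff3"], "tsg")
        em = dm.read_expression_matrix(out / "fpkm.tsv", out / "sample_map.tsv")
        ann = dm.read_gene_annotation(out / "annotation.gff3")
        tp = dm.tissue_means(em)
        filtered = dm.filter_low_expression(tp, cfg.fpkm_min)
        log.info("tsg: %d genes in, %d after FPKM filter", len(tp.gene_ids), len(filtered.gene_ids))
        cand = specificity.candidates_by_tau(filtered, cfg.top_fraction)
        calls = specificity.call_tissue_specific(cand, filtered, cfg.fpkm_min, cfg.rank_k)
        taus = specificity.tau_table(filtered)
        _write_df(taus.reset_index().rename(columns={"index": "gene_id"}), out / "tau.tsv")
        call_rows = [
            {"gene_id": c.gene_id, "tissue": t}
            for c in calls for t in sorted(c.specific_tissues)
        ]
        _write_df(pd.DataFrame(call_rows, columns=["gene_id", "tissue"]), out / "tsg_calls.tsv")
        sets = specificity.per_tissue_sets(calls)
        adipose = [t for t in sim_cfg.adipose_tissues if t in sets]
        if len(adipose) >= 2:
            report = specificity.intersect_sets({t: sets[t] for t in adipose})
            _write_df(report.to_frame(), out / "tsg_set_report.tsv")
            (out / "tsg_set_report.json").write_text(json.dumps(
                {"&".join(sorted(k)): v for k, v in report.intersections.items()},
                indent=2, sort_keys=True) + "\n")
            register("tsg", out / "tsg_set_report.tsv", out / "tsg_set_report.json")
        register("tsg", out / "tau.tsv", out / "tsg_calls.tsv")

    if "de" in cfg.stages:
        _require(out, ["counts.tsv", "sample_map.tsv"], "de")
        cm = dm.read_count_matrix(out / "counts.tsv", out / "sample_map.tsv")
        res = diffexpr.differential_expression(cm, sim_cfg.adipose_tissues, cfg.alpha)
        _write_df(res, out / "de_results.tsv")
        register("de", out / "de_results.tsv")
        if (out / "tsg_calls.tsv").exists():
            calls_df = pd.read_csv(out / "tsg_calls.tsv", sep="\t")
            sets = {
                t: set(g["gene_id"]) for t, g in calls_df.groupby("tissue")
                if t in sim_cfg.adipose_tissues
            }
            if len(sets) >= 1:
                higher, _lower = diffexpr.call_heg(res, cfg.alpha)
                report = diffexpr.intersect_tsg_heg(sets, higher)
                _write_df(report.to_frame(), out / "tsg_heg_report.tsv")
                register("de", out / "tsg_heg_report.tsv")

    if "profiles" in cfg.stages:
        _require(out, ["fpkm.tsv", "sample_map.tsv"], "profiles")
        em = dm.read_expression_matrix(out / "fpkm.tsv", out / "sample_map.tsv")
        tp = dm.tissue_means(em)
        logtp = profiles.log2p1(tp)
        gene_set = None
        if (out / "tsg_calls.tsv").exists():
            calls_df = pd.read_csv(out / "tsg_calls.tsv", sep="\t")
            gene_set = set(calls_df["gene_id"])
        corr = profiles.tissue_correlations(logtp, genes=gene_set)
        _write_df(corr, out / "correlations.tsv")
        screen = profiles.pca_outlier_screen(em, cfg.k_mads)
        _write_df(screen, out / "pca_outliers.tsv")
        z, labels = profiles.cluster_tissues(logtp, genes=gene_set)
        (out / "tissue_dendrogram.nwk").write_text(profiles.dendrogram_newick(z, labels) + "\n")
        register("profiles", out / "correlations.tsv", out / "pca_outliers.tsv",
                 out / "tissue_dendrogram.nwk")

    if "qpcr" in cfg.stages:
        _require(out, ["ct.tsv"], "qpcr")
        ct = dm.read_ct_table(out / "ct.tsv", reference_gene="GAPDH",
                              calibrator_tissue=None)
        tissues = list(ct.records["tissue"].drop_duplicates())
        rel = qpcr.delta_delta_ct(ct, cfg.qpcr_target, "GAPDH", tissues[0])
        _write_df(rel, out / "qpcr_relative.tsv")
        register("qpcr", out / "qpcr_relative.tsv")

    if "popgen" in cfg.stages:
        _require(out, ["genotypes.tsv", "traits.tsv"], "popgen")
        tables = dm.read_genotype_tables(out / "genotypes.tsv")
        _write_df(popgen.diversity_table(tables), out / "diversity.tsv")
        tt = dm.read_trait_table(out / "traits.tsv")
        assoc = popgen.associate(tt, min_n=cfg.min_n, stratify_by_sex=False)
        _write_df(assoc, out / "association.tsv")
        register("popgen", out / "diversity.tsv", out / "association.tsv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
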