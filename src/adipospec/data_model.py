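"""Typed containers and TSV/GFF3 readers-writers for every file the pipeline touches.

The pipeline's entry object is an :class:`ExpressionMatrix` (genes x samples,
FPKM) plus a sample -> tissue map; replicate averaging turns it into a
:class:`TissueProfileMatrix`, the substrate for the tau index and the
tissue-specific-gene caller.  Count matrices feed the differential-expression
stage, genotype/trait tables the population-genetics stage, and Ct tables the
qPCR stage.

All tabular formats are plain TSV; gene annotation is GFF3 with a
``gene_biotype`` attribute collapsed onto four classes
(protein_coding / lncRNA / miRNA / other).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

BIOTYPE_CLASSES = ("protein_coding", "lncRNA", "miRNA", "other")

#: raw GFF3 biotype values accepted for each collapsed class
_BIOTYPE_SYNONYMS = {
    "protein_coding": "protein_coding",
    "lncRNA": "lncRNA",
    "lnc_RNA": "lncRNA",
    "miRNA": "miRNA",
}

GENOTYPES = ("DD", "ID", "II")


class DataModelError(ValueError):
    """Raised when an input file or container violates its invariants."""


def _check_matrix(values: pd.DataFrame, *, what: str, integral: bool = False) -> None:
    if values.index.has_duplicates:
        raise DataModelError(f"{what}: duplicate gene identifiers")
    if values.columns.has_duplicates:
        raise DataModelError(f"{what}: duplicate sample identifiers")
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise DataModelError(f"{what}: non-numeric values present")
    if np.isnan(arr).any():
        g, s = np.argwhere(np.isnan(arr))[0]
        raise DataModelError(
            f"{what}: missing value for gene {values.index[g]!r} in sample "
            f"{values.columns[s]!r}; missing data are not permitted"
        )
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise DataModelError(
            f"{what}: negative value {arr[g, s]} for gene {values.index[g]!r} "
            f"in sample {values.columns[s]!r}"
        )
    if integral and not np.array_equal(arr, np.floor(arr)):
        g, s = np.argwhere(arr != np.floor(arr))[0]
        raise DataModelError(
            f"{what}: non-integral count {arr[g, s]} for gene "
            f"{values.index[g]!r} in sample {values.columns[s]!r}"
        )


def _check_sample_map(sample_ids: Sequence[str], sample_tissue: Mapping[str, str]) -> None:
    missing = [s for s in sample_ids if s not in sample_tissue]
    if missing:
        raise DataModelError(f"samples without a tissue label: {missing}")


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM matrix with a sample -> tissue assignment.

    ``values`` carries gene ids on the index and sample ids on the columns;
    entries are non-negative FPKM.  Every sample must have a tissue label.
    """

    values: pd.DataFrame
    sample_tissue: dict[str, str]

    def __post_init__(self) -> None:
        _check_matrix(self.values, what="expression matrix")
        _check_sample_map(self.values.columns, self.sample_tissue)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        """Tissue labels in order of first appearance over the sample columns."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_tissue[s], None)
        return list(seen)

    def samples_of(self, tissue: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_tissue[s] == tissue]


@dataclass
class CountMatrix:
    """Genes x samples raw read-count matrix (non-negative integers)."""

    counts: pd.DataFrame
    sample_tissue: dict[str, str]

    def __post_init__(self) -> None:
        _check_matrix(self.counts, what="count matrix", integral=True)
        _check_sample_map(self.counts.columns, self.sample_tissue)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, tissue: str) -> list[str]:
        return [s for s in self.counts.columns if self.sample_tissue[s] == tissue]


@dataclass
class TissueProfileMatrix:
    """Genes x tissues matrix of replicate-averaged mean FPKM."""

    means: pd.DataFrame

    def __post_init__(self) -> None:
        _check_matrix(self.means, what="tissue profile matrix")
        if self.means.shape[1] < 2:
            raise DataModelError("tissue profile matrix needs >= 2 tissues")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.means.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.means.columns)

    @property
    def n_tissues(self) -> int:
        return self.means.shape[1]


@dataclass
class AnnotationTable:
    """gene_id -> collapsed biotype class (one of :data:`BIOTYPE_CLASSES`)."""

    biotypes: dict[str, str]

    def __post_init__(self) -> None:
        bad = {b for b in self.biotypes.values() if b not in BIOTYPE_CLASSES}
        if bad:
            raise DataModelError(f"unknown biotype classes: {sorted(bad)}")

    def __getitem__(self, gene_id: str) -> str:
        return self.biotypes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.biotypes

    def __len__(self) -> int:
        return len(self.biotypes)


@dataclass
class GenotypeTable:
    """Per-population genotype counts for a biallelic indel (DD / ID / II)."""

    population: str
    counts: tuple[int, int, int]  # (n_DD, n_ID, n_II)

    def __post_init__(self) -> None:
        if any(c < 0 or c != int(c) for c in self.counts):
            raise DataModelError(f"{self.population}: genotype counts must be non-negative integers")
        self.counts = tuple(int(c) for c in self.counts)
        if self.n < 1:
            raise DataModelError(f"{self.population}: at least one individual required")

    @property
    def n(self) -> int:
        return sum(self.counts)


@dataclass
class TraitTable:
    """Long-format per-individual genotype + trait records.

    Columns: individual_id, sex, genotype (DD/ID/II), trait, value.
    """

    records: pd.DataFrame

    REQUIRED = ("individual_id", "sex", "genotype", "trait", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise DataModelError(f"trait table missing columns: {missing}")
        bad = set(self.records["genotype"]) - set(GENOTYPES)
        if bad:
            raise DataModelError(f"trait table has genotypes outside {GENOTYPES}: {sorted(bad)}")
        vals = self.records["value"].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise DataModelError("trait table contains non-finite values")


@dataclass
class CtTable:
    """Long-format qPCR cycle-threshold records.

    Columns: sample, tissue, gene, replicate, ct.  The reference gene and
    calibrator tissue are designated when the table is built (or at call
    time in :func:`adipospec.qpcr.delta_delta_ct`).
    """

    records: pd.DataFrame
    reference_gene: str | None = None
    calibrator_tissue: str | None = None

    REQUIRED = ("sample", "tissue", "gene", "replicate", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise DataModelError(f"Ct table missing columns: {missing}")
        ct = self.records["ct"].to_numpy(dtype=float)
        if not np.isfinite(ct).all():
            raise DataModelError("Ct table contains non-finite Ct values")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_sample_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (sample, tissue) with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataModelError(f"{path}: sample map needs 2 columns (sample, tissue)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_sample_map(sample_tissue: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(sample_tissue), "tissue": list(sample_tissue.values())}
    ).to_csv(path, sep="\t", index=False)


def _read_gene_by_sample(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return df


def read_expression_matrix(path: str | Path, sample_map: str | Path) -> ExpressionMatrix:
    """Read an FPKM TSV (header = sample ids, first column = gene id) plus a sample map."""
    return ExpressionMatrix(_read_gene_by_sample(path), read_sample_map(sample_map))


def write_expression_matrix(em: ExpressionMatrix, path: str | Path,
                            sample_map_path: str | Path | None = None) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")
    if sample_map_path is not None:
        write_sample_map(em.sample_tissue, sample_map_path)


def read_count_matrix(path: str | Path, sample_map: str | Path) -> CountMatrix:
    df = _read_gene_by_sample(path)
    return CountMatrix(df, read_sample_map(sample_map))


def write_count_matrix(cm: CountMatrix, path: str | Path,
                       sample_map_path: str | Path | None = None) -> None:
    cm.counts.astype(int).to_csv(path, sep="\t", index_label="gene_id")
    if sample_map_path is not None:
        write_sample_map(cm.sample_tissue, sample_map_path)


def collapse_biotype(raw: str | None) -> str:
    """Collapse a raw GFF3 biotype onto the four analysis classes."""
    if raw is None:
        return "other"
    return _BIOTYPE_SYNONYMS.get(raw, "other")


def read_gene_annotation(path: str | Path) -> AnnotationTable:
    """Read gene biotypes from a GFF3 file.

    Uses the ``gene_biotype`` attribute of ``gene`` features, falling back to
    ``biotype``.  A gene feature without either attribute is classed ``other``
    with a logged warning, not a failure.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    biotypes: dict[str, str] = {}
    for feat in db.features_of_type("gene"):
        raw = feat.attributes.get("gene_biotype") or feat.attributes.get("biotype")
        if raw is None:
            log.warning("gene %s has no gene_biotype/biotype attribute; classing as 'other'", feat.id)
            biotypes[feat.id] = "other"
        else:
            biotypes[feat.id] = collapse_biotype(raw[0])
    return AnnotationTable(biotypes)


def write_gene_annotation_gff3(biotypes: Mapping[str, str], path: str | Path,
                               seqid: str = "chr1", feature_span: int = 1000) -> None:
    """Write a minimal GFF3 with one ``gene`` feature per entry.

    Coordinates are synthetic placeholders; only the ``ID`` and
    ``gene_biotype`` attributes are meaningful downstream.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, (gene, biotype) in enumerate(biotypes.items()):
            start = 1 + i * (feature_span + 10)
            end = start + feature_span - 1
            fh.write(
                f"{seqid}\tadipospec\tgene\t{start}\t{end}\t.\t+\t.\t"
                f"ID={gene};gene_biotype={biotype}\n"
            )


def read_genotype_tables(path: str | Path) -> list[GenotypeTable]:
    """Read a TSV with columns population, n_DD, n_ID, n_II."""
    df = pd.read_csv(path, sep="\t")
    needed = ["population", "n_DD", "n_ID", "n_II"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DataModelError(f"{path}: genotype table missing columns {missing}")
    return [
        GenotypeTable(str(r["population"]), (int(r["n_DD"]), int(r["n_ID"]), int(r["n_II"])))
        for _, r in df.iterrows()
    ]


def write_genotype_tables(tables: Iterable[GenotypeTable], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"population": t.population, "n_DD": t.counts[0], "n_ID": t.counts[1], "n_II": t.counts[2]}
            for t in tables
        ]
    ).to_csv(path, sep="\t", index=False)


def read_trait_table(path: str | Path) -> TraitTable:
    return TraitTable(pd.read_csv(path, sep="\t"))


def write_trait_table(tt: TraitTable, path: str | Path) -> None:
    tt.records.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ct_table(path: str | Path, reference_gene: str | None = None,
                  calibrator_tissue: str | None = None) -> CtTable:
    return CtTable(pd.read_csv(path, sep="\t"), reference_gene, calibrator_tissue)


def write_ct_table(ct: CtTable, path: str | Path) -> None:
    ct.records.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# replicate averaging and the low-expression filter
# ---------------------------------------------------------------------------

def tissue_means(em: ExpressionMatrix) -> TissueProfileMatrix:
    """Average replicate samples within each tissue (arithmetic mean of FPKM).

    Tissue column order follows first appearance of each tissue over the
    sample columns; the result is invariant to sample order within a tissue.
    """
    cols = {t: em.values[em.samples_of(t)].mean(axis=1) for t in em.tissues}
    return TissueProfileMatrix(pd.DataFrame(cols, index=em.values.index))


def filter_low_expression(tp: TissueProfileMatrix, threshold: float = 1.0) -> TissueProfileMatrix:
    """Drop genes whose mean FPKM is below ``threshold`` in every tissue.

    A gene is retained iff its maximum over tissues is >= threshold, i.e. a
    gene exactly at the boundary in one tissue is kept; removal requires the
    gene to be strictly below the threshold everywhere.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    keep = tp.means.max(axis=1) >= threshold
    kept = tp.means.loc[keep]
    log.info("low-expression filter: %d of %d genes retained (threshold=%g)",
             keep.sum(), len(keep), threshold)
    if kept.empty:
        log.warning("low-expression filter removed every gene")
    return TissueProfileMatrix(kept)
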