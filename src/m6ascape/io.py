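"""Readers, writers and validated in-memory containers.

Every pipeline stage exchanges data through the five containers defined
here: an expression matrix (genes x samples, log2 scale), a clinical table
(overall survival plus covariates), a gene-set collection (GMT), a somatic
mutation table (MAF subset) and a per-gene copy-number call table.  All
containers validate their invariants on construction; malformed input is a
hard error, never a silent coercion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ParseError",
    "SchemaError",
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "MutationTable",
    "CNVCallTable",
    "VARIANT_CLASSES",
    "CNV_CALLS",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "read_maf",
    "write_maf",
    "read_cnv",
    "write_cnv",
    "harmonize_samples",
]


class ValidationError(ValueError):
    """An input violates a container invariant."""


class ParseError(ValueError):
    """A file's contents cannot be interpreted in its declared format."""


class SchemaError(ValueError):
    """A file lacks a mandatory column or header."""


#: Controlled vocabulary for somatic variant classifications.
VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "frame_shift_del",
    "frame_shift_ins",
    "in_frame_del",
    "in_frame_ins",
    "splice_site",
    "multi_hit",
    "other",
)

#: Standard MAF terms mapped onto the controlled vocabulary.
_MAF_CLASS_MAP = {
    "missense_mutation": "missense",
    "nonsense_mutation": "nonsense",
    "nonstop_mutation": "nonsense",
    "frame_shift_del": "frame_shift_del",
    "frame_shift_ins": "frame_shift_ins",
    "in_frame_del": "in_frame_del",
    "in_frame_ins": "in_frame_ins",
    "splice_site": "splice_site",
    "splice_region": "splice_site",
    "multi_hit": "multi_hit",
}

CNV_CALLS = ("loss", "neutral", "gain")

_MANDATORY_CLINICAL = ("sample_id", "os_time", "os_event")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """A genes x samples real matrix, log2 scale expected.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by gene id, columns by sample id; all entries finite.
    batch : Series, optional
        Per-sample batch/cohort label aligned to the columns.
    """

    values: pd.DataFrame
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.index, "gene id")
        _check_unique(self.values.columns, "sample id")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float, copy=False)).all():
            bad = np.argwhere(~np.isfinite(arr.astype(float)))
            g, s = bad[0]
            raise ValidationError(
                "non-finite expression value at gene "
                f"{self.values.index[g]!r}, sample {self.values.columns[s]!r}; "
                "missing values must be resolved upstream"
            )
        self.values = self.values.astype(float)
        if self.batch is not None:
            self.batch = pd.Series(self.batch)
            if not self.batch.index.equals(self.values.columns):
                self.batch = self.batch.reindex(self.values.columns)
                if self.batch.isna().any():
                    raise ValidationError("batch labels do not cover all samples")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes], self.batch)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        batch = self.batch.loc[samples] if self.batch is not None else None
        return ExpressionMatrix(self.values.loc[:, samples], batch)


@dataclass
class ClinicalTable:
    """Per-sample survival outcome plus covariates and external scores.

    ``df`` carries one row per sample with mandatory columns ``sample_id``,
    ``os_time`` (days, non-negative) and ``os_event`` (0/1); any further
    columns are preserved verbatim as covariates/extras.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df)
        for col in _MANDATORY_CLINICAL:
            if col not in df.columns:
                raise SchemaError(f"clinical table lacks mandatory column {col!r}")
        _check_unique(df["sample_id"].astype(str), "sample id")
        os_time = pd.to_numeric(df["os_time"], errors="coerce")
        if os_time.isna().any() or (os_time < 0).any():
            raise ValidationError("os_time must be numeric and >= 0")
        os_event = pd.to_numeric(df["os_event"], errors="coerce")
        if os_event.isna().any() or not os_event.isin([0, 1]).all():
            raise ValidationError("os_event must be 0 or 1")
        df = df.copy()
        df["os_time"] = os_time.astype(float)
        df["os_event"] = os_event.astype(int)
        df["sample_id"] = df["sample_id"].astype(str)
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in _MANDATORY_CLINICAL]

    def aligned_to(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        """Reorder (and subset) rows to the given sample order."""
        sub = self.df.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return ClinicalTable(sub)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, non-empty member lists."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            _check_unique(genes, f"gene in set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def restricted_to(self, universe: Iterable[str], min_size: int = 2) -> "GeneSetCollection":
        """Intersect every set with *universe*; drop sets below *min_size*."""
        universe = set(universe)
        kept: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            present = [g for g in genes if g in universe]
            if len(present) >= min_size:
                kept[name] = present
            else:
                logger.warning(
                    "gene set %s reduced to %d genes on this matrix; skipped",
                    name, len(present),
                )
        return GeneSetCollection(kept, {k: v for k, v in self.descriptions.items() if k in kept})


@dataclass
class MutationTable:
    """Somatic mutation records: (sample_id, gene_id, variant_classification)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        for col in ("sample_id", "gene_id", "variant_classification"):
            if col not in df.columns:
                raise SchemaError(f"mutation table lacks column {col!r}")
        bad = ~df["variant_classification"].isin(VARIANT_CLASSES)
        if bad.any():
            raise ValidationError(
                "variant classifications outside controlled vocabulary: "
                f"{sorted(df.loc[bad, 'variant_classification'].unique())[:5]}"
            )
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())


@dataclass
class CNVCallTable:
    """Per-(sample, gene) copy-number call in {loss, neutral, gain}."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        for col in ("sample_id", "gene_id", "call"):
            if col not in df.columns:
                raise SchemaError(f"CNV table lacks column {col!r}")
        if not df["call"].isin(CNV_CALLS).all():
            bad = sorted(set(df["call"]) - set(CNV_CALLS))
            raise ValidationError(f"CNV calls outside vocabulary: {bad[:5]}")
        if df.duplicated(subset=["sample_id", "gene_id"]).any():
            raise ValidationError("multiple CNV calls for the same (sample, gene)")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(
    path: str | Path, format: str = "tsv", log2_offset: bool = False
) -> ExpressionMatrix:
    """Read a gene x sample expression matrix from TSV or GCT (#1.2).

    TSV: header row of sample ids, first column gene ids.  GCT: the two
    standard header lines (``#1.2`` then declared dims), a Name/Description
    column pair, then the data block.  ``log2_offset`` applies log2(x+1) on
    load for raw counts/TPM input; expression is otherwise assumed to be on
    log2 scale already.
    """
    path = Path(path)
    if format not in ("tsv", "gct"):
        raise ValueError(f"unknown expression format {format!r}")
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    else:
        with open(path) as fh:
            magic = fh.readline().strip()
            if not magic.startswith("#1.2"):
                raise ParseError(f"{path}: not a GCT 1.2 file (first line {magic!r})")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise ParseError(f"{path}: malformed GCT dimension line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=["Description"], errors="ignore")
        if df.shape != (n_genes, n_samples):
            raise ParseError(
                f"{path}: GCT declares {n_genes}x{n_samples} but data block is "
                f"{df.shape[0]}x{df.shape[1]}"
            )
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicated gene rows")
    try:
        values = df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any() and not df[col].isna().any():
                row = df.index[coerced.isna().argmax()]
                raise ParseError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        raise
    if log2_offset:
        values = np.log2(values + 1.0)
    return ExpressionMatrix(values)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene...`` per line."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "%s:%d: %d duplicate genes in set %s removed",
                    path, lineno, len(genes) - len(deduped), name,
                )
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets:
            desc = sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV; unknown columns are preserved as covariates."""
    df = pd.read_csv(path, sep="\t")
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.df.to_csv(path, sep="\t", index=False)


def read_maf(path: str | Path) -> MutationTable:
    """Read a MAF-dialect TSV (case-insensitive header match).

    Only Hugo_Symbol, Tumor_Sample_Barcode and Variant_Classification are
    required; other MAF columns are ignored.  Standard MAF variant terms are
    mapped onto the controlled vocabulary; unmapped terms become ``other``
    with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    lower = {c.lower(): c for c in df.columns}
    needed = {"hugo_symbol": "gene_id", "tumor_sample_barcode": "sample_id",
              "variant_classification": "variant_classification"}
    missing = [k for k in needed if k not in lower]
    if missing:
        raise SchemaError(f"{path}: MAF lacks mandatory column(s) {missing}")
    out = pd.DataFrame({
        new: df[lower[old]].astype(str) for old, new in needed.items()
    })
    raw = out["variant_classification"].str.lower()
    mapped = raw.map(_MAF_CLASS_MAP)
    unmapped = mapped.isna() & raw.notna()
    if unmapped.any():
        for term in sorted(out.loc[unmapped, "variant_classification"].unique()):
            logger.warning("%s: variant classification %r mapped to 'other'", path, term)
        mapped = mapped.fillna("other")
    out["variant_classification"] = mapped
    return MutationTable(out[["sample_id", "gene_id", "variant_classification"]])


_MAF_WRITE_MAP = {
    "missense": "Missense_Mutation",
    "nonsense": "Nonsense_Mutation",
    "frame_shift_del": "Frame_Shift_Del",
    "frame_shift_ins": "Frame_Shift_Ins",
    "in_frame_del": "In_Frame_Del",
    "in_frame_ins": "In_Frame_Ins",
    "splice_site": "Splice_Site",
    "multi_hit": "Multi_Hit",
    "other": "Other",
}


def write_maf(mut: MutationTable, path: str | Path) -> None:
    df = pd.DataFrame({
        "Hugo_Symbol": mut.records["gene_id"],
        "Tumor_Sample_Barcode": mut.records["sample_id"],
        "Variant_Classification": mut.records["variant_classification"].map(_MAF_WRITE_MAP),
    })
    df.to_csv(path, sep="\t", index=False)


def read_cnv(path: str | Path) -> CNVCallTable:
    df = pd.read_csv(path, sep="\t")
    return CNVCallTable(df)


def write_cnv(cnv: CNVCallTable, path: str | Path) -> None:
    cnv.records.to_csv(path, sep="\t", index=False)


def harmonize_samples(
    expr: ExpressionMatrix, clinical: ClinicalTable
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Intersect sample ids across expression and clinical tables.

    Order follows the expression matrix; dropped ids are logged.
    """
    shared = [s for s in expr.sample_ids if s in set(clinical.sample_ids)]
    dropped_e = sorted(set(expr.sample_ids) - set(shared))
    dropped_c = sorted(set(clinical.sample_ids) - set(shared))
    if dropped_e:
        logger.info("harmonize: %d expression-only samples dropped: %s",
                    len(dropped_e), dropped_e[:5])
    if dropped_c:
        logger.info("harmonize: %d clinical-only samples dropped: %s",
                    len(dropped_c), dropped_c[:5])
    if not shared:
        raise ValidationError("no shared samples between expression and clinical tables")
    return expr.subset_samples(shared), clinical.aligned_to(shared)
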