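"""Readers and writers for the formats the pipeline touches.

Conventions
-----------
All coordinates are stored 0-based half-open internally (the BED convention);
GFF3's 1-based inclusive coordinates are converted at the I/O boundary only.
Library (column) order in count tables is always taken from the sample sheet,
never from file order, so downstream results are permutation invariant.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CROSSES",
    "WITHIN_SPECIES_CROSSES",
    "HYBRID_CROSSES",
    "ASSAYS",
    "STRUCTURAL_RNA_CLASSES",
    "RNA_CLASSES",
    "DICER_CALLS",
    "GeneFeature",
    "SrnaCluster",
    "SampleSheet",
    "CountTable",
    "read_gff3",
    "write_gff3",
    "read_bed_clusters",
    "write_bed_clusters",
    "read_sample_sheet",
    "read_counts",
    "write_counts",
    "load_yaml_config",
]

#: Cross codes: first letter = maternal species (P = S. peruvianum, C = S. chilense).
CROSSES = ("PP", "CC", "PC", "CP")
WITHIN_SPECIES_CROSSES = ("PP", "CC")
HYBRID_CROSSES = ("PC", "CP")
ASSAYS = ("endosperm-mRNA", "seed-sRNA")

#: Structural / housekeeping non-coding RNA classes removed before DE testing.
STRUCTURAL_RNA_CLASSES = frozenset(
    {"antisense", "rRNA", "tRNA", "snoRNA", "snRNA", "SRPRNA"}
)
RNA_CLASSES = STRUCTURAL_RNA_CLASSES | {"clean", "miRNA_annotated"}
DICER_CALLS = ("21", "22", "24", "miRNA", "none")


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True, order=True)
class GeneFeature:
    """A gene interval, 0-based half-open.

    ``annotation_label`` is the curated family/annotation used for physical
    gene-cluster calling; ``biotype`` gates flank-assignment eligibility.
    """

    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str = "."
    annotation_label: str = ""
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"{self.gene_id}: empty chrom")
        if not self.start < self.end:
            raise ValueError(
                f"{self.gene_id}: start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class SrnaCluster:
    """A small-RNA cluster interval (0-based half-open) with its size-class
    (DicerCall: predominant read length) and RNA-class labels."""

    chrom: str
    start: int
    end: int
    cluster_id: str
    dicer_call: str = "none"
    rna_class: str = "clean"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"{self.cluster_id}: empty chrom")
        if not self.start < self.end:
            raise ValueError(
                f"{self.cluster_id}: start must be < end, got "
                f"[{self.start}, {self.end})"
            )
        if self.dicer_call not in DICER_CALLS:
            raise ValueError(f"{self.cluster_id}: bad dicer_call {self.dicer_call!r}")
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"{self.cluster_id}: bad rna_class {self.rna_class!r}")


_SHEET_COLUMNS = ["library_id", "cross", "maternal_plant", "replicate", "assay"]


@dataclass(frozen=True)
class SampleSheet:
    """Per-library design: cross type, maternal plant, replicate, assay."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in _SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        df = df[_SHEET_COLUMNS].reset_index(drop=True)
        if df["library_id"].duplicated().any():
            dups = sorted(df.loc[df["library_id"].duplicated(), "library_id"])
            raise FormatError(f"duplicate library_id(s): {dups}")
        bad = set(df["cross"]) - set(CROSSES)
        if bad:
            raise FormatError(f"unknown cross code(s): {sorted(bad)}")
        bad = set(df["assay"]) - set(ASSAYS)
        if bad:
            raise FormatError(f"unknown assay value(s): {sorted(bad)}")
        if (df["replicate"].astype(int) < 1).any():
            raise FormatError("replicate indices must be positive")
        object.__setattr__(self, "df", df)

    @property
    def library_ids(self) -> list[str]:
        return list(self.df["library_id"])

    @property
    def crosses(self) -> list[str]:
        return list(self.df["cross"])

    def libraries_for(self, cross: str) -> list[str]:
        return list(self.df.loc[self.df["cross"] == cross, "library_id"])

    def require_crosses(self, crosses: Iterable[str] = CROSSES, min_reps: int = 1) -> None:
        for cross in crosses:
            n = len(self.libraries_for(cross))
            if n < min_reps:
                raise ValueError(
                    f"cross {cross} has {n} libraries, needs >= {min_reps}"
                )

    def subset(self, library_ids: Sequence[str]) -> "SampleSheet":
        keep = self.df[self.df["library_id"].isin(set(library_ids))]
        return SampleSheet(keep.copy())

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CountTable:
    """Raw integer counts, features x libraries, column order = sheet order."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        if df.index.duplicated().any():
            raise FormatError("duplicate feature ids in count table")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.issubdtype(arr.dtype, np.number) or not np.all(
                np.equal(np.mod(arr, 1), 0)
            ):
                raise FormatError("counts must be integers")
            df = df.astype(np.int64)
        if (df.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")
        object.__setattr__(self, "df", df)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def align_to(self, sheet: SampleSheet) -> "CountTable":
        """Reorder columns to sheet order, erroring on any mismatch."""
        want, have = sheet.library_ids, set(self.df.columns)
        missing = [l for l in want if l not in have]
        extra = sorted(have - set(want))
        if missing or extra:
            raise FormatError(
                f"count columns do not match sample sheet; missing={missing}, "
                f"unexpected={extra}"
            )
        return CountTable(self.df[want])

    def subset_features(self, feature_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.df.loc[list(feature_ids)])

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"malformed attribute {item!r}")
        key, value = item.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(
    path: str | Path, feature_types: Sequence[str] = ("gene",)
) -> list[GeneFeature]:
    """Read gene records from a GFF3 file.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Only rows whose type is in ``feature_types`` are kept. Output is sorted by
    (chrom, start, gene_id). ``annotation_label`` and ``biotype`` are taken
    from identically named attributes when present.
    """
    wanted = set(feature_types)
    genes: list[GeneFeature] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, ftype, start, end, _score, strand, _phase, attr = fields
            if ftype not in wanted:
                continue
            try:
                start_i, end_i = int(start), int(end)
                attrs = _parse_gff_attributes(attr)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if "ID" not in attrs:
                raise FormatError(f"{path}: line {lineno}: gene record lacks ID")
            gene_id = attrs["ID"]
            if gene_id in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            try:
                genes.append(
                    GeneFeature(
                        chrom=chrom,
                        start=start_i - 1,  # 1-based inclusive -> 0-based half-open
                        end=end_i,
                        gene_id=gene_id,
                        strand=strand if strand in ("+", "-") else ".",
                        annotation_label=attrs.get("annotation_label", ""),
                        biotype=attrs.get("biotype", "protein_coding"),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gff3(genes: Iterable[GeneFeature], path: str | Path) -> None:
    """Write genes as GFF3 (coordinates back to 1-based inclusive)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for g in sorted(genes):
            attrs = f"ID={g.gene_id}"
            if g.annotation_label:
                attrs += f";annotation_label={g.annotation_label}"
            attrs += f";biotype={g.biotype}"
            handle.write(
                f"{g.chrom}\thybridome\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BED-like sRNA cluster table
# ---------------------------------------------------------------------------

def read_bed_clusters(path: str | Path) -> list[SrnaCluster]:
    """Read an sRNA cluster table: BED3 plus optional id/DicerCall/RNA-class.

    Coordinates are BED-native 0-based half-open and kept as-is. Missing
    optional columns default to ``cluster_id="chrom:start-end"``,
    ``dicer_call="none"``, ``rna_class="clean"``.
    """
    clusters: list[SrnaCluster] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            cluster_id = (
                fields[3] if len(fields) > 3 and fields[3] else f"{chrom}:{start}-{end}"
            )
            dicer_call = fields[4] if len(fields) > 4 and fields[4] else "none"
            rna_class = fields[5] if len(fields) > 5 and fields[5] else "clean"
            try:
                clusters.append(
                    SrnaCluster(chrom, start, end, cluster_id, dicer_call, rna_class)
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return clusters


def write_bed_clusters(clusters: Iterable[SrnaCluster], path: str | Path) -> None:
    with open(path, "w") as handle:
        for c in sorted(clusters):
            handle.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.cluster_id}\t"
                f"{c.dicer_call}\t{c.rna_class}\n"
            )


# ---------------------------------------------------------------------------
# Sample sheets and count tables
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"library_id": str, "maternal_plant": str})
    return SampleSheet(df)


def read_counts(path: str | Path, sheet: SampleSheet) -> CountTable:
    """Read a TSV count table and normalize column order to the sheet."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path}: non-numeric counts")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            bad = df.columns[np.any(np.mod(arr, 1) != 0, axis=0)].tolist()
            raise FormatError(f"{path}: non-integer counts in columns {bad}")
        df = df.astype(np.int64)
    try:
        return CountTable(df).align_to(sheet)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_counts(table: CountTable, path: str | Path) -> None:
    table.to_tsv(path)


def counts_to_tsv_string(table: CountTable) -> str:
    buf = _io.StringIO()
    out = table.df.copy()
    out.index.name = "feature_id"
    out.to_csv(buf, sep="\t")
    return buf.getvalue()


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as handle:
        cfg = yaml.safe_load(handle)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: YAML config must be a mapping")
    return cfg
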