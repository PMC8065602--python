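"""Readers and writers for the on-disk formats the pipeline consumes.

Expression matrices are TSV (first column gene ids, header row sample ids)
with a CSV sample-metadata table; gene sets are GMT; gene coordinates are
BED4 (0-based half-open); GWAS summaries are TSV with columns SNP/CHR/BP/P
(1-based positions).  All loaders validate hard: duplicate identifiers,
missing metadata, non-numeric cells and out-of-range p-values are errors,
never silently repaired.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionDataset",
    "GeneSetCollection",
    "GeneAnnotation",
    "GwasSummary",
    "AnalysisConfig",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_gene_bed",
    "write_gene_bed",
    "read_gwas",
    "write_gwas",
    "write_table",
]


class FormatError(ValueError):
    """A file violated its format contract (duplicate ids, bad values...)."""


@dataclass
class ExpressionDataset:
    """Gene × sample numeric expression matrix plus per-sample metadata.

    ``values`` has one row per entry of ``genes`` and one column per entry
    of ``samples``.  ``metadata`` is indexed by sample id and carries the
    design variables (period, region, cell_type, group) and covariates
    (RIN, pH, age, PMI, sex) when present.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            dup = _first_duplicate(self.genes)
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        if len(set(self.samples)) != len(self.samples):
            dup = _first_duplicate(self.samples)
            raise FormatError(f"duplicate sample identifier: {dup!r}")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes × {len(self.samples)} samples"
            )
        if np.isnan(self.values).any():
            g, s = np.argwhere(np.isnan(self.values))[0]
            raise FormatError(
                f"missing value at gene {self.genes[g]!r}, sample "
                f"{self.samples[s]!r}; imputation is refused"
            )
        missing = [s for s in self.samples if s not in self.metadata.index]
        if missing:
            raise FormatError(f"samples absent from metadata: {missing}")
        # align metadata row order with the matrix columns
        self.metadata = self.metadata.loc[self.samples]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        idx = {g: i for i, g in enumerate(self.genes)}
        keep = [idx[g] for g in genes]
        return ExpressionDataset(
            list(genes), list(self.samples), self.values[keep], self.metadata
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionDataset":
        idx = {s: i for i, s in enumerate(self.samples)}
        keep = [idx[s] for s in samples]
        return ExpressionDataset(
            list(self.genes),
            list(samples),
            self.values[:, keep],
            self.metadata.loc[list(samples)],
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> (description, members)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def items(self):
        return self.sets.items()


@dataclass
class GeneAnnotation:
    """Gene coordinates, 0-based half-open, one record per gene id."""

    records: pd.DataFrame  # columns: gene, chrom, start, end

    def __post_init__(self) -> None:
        r = self.records
        if r["gene"].duplicated().any():
            dup = r.loc[r["gene"].duplicated(), "gene"].iloc[0]
            raise FormatError(f"duplicate gene in annotation: {dup!r}")
        bad = r[r["start"] >= r["end"]]
        if len(bad):
            raise FormatError(
                f"gene {bad['gene'].iloc[0]!r} has start >= end "
                f"({bad['start'].iloc[0]} >= {bad['end'].iloc[0]})"
            )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GwasSummary:
    """Per-SNP association summary: SNP id, chromosome, 1-based position, p."""

    records: pd.DataFrame  # columns: snp, chrom, pos, p

    def __post_init__(self) -> None:
        r = self.records
        bad = r[(r["p"] <= 0) | (r["p"] > 1)]
        if len(bad):
            raise FormatError(
                f"SNP {bad['snp'].iloc[0]!r} has p={bad['p'].iloc[0]} "
                "outside (0, 1]"
            )
        if (r["pos"] <= 0).any():
            raise FormatError("GWAS positions must be positive 1-based integers")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class AnalysisConfig:
    """Tunable thresholds and paths for the end-to-end pipeline run.

    Thresholds follow the source analyses: genome-wide significance 5e-8
    for the well-powered GWAS (AN), a relaxed 1e-5 for the underpowered
    one (OCD); TOM edge cutoff 0.1 for subnetwork extraction; BH alpha
    0.05 throughout.
    """

    an_gwas_threshold: float = 5e-8
    ocd_gwas_threshold: float = 1e-5
    ld_window: int = 250_000
    tom_cutoff: float = 0.1
    bh_alpha: float = 0.05
    # soft_power: explicit power for every network; when None the pipeline
    # uses the reference epoch powers (12 prenatal, 16 postnatal) unless
    # soft_power_auto asks for the scale-free fit to choose per subset
    soft_power: int | None = None
    soft_power_auto: bool = False
    cut_height: float = 0.3
    min_module_size: int = 20
    max_module_size: int = 1000
    n_bootstrap: int = 10_000
    n_permutations: int = 10_000
    seed: int = 0
    # file paths (None where a stage is skipped)
    expression: str | None = None
    expression_meta: str | None = None
    celltype_expression: str | None = None
    celltype_meta: str | None = None
    casecontrol: str | None = None
    casecontrol_meta: str | None = None
    gene_bed: str | None = None
    an_gwas: str | None = None
    ocd_gwas: str | None = None
    gene_sets: str | None = None

    def __post_init__(self) -> None:
        for name in ("ld_window", "min_module_size", "max_module_size",
                     "n_bootstrap", "n_permutations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def header_lines(self) -> list[str]:
        """Commented echo of seed and parameters for result-table headers."""
        d = dataclasses.asdict(self)
        keys = ["seed", "an_gwas_threshold", "ocd_gwas_threshold", "ld_window",
                "tom_cutoff", "bh_alpha", "soft_power", "cut_height",
                "min_module_size", "max_module_size", "n_bootstrap",
                "n_permutations"]
        return [f"# {k}={d[k]}" for k in keys]


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    raise ValueError("no duplicate present")


def read_expression(path: str | Path, metadata_path: str | Path) -> ExpressionDataset:
    """Load a gene × sample TSV plus its CSV metadata into one dataset.

    The TSV must have a header row of sample ids and gene ids in the first
    column; the CSV must be keyed by a ``sample`` column covering every
    sample in the matrix.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id in {path}: {dup!r}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = df.index[coerced.isna()][0]
                raise FormatError(
                    f"non-numeric cell at gene {row!r}, sample {col!r} in {path}"
                ) from exc
        raise
    meta = pd.read_csv(metadata_path)
    if "sample" not in meta.columns:
        raise FormatError(f"metadata {metadata_path} lacks a 'sample' column")
    if meta["sample"].duplicated().any():
        dup = meta.loc[meta["sample"].duplicated(), "sample"].iloc[0]
        raise FormatError(f"duplicate sample in metadata: {dup!r}")
    meta = meta.set_index("sample")
    return ExpressionDataset(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=values,
        metadata=meta,
    )


def write_expression(dataset: ExpressionDataset, path: str | Path,
                     metadata_path: str | Path | None = None) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index_label="gene")
    if metadata_path is not None:
        dataset.metadata.to_csv(metadata_path, index_label="sample")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name, description, then tab-separated members.

    Duplicate members within a line are collapsed (first occurrence kept).
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc = fields[0], fields[1]
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gene_bed(path: str | Path) -> GeneAnnotation:
    """Read BED4 gene coordinates (chrom, start, end, gene), 0-based half-open."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED4 needs 4 fields")
            chrom, start, end, gene = fields[0], int(fields[1]), int(fields[2]), fields[3]
            rows.append((gene, chrom, start, end))
    return GeneAnnotation(pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]))


def write_gene_bed(annotation: GeneAnnotation, path: str | Path) -> None:
    annotation.records[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gwas(path: str | Path) -> GwasSummary:
    """Read a GWAS summary TSV with header columns SNP, CHR, BP, P."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.upper(): c for c in df.columns}
    for need in ("SNP", "CHR", "BP", "P"):
        if need not in cols:
            raise FormatError(f"{path}: missing GWAS column {need}")
    out = pd.DataFrame({
        "snp": df[cols["SNP"]].astype(str),
        "chrom": df[cols["CHR"]].astype(str),
        "pos": df[cols["BP"]].astype(int),
        "p": df[cols["P"]].astype(float),
    })
    return GwasSummary(out)


def write_gwas(gwas: GwasSummary, path: str | Path) -> None:
    out = gwas.records.rename(
        columns={"snp": "SNP", "chrom": "CHR", "pos": "BP", "p": "P"}
    )
    out.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path,
                header_lines: Sequence[str] = (), index: bool = False) -> None:
    """Write a result TSV with commented seed/parameter header lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
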