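"""Readers, writers and validated in-memory containers.

Internal genomic coordinates are 1-based inclusive (the GFF3 convention);
BED input, which is 0-based half-open, is converted on ingest. The TSS of a
gene is its `start` on the + strand and its `end` on the − strand.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

_VALID_STRANDS = frozenset({"+", "-"})


@dataclass(frozen=True)
class GeneRecord:
    """A gene locus: 1-based inclusive coordinates plus effective length.

    ``length_bp`` is the effective transcript length used for RPKM; it
    defaults to the genomic span but may be supplied separately (e.g. an
    exonic-union length).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    length_bp: int = 0

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if self.length_bp == 0:
            object.__setattr__(self, "length_bp", self.end - self.start + 1)
        if self.length_bp <= 0:
            raise ValueError(f"gene {self.gene_id}: length_bp must be positive")

    @property
    def tss(self) -> int:
        """Transcription start site: start for + strand, end for − strand."""
        return self.start if self.strand == "+" else self.end


@dataclass
class ExpressionMatrix:
    """Genes × samples non-negative expression with a sample→condition design.

    ``unit`` is "counts" or "rpkm". Any testing operation requires at least
    two replicates per condition.
    """

    values: pd.DataFrame  # index: gene_id, columns: sample_id
    design: pd.Series  # index: sample_id, value: condition
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "rpkm"):
            raise ValueError(f"unit must be 'counts' or 'rpkm', got {self.unit!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("expression values must be finite")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative expression at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        self.design = self.design.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.design))

    def samples_of(self, condition: str) -> list[str]:
        out = [s for s in self.values.columns if self.design[s] == condition]
        if not out:
            raise KeyError(f"no samples for condition {condition!r}")
        return out

    def condition_values(self, condition: str) -> pd.DataFrame:
        return self.values[self.samples_of(condition)]


@dataclass
class QpcrTable:
    """Long-format qPCR CT measurements.

    Columns: target_gene, condition, replicate, ct_target, ct_reference.
    ``ct_reference`` is the reference-gene (e.g. rpL32) CT measured in the
    same well/sample, so the per-row ΔCT is ``ct_target − ct_reference``.
    """

    rows: pd.DataFrame

    REQUIRED = ("target_gene", "condition", "replicate", "ct_target", "ct_reference")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ValueError(f"qPCR table missing columns: {missing}")
        for col in ("ct_target", "ct_reference"):
            if not np.isfinite(self.rows[col].to_numpy(dtype=float)).all():
                raise ValueError(f"non-finite CT values in column {col}")


# ---------------------------------------------------------------------------
# readers


def read_expression(path: str | Path, design_path: str | Path, unit: str = "counts") -> ExpressionMatrix:
    """Read an expression TSV (gene_id + one column per sample) and a design
    TSV (sample, condition[, replicate]) into a validated ExpressionMatrix."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    design_df = pd.read_csv(design_path, sep="\t", comment="#", dtype=str)
    if "sample" not in design_df.columns or "condition" not in design_df.columns:
        raise ValueError("design file must have 'sample' and 'condition' columns")
    design = design_df.set_index("sample")["condition"]
    missing = [s for s in df.columns if s not in design.index]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")
    return ExpressionMatrix(values=df.astype(float), design=design, unit=unit)


def read_gene_loci(path: str | Path, format: str) -> list[GeneRecord]:
    """Read gene loci from BED6 or GFF3.

    BED's 0-based half-open intervals are converted to the internal 1-based
    inclusive convention (start+1, end). GFF3 coordinates are taken as-is.
    """
    records: list[GeneRecord] = []
    if format == "bed":
        for ln, line in enumerate(_data_lines(path), 1):
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: BED6 requires 6 columns, got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            records.append(
                GeneRecord(gene_id=name, chrom=chrom, start=int(start) + 1,
                           end=int(end), strand=strand)
            )
    elif format == "gff3":
        for ln, line in enumerate(_data_lines(path), 1):
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{ln}: GFF3 requires 9 columns, got {len(parts)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            gene_id = _gff3_attr(attrs, "ID")
            if gene_id is None:
                raise ValueError(f"{path}:{ln}: gene feature lacks ID attribute")
            records.append(
                GeneRecord(gene_id=gene_id, chrom=chrom, start=int(start),
                           end=int(end), strand=strand)
            )
    else:
        raise ValueError(f"unknown loci format {format!r} (expected 'bed' or 'gff3')")
    seen: set[str] = set()
    for r in records:
        if r.gene_id in seen:
            raise ValueError(f"duplicate gene id {r.gene_id!r} in {path}")
        seen.add(r.gene_id)
    return records


def read_qpcr(path: str | Path) -> QpcrTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return QpcrTable(rows=df)


def _data_lines(path: str | Path) -> Iterable[str]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield line


def _gff3_attr(attrs: str, key: str) -> str | None:
    for item in attrs.split(";"):
        item = item.strip()
        if item.startswith(key + "="):
            return item[len(key) + 1:]
    return None


# ---------------------------------------------------------------------------
# writers

def _comment_header(params: Mapping[str, object] | None) -> str:
    from coopdeg import __version__

    lines = [f"# coopdeg {__version__}"]
    if params:
        for k, v in params.items():
            lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path: str | Path,
                params: Mapping[str, object] | None = None,
                index: bool = False) -> None:
    """Write a result table as TSV with a versioned comment header.

    Floats are written with 12 significant digits so that read(write(x))
    round-trips result tables to that precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index, float_format="%.12g")
    with open(path, "w") as fh:
        fh.write(_comment_header(params))
        fh.write(buf.getvalue())


def read_table(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     design_path: str | Path | None = None) -> None:
    write_table(matrix.values.rename_axis("gene_id"), path,
                params={"unit": matrix.unit}, index=True)
    if design_path is not None:
        design_df = pd.DataFrame(
            {"sample": matrix.design.index, "condition": matrix.design.values}
        )
        write_table(design_df, design_path)


def write_bed(records: Iterable[GeneRecord], path: str | Path) -> None:
    """BED6 output: convert internal 1-based inclusive back to 0-based half-open."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")


def write_gff3(records: Iterable[GeneRecord], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            fh.write(
                f"{r.chrom}\tcoopdeg\tgene\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t"
                f"ID={r.gene_id}\n"
            )
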