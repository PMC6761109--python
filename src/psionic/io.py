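"""Readers and writers for the external text formats, plus model serialization.

All tabular formats are plain TSV. Genomic intervals use the BED convention
(0-based, half-open, tab-separated, no header). Readers validate and reject
malformed input rather than silently coercing it.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MODEL_FORMAT_VERSION = 1


class FormatError(ValueError):
    """Raised when an input file violates its expected dialect."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"interval {self.id!r}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class GeneModel:
    """A gene's transcription unit; the TSS is the strand-aware 5' end."""

    gene_id: str
    chrom: str
    strand: str
    tu_start: int
    tu_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if self.tu_start >= self.tu_end:
            raise FormatError(
                f"gene {self.gene_id!r}: tu_start ({self.tu_start}) must be < "
                f"tu_end ({self.tu_end})"
            )

    @property
    def tss(self) -> int:
        return self.tu_start if self.strand == "+" else self.tu_end - 1


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED-like file into a list of intervals (file order preserved).

    The optional 4th column supplies the interval id; otherwise ids are
    auto-generated as ``peak_<n>`` (1-based). Duplicate ids are rejected.
    """
    intervals: list[GenomicInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            iid = fields[3] if len(fields) >= 4 and fields[3] else f"peak_{lineno}"
            if iid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate interval id {iid!r}")
            seen.add(iid)
            try:
                intervals.append(GenomicInterval(chrom, start, end, iid))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\n")


# ---------------------------------------------------------------------------
# Gene table
# ---------------------------------------------------------------------------

GENE_TABLE_COLUMNS = ["gene_id", "chrom", "strand", "tu_start", "tu_end"]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a minimal gene table: gene_id, chrom, strand, tu_start, tu_end (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(row.gene_id, row.chrom, row.strand,
                      int(row.tu_start), int(row.tu_end))
        )
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [(g.gene_id, g.chrom, g.strand, g.tu_start, g.tu_end) for g in genes]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Motif hit tables (FIMO-style)
# ---------------------------------------------------------------------------

HIT_COLUMNS = ["motif_id", "peak_id", "score"]


def read_motif_hits(path: str | Path) -> pd.DataFrame:
    """Read a motif-hit table: motif_id, peak_id, score (TSV, header required).

    Scores are nonnegative motif-match strengths (e.g. -log10 of the FIMO
    hit p-value); an absent (peak, motif) row means no hit.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df[HIT_COLUMNS].copy()
    df["score"] = pd.to_numeric(df["score"], errors="raise")
    if (df["score"] < 0).any():
        raise FormatError(f"{path}: negative motif score")
    if df.duplicated(["motif_id", "peak_id"]).any():
        raise FormatError(f"{path}: duplicate (motif_id, peak_id) entry")
    return df


def write_motif_hits(hits: pd.DataFrame, path: str | Path) -> None:
    hits[HIT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene × sample TSV (header = sample ids, first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            gene = df.index[bad.isna().to_numpy().argmax()]
            raise FormatError(f"{path}: non-numeric value at gene {gene!r}, sample {col!r}")
        df[col] = bad
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values are not permitted")
    return df.astype(float)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def normalize_expression(
    raw: pd.DataFrame,
    pseudocount: float = 1.0,
    log_input: bool = False,
) -> pd.DataFrame:
    """Per-sample normalization: log10(x + pseudocount), then unit L2 norm.

    ``log_input=True`` skips the log step for matrices that are already on a
    log scale (e.g. log10 RSEM); unit-normalization is always applied.
    """
    values = raw.to_numpy(dtype=float)
    if not log_input:
        if (values < 0).any():
            raise ValueError("negative expression on linear scale")
        values = np.log10(values + pseudocount)
    norms = np.linalg.norm(values, axis=0)
    if (norms == 0).any():
        col = raw.columns[int(np.argmin(norms))]
        raise ValueError(f"sample {col!r} has zero norm after transform")
    return pd.DataFrame(values / norms, index=raw.index, columns=raw.columns)


# ---------------------------------------------------------------------------
# Matrix TSV helpers (feature matrices, activity matrices)
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labelled numeric matrix TSV (same dialect as expression)."""
    return read_expression(path)


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label, float_format="%.17g")


# ---------------------------------------------------------------------------
# Model serialization
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path) -> None:
    """Serialize a fitted model to a single zip archive.

    Layout: ``manifest.json`` (labels, penalties, fit metadata, format
    version) plus one ``.npy`` member per dense array. The archive
    round-trips predictions bit-identically.
    """
    manifest = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": type(model).__name__,
        "tf_ids": list(model.tf_ids),
        "sample_ids": list(model.sample_ids),
        "params": model.params_dict(),
        "metadata": model.metadata_dict(),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        for name, arr in model.arrays_dict().items():
            buf = _io.BytesIO()
            np.save(buf, np.asarray(arr, dtype=float))
            zf.writestr(f"{name}.npy", buf.getvalue())


def load_model(path: str | Path):
    """Inverse of :func:`save_model`; raises on truncation or version mismatch."""
    from . import mtl  # local import to avoid a cycle

    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            if manifest.get("format_version") != MODEL_FORMAT_VERSION:
                raise FormatError(
                    f"model format version {manifest.get('format_version')!r} "
                    f"!= supported {MODEL_FORMAT_VERSION}"
                )
            arrays = {}
            for member in zf.namelist():
                if member.endswith(".npy"):
                    arrays[member[:-4]] = np.load(_io.BytesIO(zf.read(member)))
    except (zipfile.BadZipFile, KeyError, EOFError) as exc:
        raise FormatError(f"{path}: unreadable or truncated model archive") from exc
    kind = manifest["kind"]
    if kind == "PsionicModel":
        cls = mtl.PsionicModel
    elif kind == "StlModel":
        cls = mtl.StlModel
    else:
        raise FormatError(f"unknown model kind {kind!r}")
    return cls.from_serialized(manifest, arrays)
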