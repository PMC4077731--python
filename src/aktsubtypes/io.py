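"""Readers and writers for the pipeline's plain-text formats.

Expression matrices and clinical tables are tab-delimited; gene sets use
the GMT convention (term, description, then member genes); q-value tracks
are BED-like TSV (chrom, start, end, gene, q_amp, q_del) with 0-based
half-open coordinates.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocessing import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_qtrack",
    "write_qtrack",
]

CLINICAL_REQUIRED = ("sample_id", "os_years", "event", "age")


def read_expression(
    path: str | Path, max_missing_frac: float = 0.1, centered: bool = False
) -> ExpressionMatrix:
    """Read a genes x samples TSV (gene IDs in the first column).

    Non-numeric cells are reported with their row/column address; matrices
    whose missing-value fraction exceeds ``max_missing_frac`` are rejected.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs in {path}: {dups[:5]}")
    df = raw.apply(pd.to_numeric, errors="coerce")
    bad = df.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value at gene {df.index[r]!r}, sample {df.columns[c]!r} in {path}"
        )
    missing_frac = float(df.isna().to_numpy().mean())
    if missing_frac > max_missing_frac:
        raise ValueError(
            f"{missing_frac:.1%} missing values exceeds limit {max_missing_frac:.1%}"
        )
    df.index.name = None
    df.columns.name = None
    return ExpressionMatrix(df, centered=centered)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample IDs in clinical table")
    return df


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, ...]]:
    sets: dict[str, tuple[str, ...]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs term, description, >=1 gene")
        term, _desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise ValueError(f"{path}:{ln}: empty gene set {term!r}")
        if term in sets:
            raise ValueError(f"{path}:{ln}: duplicate term {term!r}")
        sets[term] = tuple(genes)
    return sets


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    lines = [
        "\t".join([term, "na", *genes]) for term, genes in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_qtrack(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        names=["chrom", "start", "end", "gene", "q_amp", "q_del"],
        header=0,
    )
    for col in ("q_amp", "q_del"):
        q = df[col].to_numpy(dtype=float)
        if ((q < 0) | (q > 1)).any():
            raise ValueError(f"{col} outside [0, 1] in {path}")
    return df


def write_qtrack(track: pd.DataFrame, path: str | Path) -> None:
    track.to_csv(path, sep="\t", index=False)
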