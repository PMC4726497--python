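"""File I/O for the pipeline: FASTA, TSV tables, gene lists, JSON reports.

All tabular files are tab-delimited with a header row; lines starting
with '#' are comments and carry reproducibility metadata (tool version,
seed, config hash) written by :func:`tsv_header`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .expression import ExpressionMatrix
from .scan import UtrRecord


def read_fasta(path: str | Path) -> list[UtrRecord]:
    """Read UTRs from FASTA: id = first whitespace token, T -> U, uppercase."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate gene id {rec.id!r} in {path}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        records.append(UtrRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(utrs: list[UtrRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(u.sequence), id=u.gene_id, description="") for u in utrs),
        str(path),
        "fasta",
    )


def config_hash(obj) -> str:
    """Short stable hash of a config-like object for output provenance."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def tsv_header(seed: int | None = None, cfg_hash: str | None = None) -> str:
    parts = [f"# cnotscreen {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config={cfg_hash}")
    return " ".join(parts) + "\n"


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str | None = None,
    index: bool = True,
) -> None:
    with open(path, "w") as fh:
        fh.write(tsv_header(seed, cfg_hash))
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_gene_list(genes: list[str] | set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def write_expression(
    matrix: ExpressionMatrix,
    values_path: str | Path,
    groups_path: str | Path,
    seed: int | None = None,
) -> None:
    write_tsv(matrix.values, values_path, seed=seed)
    groups = matrix.groups.rename_axis("sample_id").to_frame()
    write_tsv(groups, groups_path, seed=seed)


def read_expression(values_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    values = read_tsv(values_path)
    groups = read_tsv(groups_path)["group"]
    return ExpressionMatrix(values, groups)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
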