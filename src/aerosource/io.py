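"""Readers and writers for the flat tabular artifacts the pipeline touches.

TSV is the canonical interchange format (the flat-table world of the
mothur/USEARCH toolchain); BIOM 1.0 JSON tables are supported read-only.
All validation happens here, once, at the boundary: everything downstream
can assume well-formed containers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .containers import (
    CountTable,
    Habitat,
    Kingdom,
    SampleInfo,
    TaxonomyTable,
    ValidationError,
)

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_sample_info",
    "write_sample_info",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_taxonomy",
]


def read_count_table(path: str | Path, format: str = "tsv") -> CountTable:
    """Read an OTU-by-sample count table.

    ``tsv``: first column OTU ids, remaining columns samples, header row of
    sample ids. ``biom_json``: a BIOM 1.0 JSON table (dense or sparse).
    Counts must parse as non-negative integers; violations are reported with
    1-based (row, column) coordinates of the offending cell.
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv_counts(path)
    if format == "biom_json":
        return _read_biom_json(path)
    raise ValueError(f"unknown count-table format {format!r}")


def _read_tsv_counts(path: Path) -> CountTable:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    parsed = pd.DataFrame(index=raw.index)
    for j, col in enumerate(raw.columns):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValidationError(
                f"cannot parse count {raw[col].iloc[i]!r} at "
                f"(row {i + 1}, col {j + 1}) of {path}"
            )
        if (vals < 0).any():
            i = int(np.argmax((vals < 0).to_numpy()))
            raise ValidationError(
                f"negative count {vals.iloc[i]} at (row {i + 1}, col {j + 1}) of {path}"
            )
        if ((vals % 1) != 0).any():
            i = int(np.argmax(((vals % 1) != 0).to_numpy()))
            raise ValidationError(
                f"non-integer count {vals.iloc[i]} at (row {i + 1}, col {j + 1}) of {path}"
            )
        parsed[col] = vals.astype(np.int64)
    return CountTable(parsed)


def _read_biom_json(path: Path) -> CountTable:
    # BIOM 1.0 is plain JSON: rows = observations (OTUs), columns = samples.
    with open(path) as fh:
        obj = json.load(fh)
    otu_ids = [r["id"] for r in obj["rows"]]
    sample_ids = [c["id"] for c in obj["columns"]]
    n_rows, n_cols = obj["shape"]
    mat = np.zeros((n_rows, n_cols))
    if obj.get("matrix_type", "dense") == "sparse":
        for r, c, v in obj["data"]:
            mat[int(r), int(c)] = v
    else:
        mat[:, :] = np.asarray(obj["data"], dtype=float)
    df = pd.DataFrame(mat, index=otu_ids, columns=sample_ids)
    return CountTable(df)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="otu_id")


def read_sample_info(path: str | Path) -> list[SampleInfo]:
    """Read metadata TSV with columns sample_id, habitat, site, kingdom.

    Habitat and kingdom tokens are validated case-insensitively.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "habitat", "site"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata {path} lacks columns {sorted(missing)}")
    rows = []
    for _, rec in df.iterrows():
        kingdom = Kingdom.parse(rec["kingdom"]) if "kingdom" in df.columns else Kingdom.BACTERIA
        rows.append(
            SampleInfo(
                sample_id=str(rec["sample_id"]).strip(),
                habitat=Habitat.parse(rec["habitat"]),
                site=str(rec["site"]).strip(),
                kingdom=kingdom,
            )
        )
    ids = [r.sample_id for r in rows]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample_ids in metadata: {dups}")
    return rows


def write_sample_info(meta: Sequence[SampleInfo], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "habitat": [m.habitat.value for m in meta],
            "site": [m.site for m in meta],
            "kingdom": [m.kingdom.value for m in meta],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    return DistanceMatrix.read(str(path), format="lsmat")


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a labelled square TSV; round-trips with its reader to 1e-12.

    skbio's DistanceMatrix enforces symmetry/hollowness at construction, so
    any ``dm`` reaching this point is safe to serialize.
    """
    if not isinstance(dm, DistanceMatrix):
        raise ValidationError("write_distance_matrix expects a skbio DistanceMatrix")
    dm.write(str(path), format="lsmat")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a taxonomy TSV: first column otu_id, remaining columns ranks."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("unclassified")
    return TaxonomyTable(ranks=list(df.columns), labels=df)
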