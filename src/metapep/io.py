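"""Strict TSV readers/writers for quantification matrices and metadata.

All tables are UTF-8 TSV with a header row, '.' decimal separator and
missing values encoded as empty strings, so that every writer/reader pair
round-trips bit-identically on its own output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .peptides import equalize_il, strip_modifications

logger = logging.getLogger(__name__)


def read_peptide_quant(
    path: str | Path,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a peptide quantification TSV.

    Layout: first column ``peptide``, optional second column ``proteins``
    (semicolon-separated protein group; only the leading protein is kept),
    remaining columns one per sample.  Peptide strings are stripped of
    modification annotations and I/L-equalized; rows that collide after
    equalization are summed.  Blanks are missing; negative intensities and
    ragged rows are errors.

    Returns ``(matrix, peptide -> leading protein)``; the mapping is empty
    when the file has no protein column.
    """
    rows: dict[str, np.ndarray] = {}
    proteins: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "peptide":
            raise ValueError(
                f"{path}: first column must be 'peptide', got {header[:1]}"
            )
        has_proteins = len(header) > 1 and header[1] == "proteins"
        first_sample = 2 if has_proteins else 1
        samples = header[first_sample:]
        if not samples:
            raise ValueError(f"{path}: no sample columns")
        width = len(header)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(fields)} fields, expected {width})"
                )
            pep = equalize_il(strip_modifications(fields[0]))
            values = np.array(
                [float(v) if v != "" else np.nan for v in fields[first_sample:]]
            )
            if np.nanmin(values, initial=0.0) < 0:
                raise ValueError(
                    f"{path}: negative intensity at line {lineno}"
                )
            if pep in rows:
                old = rows[pep]
                both_nan = np.isnan(old) & np.isnan(values)
                rows[pep] = np.where(
                    both_nan, np.nan, np.nansum([old, values], axis=0)
                )
            else:
                rows[pep] = values
            if has_proteins and fields[1]:
                proteins.setdefault(pep, fields[1].split(";")[0])
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    matrix.index.name = "peptide"
    return matrix, proteins


def read_quant_matrix(path: str | Path) -> pd.DataFrame:
    """Read a generic feature x sample TSV (no equalization or merging)."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if (matrix.fillna(0) < 0).any().any():
        raise ValueError(f"{path}: negative intensities")
    return matrix


def write_quant_matrix(
    matrix: pd.DataFrame,
    path: str | Path,
    proteins: Mapping[str, str] | None = None,
    feature_column: str = "peptide",
) -> None:
    """Write a feature x sample matrix; NaN rendered as empty string."""
    with open(path, "w", encoding="utf-8") as fh:
        cols = list(matrix.columns)
        header = [feature_column]
        if proteins is not None:
            header.append("proteins")
        fh.write("\t".join(header + [str(c) for c in cols]) + "\n")
        for feature, row in matrix.iterrows():
            out = [str(feature)]
            if proteins is not None:
                out.append(proteins.get(feature, ""))
            for v in row:
                out.append("" if (v is None or math.isnan(v)) else repr(float(v)))
            fh.write("\t".join(out) + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError(f"{path}: metadata must contain a sample_id column")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in metadata")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def write_assignments(assignments, path: str | Path) -> None:
    """Peptide assignment TSV: peptide, proteins (;-joined), taxon_id."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("peptide\tproteins\ttaxon_id\n")
        for a in assignments:
            fh.write(
                f"{a.peptide}\t{';'.join(sorted(a.proteins))}\t"
                f"{a.taxon_id or ''}\n"
            )


def read_assignments(path: str | Path):
    from .peptides import PeptideAssignment

    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["peptide", "proteins", "taxon_id"]:
            raise ValueError(f"{path}: unexpected assignment header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pep, prots, taxon = line.split("\t")
            out.append(
                PeptideAssignment(
                    pep,
                    frozenset(p for p in prots.split(";") if p),
                    taxon or None,
                )
            )
    return out


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Differential tables and other frames, index included."""
    table.to_csv(path, sep="\t")


def sha256_of(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    params: Mapping,
    inputs: Mapping[str, str | Path],
    outputs: Mapping[str, str | Path],
) -> None:
    """Machine-readable run manifest with checksums of inputs/outputs."""
    manifest = {
        "command": command,
        "params": {k: _jsonable(v) for k, v in params.items()},
        "inputs": {k: sha256_of(v) for k, v in inputs.items()},
        "outputs": {k: sha256_of(v) for k, v in outputs.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(value):
    if isinstance(value, Path):
        return str(value)
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value
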