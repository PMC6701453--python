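"""Tab-separated file formats used throughout the pipeline.

All artifacts are plain TSV: an expression matrix has gene identifiers in the
first column and one column per sample; a sample table is indexed by sample id
with a ``group`` column (``control``/``treated``) and free phenotype columns
(missing values allowed, encoded as empty cells); a gene annotation table maps
gene id to symbol and a control-probe flag; a homolog map is two columns of
gene ids. Reading is strict: duplicate identifiers, ragged rows and
non-numeric cells raise :class:`~coexnet.errors.ParseError` naming the line.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Iterable, Mapping

import pandas as pd

from .errors import ParseError

VALID_GROUPS = frozenset({"control", "treated"})


def _check_nonempty(path: str) -> None:
    if not os.path.exists(path):
        raise ParseError(f"{path}: file does not exist")
    if os.path.getsize(path) == 0:
        raise ParseError(f"{path}: file is empty")


def _check_unique_index(df: pd.DataFrame, path: str, what: str) -> None:
    dup = df.index.duplicated(keep="first")
    if dup.any():
        # +2: one for the header row, one for 0- vs 1-based counting
        line = int(dup.argmax()) + 2
        raise ParseError(
            f"{path}: duplicate {what} {df.index[dup.argmax()]!r} on line {line}"
        )


def _read_tsv(path: str) -> pd.DataFrame:
    _check_nonempty(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         keep_default_na=False, na_values=[""])
    except pd.errors.ParserError as exc:  # ragged rows etc.; pandas names the line
        raise ParseError(f"{path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    if df.index.isna().any() or df.columns.duplicated().any():
        raise ParseError(f"{path}: missing identifiers or duplicate column names")
    return df


def read_expression(path: str) -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV.

    Returns a float DataFrame indexed by gene id with sample ids as columns.
    """
    df = _read_tsv(path)
    _check_unique_index(df, path, "gene id")
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str),
                       dtype=float)
    for col in df.columns:
        try:
            # astype(float) parses via float(), which round-trips exactly;
            # pd.to_numeric's fast path can drop the last digit
            numeric = df[col].astype(float)
        except (TypeError, ValueError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            line = int(bad.to_numpy().argmax()) + 2
            raise ParseError(
                f"{path}: non-numeric value {df[col][bad].iloc[0]!r} in column "
                f"{col!r} on line {line}"
            ) from None
        if numeric.isna().any():
            line = int(numeric.isna().to_numpy().argmax()) + 2
            raise ParseError(f"{path}: missing value in column {col!r} on line {line}")
        out[col] = numeric.to_numpy()
    if out.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns")
    return out


def write_expression(expr: pd.DataFrame, path: str) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_info(path: str) -> pd.DataFrame:
    """Read a sample table: index sample_id, ``group`` column plus phenotypes.

    Phenotype columns are parsed as floats with missing values preserved
    (the drinker-only convention stores controls' intake as empty cells, never
    as zeros).
    """
    df = _read_tsv(path)
    _check_unique_index(df, path, "sample id")
    if "group" not in df.columns:
        raise ParseError(f"{path}: missing required 'group' column")
    bad = ~df["group"].isin(VALID_GROUPS)
    if bad.any():
        raise ParseError(
            f"{path}: invalid group {df['group'][bad].iloc[0]!r} "
            f"(expected one of {sorted(VALID_GROUPS)})"
        )
    out = df.copy()
    for col in df.columns:
        if col in ("group", "species"):
            continue
        out[col] = pd.to_numeric(df[col], errors="coerce")
    out.index = out.index.astype(str)
    return out


def write_sample_info(info: pd.DataFrame, path: str) -> None:
    info.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_annotation(path: str) -> pd.DataFrame:
    """Read gene annotation: index gene_id, columns ``symbol`` (may be empty)
    and ``is_control_probe`` (0/1 or true/false)."""
    df = _read_tsv(path)
    _check_unique_index(df, path, "gene id")
    for col in ("symbol", "is_control_probe"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    flag = df["is_control_probe"].astype(str).str.lower()
    mapping = {"0": False, "1": True, "true": True, "false": False}
    bad = ~flag.isin(mapping)
    if bad.any():
        raise ParseError(
            f"{path}: invalid is_control_probe value {df['is_control_probe'][bad].iloc[0]!r}"
        )
    out = pd.DataFrame(
        {"symbol": df["symbol"], "is_control_probe": flag.map(mapping).astype(bool)},
        index=df.index.astype(str),
    )
    return out


def write_gene_annotation(annot: pd.DataFrame, path: str) -> None:
    out = annot.copy()
    out["is_control_probe"] = out["is_control_probe"].astype(int)
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_homolog_map(path: str) -> pd.DataFrame:
    """Read a two-column homolog map (species A id, species B id), strictly 1:1."""
    _check_nonempty(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected exactly two columns, found {df.shape[1]}")
    df.columns = ["species_a", "species_b"]
    for col in df.columns:
        dup = df[col].duplicated(keep="first")
        if dup.any():
            line = int(dup.to_numpy().argmax()) + 2
            raise ParseError(
                f"{path}: homolog map is not 1:1, duplicate {df[col][dup].iloc[0]!r} "
                f"on line {line}"
            )
    return df


def write_homolog_map(pairs: pd.DataFrame, path: str) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def sha256_of(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str, *, stage: str, config: Mapping,
                   inputs: Iterable[str] = (), outputs: Iterable[str] = ()) -> None:
    """Write a machine-readable run manifest.

    Deliberately timestamp-free so reruns with the same seed and config produce
    byte-identical manifests.
    """
    from . import __version__

    manifest = {
        "stage": stage,
        "coexnet_version": __version__,
        "config": dict(config),
        "inputs": {os.path.basename(p): sha256_of(p) for p in inputs},
        "outputs": sorted(os.path.basename(p) for p in outputs),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
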