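"""Readers and writers for expression tables, drug-response tables, GMT gene
sets and the on-disk DGCP library.

Gene and sample identifiers are matched exactly (case-sensitive); inputs are
expected to share one identifier namespace. All files are UTF-8 text with dot
decimal separators. Duplicate gene rows in expression input are collapsed by
mean with a logged warning.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import DGCP, DGCPLibrary, validate_expression, validate_response

logger = logging.getLogger(__name__)

LIBRARY_FORMAT_VERSION = 1


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""


def read_expression(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read a genes x samples expression table.

    ``format="tsv"``: first column gene ids, header row sample ids.
    ``format="gct"``: GCT 1.2 dialect — two-line preamble ("#1.2" then
    dimensions), ``Name`` column as gene id, ``Description`` column ignored.
    Duplicate gene rows are collapsed by mean. Blank cells become NaN.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise ParseError(f"{path}: malformed expression TSV: {exc}") from exc
    elif format == "gct":
        with open(path, encoding="utf-8") as fh:
            first = fh.readline().strip()
            if not first.startswith("#1.2"):
                raise ParseError(f"{path}: line 1: expected GCT '#1.2' preamble, got {first!r}")
            fh.readline()  # dimensions line, trusted but unused
            df = pd.read_csv(fh, sep="\t")
        if "Name" not in df.columns:
            raise ParseError(f"{path}: line 3: GCT header lacks a 'Name' column")
        df = df.set_index("Name")
        df = df.drop(columns=[c for c in ("Description",) if c in df.columns])
    else:
        raise ValueError(f"unknown expression format {format!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: expression table has zero genes or zero samples")
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.warning("%s: collapsing %d duplicate gene rows by mean", path, n_dup)
        order = df.index.drop_duplicates()
        df = df.groupby(level=0, sort=False).mean().loc[order]
    return validate_expression(df)


def read_response(path: str | Path) -> pd.DataFrame:
    """Read a drugs x cell-lines AUC table (CSV or TSV by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = df.apply(pd.to_numeric, errors="coerce")
    return validate_response(df)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def write_response(response: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    response.to_csv(path, sep=sep, index_label="drug_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name TAB description TAB gene TAB gene ...

    Genes are deduplicated preserving order. An empty file yields an empty
    collection (warned). Returns a mapping set-name -> gene list; descriptions
    are kept on the returned dict under the ``.descriptions`` attribute-free
    convention of a parallel mapping accessible via :func:`read_gmt_full`.
    """
    sets, _ = read_gmt_full(path)
    return sets


def read_gmt_full(path: str | Path) -> tuple[dict[str, list[str]], dict[str, str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate gene-set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ParseError(f"{path}: line {lineno}: gene set {name!r} empty after deduplication")
            sets[name] = genes
            descriptions[name] = desc
    if not sets:
        logger.warning("%s: GMT file contains no gene sets", path)
    return sets, descriptions


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def write_dgcp_library(lib: DGCPLibrary, path: str | Path) -> None:
    """Write a DGCP library as a single JSON document (lossless round trip)."""
    doc = {
        "format_version": LIBRARY_FORMAT_VERSION,
        "lineage_label": lib.lineage_label,
        "gene_universe": list(lib.gene_universe),
        "provenance": lib.provenance,
        "dgcps": {
            drug: {
                "genes": [str(g) for g in d.genes],
                "pcc": [float(v) for v in d.pcc],
                "n_cell_lines": int(d.n_cell_lines),
            }
            for drug, d in lib.dgcps.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def read_dgcp_library(path: str | Path) -> DGCPLibrary:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: corrupted DGCP library (JSON error at line {exc.lineno})") from exc
    version = doc.get("format_version")
    if version != LIBRARY_FORMAT_VERSION:
        raise ParseError(
            f"{path}: DGCP library format version {version!r} != supported {LIBRARY_FORMAT_VERSION}"
        )
    universe = list(doc["gene_universe"])
    universe_set = set(universe)
    dgcps: dict[str, DGCP] = {}
    for drug, rec in doc["dgcps"].items():
        d = DGCP(drug, np.array(rec["genes"], dtype=object), np.array(rec["pcc"], float), int(rec["n_cell_lines"]))
        if set(d.genes) != universe_set:
            raise ParseError(f"{path}: DGCP {drug!r} does not cover the library gene universe")
        dgcps[drug] = d
    return DGCPLibrary(doc["lineage_label"], dgcps, universe, doc.get("provenance", {}))
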