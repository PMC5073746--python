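"""Readers and writers for the pipeline's on-disk formats.

Formats are deliberately plain text: expression matrices are TSV with a
``gene_id`` first column, sample sheets are CSV, gene-set maps are GMT or
two-column TSV, networks go out as GraphML plus a mirrored edge-list TSV.
Every reader/writer pair round-trips losslessly at 6-decimal precision.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .core import AnnotationTable, ExpressionMatrix, FormatError, SampleDesign

logger = logging.getLogger("vinestress")

FLOAT_FMT = "%.6f"


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> list[SampleDesign]:
    """Read a sample sheet CSV (sample_id,genotype,treatment,timepoint,replicate)."""
    path = Path(path)
    design = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "genotype", "treatment", "timepoint", "replicate"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(
                f"{path}: sample sheet must have columns {sorted(required)}"
            )
        for row in reader:
            design.append(
                SampleDesign(
                    sample_id=row["sample_id"],
                    genotype=row["genotype"],
                    treatment=row["treatment"],
                    timepoint=int(row["timepoint"]),
                    replicate=int(row["replicate"]),
                )
            )
    if not design:
        raise FormatError(f"{path}: empty sample sheet")
    return design


def write_design(design: list[SampleDesign], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "genotype", "treatment", "timepoint", "replicate"])
        for s in design:
            writer.writerow([s.sample_id, s.genotype, s.treatment, s.timepoint, s.replicate])


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: str | Path,
    design_path: str | Path,
    linear_scale: bool = False,
) -> ExpressionMatrix:
    """Read an expression TSV against a sample sheet.

    Rows containing any unparseable or missing value are dropped with a
    logged count.  ``linear_scale=True`` log2-transforms intensities at load.
    """
    path = Path(path)
    design = read_design(design_path)
    table = pd.read_csv(path, sep="\t", dtype={0: str})
    if table.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id', got {table.columns[0]!r}")
    table = table.set_index("gene_id")
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    missing = [s.sample_id for s in design if s.sample_id not in table.columns]
    if missing:
        raise FormatError(f"{path}: design sample column(s) missing from table: {missing}")
    table = table[[s.sample_id for s in design]]
    table = table.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(table.to_numpy()).all(axis=1)
    if bad.any():
        logger.info("dropped %d gene row(s) with missing/unparseable values", int(bad.sum()))
        table = table.loc[~bad]
    if linear_scale:
        table = np.log2(table)
    return ExpressionMatrix(table, design)


def write_expression_matrix(
    em: ExpressionMatrix, path: str | Path, design_path: str | Path | None = None
) -> None:
    path = Path(path)
    em.values.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)
    if design_path is not None:
        write_design(em.design, design_path)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> AnnotationTable:
    """Two-column TSV: gene id, annotation string (may be empty)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            mapping[parts[0]] = parts[1] if len(parts) > 1 else ""
    return AnnotationTable(mapping)


def write_annotation(annotation: AnnotationTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gene in annotation:
            fh.write(f"{gene}\t{annotation[gene]}\n")


# ---------------------------------------------------------------------------
# gene-set / term maps
# ---------------------------------------------------------------------------

def read_gene_term_map(path: str | Path) -> dict[str, set[str]]:
    """Read a term -> gene-set mapping from GMT or two-column TSV.

    GMT lines are ``term<TAB>description<TAB>gene...``; two-column lines are
    ``term<TAB>gene``.  The dialect is chosen per file: a ``.gmt`` suffix or
    any line with >= 3 fields means GMT.  Duplicate (term, gene) pairs are
    deduplicated (sets).
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.open() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty gene-set file")
    rows = [ln.split("\t") for ln in lines]
    is_gmt = path.suffix.lower() == ".gmt" or any(len(r) > 2 for r in rows)
    mapping: dict[str, set[str]] = {}
    if is_gmt:
        for i, r in enumerate(rows, start=1):
            if len(r) < 3:
                raise FormatError(f"{path}:{i}: GMT line has {len(r)} field(s), need >= 3")
            mapping.setdefault(r[0], set()).update(g for g in r[2:] if g)
    else:
        for i, r in enumerate(rows, start=1):
            if len(r) != 2:
                raise FormatError(f"{path}:{i}: expected 'term<TAB>gene'")
            mapping.setdefault(r[0], set()).add(r[1])
    return mapping


def write_gene_term_map(mapping: Mapping[str, set[str]], path: str | Path) -> None:
    """Write a term map as GMT (description field carries the set size)."""
    with Path(path).open("w") as fh:
        for term in sorted(mapping):
            genes = sorted(mapping[term])
            fh.write("\t".join([term, f"n={len(genes)}"] + genes) + "\n")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(
    graph: nx.Graph, path: str | Path, edge_list_path: str | Path | None = None
) -> None:
    """Write a co-expression network as GraphML plus an edge-list TSV mirror.

    Node topology attributes (module, Z, P, APCC, region, role) are carried
    when present; edge ``weight`` is the signed Pearson correlation.
    """
    path = Path(path)
    out = nx.Graph()
    out.graph.update(graph.graph)
    for node, attrs in graph.nodes(data=True):
        clean = {}
        for k, v in attrs.items():
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            if isinstance(v, (np.floating,)):
                v = round(float(v), 6)
            elif isinstance(v, float):
                v = round(v, 6)
            elif isinstance(v, (np.integer,)):
                v = int(v)
            clean[k] = v
        out.add_node(node, **clean)
    for u, v, attrs in graph.edges(data=True):
        w = attrs.get("weight")
        out.add_edge(u, v, weight=round(float(w), 6) if w is not None else 0.0)
    nx.write_graphml(out, path)
    if edge_list_path is not None:
        with Path(edge_list_path).open("w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, attrs in out.edges(data=True):
                fh.write(f"{u}\t{v}\t{attrs['weight']:.6f}\n")


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(Path(path))


# ---------------------------------------------------------------------------
# small JSON results
# ---------------------------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
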