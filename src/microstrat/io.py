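"""File readers and writers for every pipeline artefact.

Dialects
--------
OTU table TSV: OTUs x samples, first column ``#OTU ID``, last column
``taxonomy`` with a semicolon lineage string (internally the table is
transposed to samples x OTUs).  BIOM-JSON: format-1.0 JSON, dense or sparse.
Trees: newick.  Metadata / FFQ / labels: CSV with a header row.  Distance
matrices and ordinations: square / rectangular TSV with ids in header and
first column.

All writers accept an optional provenance string (config hash + seed) that is
embedded as leading ``#`` comment lines; all readers skip such lines.
Floats are written with 17 significant digits so that read(write(x)) == x
within 1e-12.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .associations import FfqTable
from .community import OtuTable
from .ordination import Ordination

__all__ = [
    "read_otu_tsv", "write_otu_tsv", "read_biom_json",
    "read_tree", "write_tree",
    "read_metadata_csv", "write_metadata_csv",
    "read_ffq", "write_ffq",
    "read_distance_tsv", "write_distance_tsv",
    "read_ordination_tsv", "write_ordination_tsv",
    "read_labels_csv", "write_labels_csv",
    "write_edge_list", "read_edge_list",
]

FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed input file."""


def _comment_header(provenance: str | None) -> str:
    return f"# {provenance}\n" if provenance else ""


def _check_unique(values, what: str) -> None:
    s = pd.Series(values)
    dup = s[s.duplicated()].unique().tolist()
    if dup:
        raise ParseError(f"duplicate {what}: {dup[:5]}")


def write_otu_tsv(table: OtuTable, path, provenance: str | None = None) -> None:
    """OTUs x samples TSV with an ``#OTU ID`` id column and trailing
    ``taxonomy`` lineage column."""
    path = Path(path)
    df = table.counts.T.copy()
    df.insert(len(df.columns), "taxonomy", table.taxonomy)
    with path.open("w") as fh:
        fh.write(_comment_header(provenance))
        fh.write("#OTU ID\t" + "\t".join(map(str, table.counts.index)) + "\ttaxonomy\n")
        for otu, row in df.iterrows():
            counts = "\t".join(str(int(v)) for v in row.iloc[:-1])
            fh.write(f"{otu}\t{counts}\t{row.iloc[-1]}\n")


def read_otu_tsv(path) -> OtuTable:
    path = Path(path)
    header = None
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#OTU ID"):
                header = line.split("\t")
                continue
            if line.startswith("#"):
                continue
            if header is None:
                raise ParseError(f"{path}:{lineno}: data before '#OTU ID' header")
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            rows.append(parts)
    if header is None:
        raise ParseError(f"{path}: missing '#OTU ID' header")
    if header[-1] != "taxonomy":
        raise ParseError(f"{path}: last column must be 'taxonomy'")
    samples = header[1:-1]
    _check_unique(samples, "sample ids")
    otu_ids = [r[0] for r in rows]
    _check_unique(otu_ids, "OTU ids")
    counts = np.array([[int(v) for v in r[1:-1]] for r in rows], dtype=int)
    taxonomy = pd.Series([r[-1] for r in rows], index=otu_ids)
    return OtuTable(
        counts=pd.DataFrame(counts.T, index=samples, columns=otu_ids),
        taxonomy=taxonomy,
    )


def read_biom_json(path) -> OtuTable:
    """Minimal BIOM format-1.0 (JSON) reader, dense or sparse OTU tables."""
    with Path(path).open() as fh:
        doc = json.load(fh)
    try:
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = doc["shape"]
        mtype = doc.get("matrix_type", "sparse")
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: not a BIOM 1.0 JSON table ({exc})")
    _check_unique(otu_ids, "OTU ids")
    _check_unique(sample_ids, "sample ids")
    mat = np.zeros((shape[0], shape[1]))
    if mtype == "dense":
        mat[:] = np.asarray(data, dtype=float)
    else:
        for r, c, v in data:
            mat[int(r), int(c)] = v
    taxa = []
    for r in doc["rows"]:
        t = (r.get("metadata") or {}).get("taxonomy", "")
        taxa.append(";".join(t) if isinstance(t, (list, tuple)) else str(t))
    return OtuTable(
        counts=pd.DataFrame(mat.T.astype(int), index=sample_ids, columns=otu_ids),
        taxonomy=pd.Series(taxa, index=otu_ids),
    )


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_metadata_csv(metadata: pd.DataFrame, path, provenance: str | None = None) -> None:
    with Path(path).open("w") as fh:
        fh.write(_comment_header(provenance))
        metadata.to_csv(fh, index_label="sample", float_format=FLOAT_FMT)


def read_metadata_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", index_col="sample")
    _check_unique(df.index, "sample ids")
    return df


def write_ffq(ffq: FfqTable, consumption_path, annotation_path, provenance: str | None = None) -> None:
    with Path(consumption_path).open("w") as fh:
        fh.write(_comment_header(provenance))
        ffq.consumption.to_csv(fh, index_label="sample", float_format=FLOAT_FMT)
    with Path(annotation_path).open("w") as fh:
        fh.write(_comment_header(provenance))
        ffq.annotations.to_csv(fh, index_label="food", float_format=FLOAT_FMT)


def read_ffq(consumption_path, annotation_path) -> FfqTable:
    """Read an FFQ; consumption columns holding frequency-category strings are
    converted to daily values through the default dialect."""
    cons = pd.read_csv(consumption_path, comment="#", index_col="sample")
    _check_unique(cons.index, "sample ids")
    ann = pd.read_csv(annotation_path, comment="#", index_col="food")
    _check_unique(ann.index, "food ids")
    if any(dt == object for dt in cons.dtypes):
        from .associations import convert_ffq_frequencies
        cons = convert_ffq_frequencies(cons)
    return FfqTable(consumption=cons, annotations=ann)


def write_distance_tsv(dm: DistanceMatrix, path, provenance: str | None = None) -> None:
    with Path(path).open("w") as fh:
        fh.write(_comment_header(provenance))
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            fh, sep="\t", index_label="id", float_format=FLOAT_FMT
        )


def read_distance_tsv(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="id")
    _check_unique(df.index, "ids")
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: row and column ids differ")
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


def write_ordination_tsv(ordination: Ordination, path, provenance: str | None = None) -> None:
    """Coordinates TSV plus a ``<path>.eigen.tsv`` sidecar of eigenvalues and
    explained proportions."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_comment_header(provenance))
        fh.write(f"# method={ordination.method}\n")
        ordination.coordinates.to_csv(fh, sep="\t", index_label="sample", float_format=FLOAT_FMT)
    side = path.with_suffix(path.suffix + ".eigen.tsv")
    with side.open("w") as fh:
        fh.write(_comment_header(provenance))
        pd.DataFrame({
            "axis": ordination.coordinates.columns,
            "eigenvalue": ordination.eigenvalues,
            "proportion_explained": ordination.proportion_explained,
        }).to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_ordination_tsv(path) -> Ordination:
    path = Path(path)
    method = "pcoa"
    with path.open() as fh:
        for line in fh:
            if line.startswith("# method="):
                method = line.strip().split("=", 1)[1]
    coords = pd.read_csv(path, sep="\t", comment="#", index_col="sample")
    side = path.with_suffix(path.suffix + ".eigen.tsv")
    eig = pd.read_csv(side, sep="\t", comment="#")
    return Ordination(
        coordinates=coords,
        eigenvalues=eig["eigenvalue"].to_numpy(),
        proportion_explained=eig["proportion_explained"].to_numpy(),
        method=method,
    )


def write_labels_csv(labels: pd.Series | pd.DataFrame, path, provenance: str | None = None) -> None:
    df = labels.to_frame() if isinstance(labels, pd.Series) else labels
    with Path(path).open("w") as fh:
        fh.write(_comment_header(provenance))
        df.to_csv(fh, index_label="sample")


def read_labels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", index_col="sample")
    _check_unique(df.index, "sample ids")
    return df


def write_edge_list(edges: pd.DataFrame, path, provenance: str | None = None) -> None:
    """CAG network edges as TSV (genus_a, genus_b, tau_b, q, sign)."""
    with Path(path).open("w") as fh:
        fh.write(_comment_header(provenance))
        edges.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_edge_list(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
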