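"""Readers and writers for the plain-text formats the package exchanges.

* GCT 1.3 (``#1.3`` header) for signature matrices, with ``entity_id``,
  ``cell_line`` and ``pert_type`` carried as column metadata.
* Long TSV (``entity_id, cell_line, gene_id, z``) and wide TSV
  (genes x ``entity|cell`` columns) for signatures.
* Interaction TSV (``compound_id, protein_id, definition, affinity_type,
  affinity_value_uM, active_flag, source_db``).
* Sparse triplet TSV for label matrices and a disease-target TSV
  (``disease_id, protein_id, required_mode``).
"""

from __future__ import annotations

from collections.abc import Iterable
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .signatures import GeneSpace, SignatureSet

COLUMN_META = ("entity_id", "cell_line", "pert_type")

INTERACTION_COLUMNS = (
    "compound_id",
    "protein_id",
    "definition",
    "affinity_type",
    "affinity_value_uM",
    "active_flag",
    "source_db",
)


# ---------------------------------------------------------------------------
# GCT 1.3


def write_gct(sigset: SignatureSet, path: str | Path) -> None:
    """Write a (replicate-collapsed) SignatureSet as GCT 1.3 text."""
    keys = sigset.keys()
    genes = list(sigset.gene_space.gene_ids)
    n_rows, n_cols = len(genes), len(keys)
    with open(path, "w") as fh:
        fh.write("#1.3\n")
        fh.write(f"{n_rows}\t{n_cols}\t0\t{len(COLUMN_META)}\n")
        cids = [f"{e}|{c}" for e, c in keys]
        fh.write("\t".join(["id", *cids]) + "\n")
        meta_rows = {
            "entity_id": [e for e, _ in keys],
            "cell_line": [c for _, c in keys],
            "pert_type": [sigset.pert_type] * n_cols,
        }
        for name in COLUMN_META:
            fh.write("\t".join([name, *meta_rows[name]]) + "\n")
        mat = np.column_stack([sigset.get(*k) for k in keys]) if keys else None
        for i, gene in enumerate(genes):
            row = mat[i] if mat is not None else []
            fh.write("\t".join([gene, *(repr(float(v)) for v in row)]) + "\n")


def read_gct(path: str | Path) -> SignatureSet:
    """Read a GCT 1.3 text file written by :func:`write_gct` (or compatible)."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.3":
            raise InputError(f"{path}: expected '#1.3' header, got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 4:
            raise InputError(f"{path}: malformed dimensions line")
        n_rows, n_cols, n_rmeta, n_cmeta = map(int, dims)
        header = fh.readline().rstrip("\n").split("\t")
        cids = header[1 + n_rmeta :]
        if len(cids) != n_cols:
            raise InputError(f"{path}: expected {n_cols} column ids, got {len(cids)}")
        cmeta: dict[str, list[str]] = {}
        for _ in range(n_cmeta):
            parts = fh.readline().rstrip("\n").split("\t")
            cmeta[parts[0]] = parts[1 + n_rmeta :]
        genes: list[str] = []
        data = np.empty((n_rows, n_cols))
        for i in range(n_rows):
            parts = fh.readline().rstrip("\n").split("\t")
            genes.append(parts[0])
            data[i] = [float(v) for v in parts[1 + n_rmeta : 1 + n_rmeta + n_cols]]

    entities = cmeta.get("entity_id") or [cid.split("|")[0] for cid in cids]
    cells = cmeta.get("cell_line") or [
        cid.split("|", 1)[1] if "|" in cid else "plate" for cid in cids
    ]
    pert = (cmeta.get("pert_type") or ["chemical"] * n_cols)[0] if n_cols else "chemical"
    out = SignatureSet(GeneSpace(tuple(genes)), pert)
    for j in range(n_cols):
        out.add(entities[j], cells[j], data[:, j])
    return out


# ---------------------------------------------------------------------------
# long / wide TSV signatures


def read_long_tsv(path: str | Path, *, pert_type: str = "chemical") -> SignatureSet:
    """Read signatures from a long TSV: entity_id, cell_line, gene_id, z."""
    df = pd.read_csv(path, sep="\t", dtype={"entity_id": str, "cell_line": str, "gene_id": str})
    required = {"entity_id", "cell_line", "gene_id", "z"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: long TSV needs columns {sorted(required)}")
    genes = list(dict.fromkeys(df["gene_id"]))
    gene_space = GeneSpace(tuple(genes))
    wide = df.pivot_table(
        index="gene_id", columns=["entity_id", "cell_line"], values="z"
    ).reindex(genes)
    if wide.isna().any().any():
        raise InputError(f"{path}: missing (entity, cell, gene) combinations")
    out = SignatureSet(gene_space, pert_type)
    for entity, cell in wide.columns:
        out.add(str(entity), str(cell), wide[(entity, cell)].to_numpy())
    return out


def read_wide_tsv(path: str | Path, *, pert_type: str = "chemical") -> SignatureSet:
    """Read genes x signatures wide TSV; columns named ``entity|cell``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    out = SignatureSet(GeneSpace(tuple(str(g) for g in df.index)), pert_type)
    for col in df.columns:
        entity, _, cell = str(col).partition("|")
        out.add(entity, cell or "plate", df[col].to_numpy(dtype=float))
    return out


def write_wide_tsv(sigset: SignatureSet, path: str | Path) -> None:
    sigset.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# interactions, label matrices, disease targets


def read_interactions_tsv(path: str | Path):
    """Read raw interaction records; returns a list of InteractionRecord."""
    from .gold_standard import InteractionRecord

    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "protein_id": str})
    missing = set(INTERACTION_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise InputError(f"{path}: interaction TSV needs columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        affinity = getattr(row, "affinity_value_uM", None)
        affinity = None if affinity is None or pd.isna(affinity) else float(affinity)
        flag = getattr(row, "active_flag", None)
        if flag is None or pd.isna(flag):
            flag = None
        else:
            flag = str(flag).strip().lower() in ("1", "true", "yes")
        records.append(
            InteractionRecord(
                compound_id=str(row.compound_id),
                protein_id=str(row.protein_id),
                definition=str(getattr(row, "definition", "") or ""),
                affinity_type=str(getattr(row, "affinity_type", "none") or "none"),
                affinity_value=affinity,
                active_flag=flag,
                source_db=str(getattr(row, "source_db", "") or ""),
            )
        )
    return records


def write_interactions_tsv(records: Iterable, path: str | Path) -> None:
    rows = [
        {
            "compound_id": r.compound_id,
            "protein_id": r.protein_id,
            "definition": r.definition,
            "affinity_type": r.affinity_type,
            "affinity_value_uM": r.affinity_value,
            "active_flag": r.active_flag,
            "source_db": r.source_db,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(INTERACTION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def write_label_triplets(matrix, path: str | Path) -> None:
    """Export a LabelMatrix as sparse triplets (only in-play pairs)."""
    rows = []
    mask = matrix.mask if matrix.mask is not None else np.ones_like(matrix.labels, bool)
    for i, compound in enumerate(matrix.compounds):
        for j, protein in enumerate(matrix.proteins):
            if mask[i, j]:
                rows.append((compound, protein, matrix.mode, int(matrix.labels[i, j])))
    pd.DataFrame(rows, columns=["compound_id", "protein_id", "mode", "label"]).to_csv(
        path, sep="\t", index=False
    )


def write_feature_tsv(features, path: str | Path) -> None:
    """FeatureMatrix as entities x features TSV."""
    cols = (
        list(features.feature_names)
        if features.feature_names
        else [f"f{j}" for j in range(features.n_features)]
    )
    pd.DataFrame(features.X, index=list(features.ids), columns=cols).to_csv(
        path, sep="\t", index_label="entity_id"
    )


def read_feature_tsv(path: str | Path):
    from .jl import FeatureMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureMatrix(
        tuple(str(i) for i in df.index),
        df.to_numpy(dtype=float),
        tuple(str(c) for c in df.columns),
    )


def read_label_triplets(path: str | Path):
    """Rebuild a LabelMatrix from sparse triplet TSV.

    Universes are the entities appearing in the file; pairs absent from the
    file are marked out of play via the mask (a full export has no mask).
    """
    from .gold_standard import LabelMatrix

    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "protein_id": str})
    compounds = tuple(dict.fromkeys(df["compound_id"]))
    proteins = tuple(dict.fromkeys(df["protein_id"]))
    mode = df["mode"].iloc[0]
    cidx = {c: i for i, c in enumerate(compounds)}
    pidx = {p: j for j, p in enumerate(proteins)}
    labels = np.full((len(compounds), len(proteins)), -1, dtype=np.int8)
    mask = np.zeros_like(labels, dtype=bool)
    for row in df.itertuples(index=False):
        i, j = cidx[row.compound_id], pidx[row.protein_id]
        labels[i, j] = row.label
        mask[i, j] = True
    return LabelMatrix(mode, compounds, proteins, labels, None if mask.all() else mask)


def write_positives_tsv(positives: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """(compound, protein, mode) triples as TSV."""
    pd.DataFrame(
        sorted(positives), columns=["compound_id", "protein_id", "mode"]
    ).to_csv(path, sep="\t", index=False)


def read_positives_tsv(path: str | Path) -> set[tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {(r.compound_id, r.protein_id, r.mode) for r in df.itertuples(index=False)}


def read_disease_targets_tsv(path: str | Path) -> dict[str, set[tuple[str, str]]]:
    """Disease therapeutic-target table -> {disease: {(protein, mode)}}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"disease_id", "protein_id", "required_mode"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: disease TSV needs columns {sorted(required)}")
    out: dict[str, set[tuple[str, str]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.disease_id, set()).add((row.protein_id, row.required_mode))
    return out
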