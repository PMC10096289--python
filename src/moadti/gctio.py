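"""Readers and writers for the pipeline's external text formats.

GCT 1.2/1.3 text matrices (rows = genes, columns = signatures), typed TSV
tables, the signature-metadata table, embedding tables, target-vector stores
and run manifests.  GCTX/HDF5 is deliberately out: the text GCT dialect is
the tested contract.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .compounds import EmbeddingTable
from .exceptions import ParseError
from .ppi import TargetVectorStore
from .signatures import GenePanel, Signature

NA_TOKEN = "NA"


# ---------------------------------------------------------------- GCT text

def read_gct(path) -> pd.DataFrame:
    """Read a GCT 1.2 or 1.3 text matrix as rows=genes x cols=samples.

    1.3 row/column metadata blocks are skipped; the numeric matrix and the
    row/column identifiers are returned.  Raises on version or dimension
    mismatches.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().strip()
        dims_line = fh.readline().strip()
        if version not in ("#1.2", "#1.3"):
            raise ParseError(f"{path.name}: unknown GCT version line {version!r}")
        dims = dims_line.split("\t")
        if version == "#1.2":
            if len(dims) != 2:
                raise ParseError(f"{path.name}: GCT 1.2 dimension line needs 2 fields")
            n_rows, n_cols = int(dims[0]), int(dims[1])
            n_rmeta, n_cmeta = 0, 0
        else:
            if len(dims) != 4:
                raise ParseError(f"{path.name}: GCT 1.3 dimension line needs 4 fields")
            n_rows, n_cols, n_rmeta, n_cmeta = map(int, dims)
        header = fh.readline().rstrip("\n").split("\t")
        expected_width = 1 + 1 + n_rmeta + n_cols if version == "#1.3" else 2 + n_cols
        if version == "#1.2":
            col_ids = header[2:]
        else:
            col_ids = header[2 + n_rmeta:]
        if len(header) != expected_width or len(col_ids) != n_cols:
            raise ParseError(
                f"{path.name}: header width {len(header)} != declared {expected_width}"
            )
        for _ in range(n_cmeta):  # 1.3 column-metadata rows
            fh.readline()
        row_ids, data = [], []
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != expected_width:
                raise ParseError(
                    f"{path.name}: data row {lineno} width {len(parts)} "
                    f"!= {expected_width}"
                )
            row_ids.append(parts[0])
            values = parts[2 + n_rmeta:] if version == "#1.3" else parts[2:]
            data.append([np.nan if v == NA_TOKEN else float(v) for v in values])
    if len(row_ids) != n_rows:
        raise ParseError(f"{path.name}: {len(row_ids)} data rows, declared {n_rows}")
    return pd.DataFrame(np.array(data, dtype=float), index=row_ids, columns=col_ids)


def write_gct(path, matrix: pd.DataFrame) -> None:
    """Write rows=genes x cols=samples as GCT 1.2 text."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        fh.write("NAME\tDescription\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for rid, row in zip(matrix.index, matrix.to_numpy()):
            vals = "\t".join(NA_TOKEN if np.isnan(v) else repr(float(v)) for v in row)
            fh.write(f"{rid}\t{NA_TOKEN}\t{vals}\n")


# ---------------------------------------------------------------- TSV tables

def read_tsv_table(path, required_columns=None) -> pd.DataFrame:
    """UTF-8 TSV with a header row; 'NA' is the missing-value token."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_TOKEN],
                     keep_default_na=False, encoding="utf-8")
    if required_columns:
        missing = set(required_columns) - set(df.columns)
        if missing:
            raise ParseError(f"{Path(path).name}: missing columns {sorted(missing)}")
    return df


def write_tsv_table(path, df: pd.DataFrame) -> None:
    for col in df.columns:
        if df[col].dtype == object and df[col].astype(str).str.contains("\t").any():
            raise ParseError(f"column {col!r} contains embedded tab characters")
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, encoding="utf-8")


# ------------------------------------------------------- domain round-trips

def read_signatures(gct_path, metadata_path) -> tuple[list[Signature], GenePanel]:
    """Signatures from a GCT matrix plus a metadata TSV.

    Metadata columns: signature_id, perturbed_gene, perturbation_kind,
    cell_line, condition.  Every metadata row must have a GCT column.
    """
    matrix = read_gct(gct_path)
    meta = read_tsv_table(
        metadata_path,
        required_columns=[
            "signature_id", "perturbed_gene", "perturbation_kind",
            "cell_line", "condition",
        ],
    )
    panel = GenePanel(tuple(matrix.index))
    signatures = []
    for row in meta.itertuples(index=False):
        if row.signature_id not in matrix.columns:
            raise ParseError(f"signature {row.signature_id!r} absent from GCT matrix")
        signatures.append(
            Signature(
                values=matrix[row.signature_id].to_numpy(),
                perturbed_gene=row.perturbed_gene,
                perturbation_kind=row.perturbation_kind,
                cell_line=row.cell_line,
                condition=row.condition,
                signature_id=row.signature_id,
                panel=panel,
            )
        )
    return signatures, panel


def write_signatures(gct_path, metadata_path, signatures: list[Signature]) -> None:
    panel = signatures[0].panel
    matrix = pd.DataFrame(
        np.column_stack([s.values for s in signatures]),
        index=list(panel.gene_ids),
        columns=[s.signature_id for s in signatures],
    )
    write_gct(gct_path, matrix)
    meta = pd.DataFrame(
        [
            {
                "signature_id": s.signature_id,
                "perturbed_gene": s.perturbed_gene,
                "perturbation_kind": s.perturbation_kind,
                "cell_line": s.cell_line,
                "condition": s.condition,
            }
            for s in signatures
        ]
    )
    write_tsv_table(metadata_path, meta)


def read_embedding_table(path, unk_policy: str = "skip") -> EmbeddingTable:
    """token, v1..vd TSV -> EmbeddingTable."""
    df = read_tsv_table(path)
    if "token" not in df.columns or df.shape[1] < 2:
        raise ParseError(f"{Path(path).name}: expected columns token, v1..vd")
    vec_cols = [c for c in df.columns if c != "token"]
    return EmbeddingTable(
        {
            str(row["token"]): np.array([float(row[c]) for c in vec_cols])
            for _, row in df.iterrows()
        },
        unk_policy=unk_policy,
    )


def write_embedding_table(path, table: EmbeddingTable) -> None:
    rows = []
    for token in sorted(table.vectors):
        rows.append({"token": token, **{
            f"v{i + 1}": repr(float(x)) for i, x in enumerate(table.vectors[token])
        }})
    write_tsv_table(path, pd.DataFrame(rows))


def write_target_store(gct_path, provenance_path, store: TargetVectorStore,
                       panel: GenePanel) -> None:
    """Consensus vectors as GCT (cols keyed gene|provenance) + provenance TSV."""
    cols, names, prov_rows = [], [], []
    for gene in store.genes():
        for provenance in ("measured", "inferred"):
            if store.has(gene, provenance):
                tv = store.get(gene, provenance)
                cols.append(tv.vector)
                names.append(f"{gene}|{provenance}")
                prov_rows.append(
                    {"gene": gene, "provenance": provenance,
                     "n_support": str(tv.n_support), "mode": store.mode}
                )
    matrix = pd.DataFrame(
        np.column_stack(cols), index=list(panel.gene_ids), columns=names
    )
    write_gct(gct_path, matrix)
    write_tsv_table(provenance_path, pd.DataFrame(prov_rows))


def read_target_store(gct_path, provenance_path) -> tuple[TargetVectorStore, GenePanel]:
    matrix = read_gct(gct_path)
    prov = read_tsv_table(
        provenance_path, required_columns=["gene", "provenance", "n_support", "mode"]
    )
    store = TargetVectorStore(prov["mode"].iloc[0])
    for row in prov.itertuples(index=False):
        col = f"{row.gene}|{row.provenance}"
        store.add(row.gene, matrix[col].to_numpy(), row.provenance, int(row.n_support))
    return store, GenePanel(tuple(matrix.index))


def read_dti_table(path) -> pd.DataFrame:
    return read_tsv_table(
        path, required_columns=["compound_id", "target_gene", "moa_term"]
    )


def read_ppi_edges(path, id_map_path=None):
    """STRING-style TSV -> ((a, b, score), ...) row iterator + optional id map."""
    df = read_tsv_table(
        path, required_columns=["protein1", "protein2", "combined_score"]
    )
    rows = [
        (r.protein1, r.protein2, r.combined_score) for r in df.itertuples(index=False)
    ]
    id_map = None
    if id_map_path is not None:
        mdf = read_tsv_table(id_map_path, required_columns=["protein_id", "gene_symbol"])
        id_map = dict(zip(mdf["protein_id"], mdf["gene_symbol"]))
    return rows, id_map


# ------------------------------------------------------------- manifests

def write_manifest(path, payload: dict) -> None:
    """JSON manifest recording enough to re-run the producing command."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
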