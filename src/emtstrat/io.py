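"""File readers and writers.

Formats are deliberately plain text: MatrixMarket coordinate files with
one-column observation / gene ID sidecars, dense TSV with a header row of
gene symbols, a three-column signature TSV (signature_name, gene,
set_role), a methylation TSV (sample_id, group, one column per probe), and
a two-column annotation TSV.  Gene symbols are normalised (upper-cased,
whitespace-stripped) on the way in; no alias or HGNC resolution is
attempted — the analysis matches plain symbols.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import DuplicateIDError, FormatError, ValidationError
from .types import ExpressionMatrix, GeneSignature, MethylationTable, SignatureRegistry


def normalize_gene_symbols(gene_ids) -> tuple[list[str], dict[str, str]]:
    """Upper-case and strip raw gene identifiers.

    Returns the normalised list and a mapping of the identifiers that
    changed (raw -> normalised), for logging.  Raises
    :class:`DuplicateIDError` if normalisation creates a collision
    (e.g. ``MCAM`` and ``mcam`` in the same file).
    """
    normalized: list[str] = []
    changed: dict[str, str] = {}
    for raw in gene_ids:
        raw = str(raw)
        norm = raw.strip().upper()
        if norm != raw:
            changed[raw] = norm
        normalized.append(norm)
    seen: set[str] = set()
    dups = [g for g in normalized if g in seen or seen.add(g)]
    if dups:
        raise DuplicateIDError("gene (after symbol normalisation)", dups)
    return normalized, changed


def _read_id_file(path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                ids.append(line)
    return ids


def read_mtx_triplet(matrix_path, obs_path, gene_path, scale, obs_kind) -> ExpressionMatrix:
    """Read a MatrixMarket coordinate matrix (obs x genes) plus ID files.

    The coordinate file holds the nonzeros; absent entries are 0
    expression.  Dimension mismatches between the header and the ID files
    are rejected.
    """
    try:
        mat = scipy.io.mmread(matrix_path)
    except Exception as exc:  # scipy raises ValueError on malformed headers
        raise FormatError(f"{matrix_path}: not a readable MatrixMarket file: {exc}") from exc
    obs_ids = _read_id_file(obs_path)
    raw_genes = _read_id_file(gene_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (len(obs_ids), len(raw_genes)):
        raise FormatError(
            f"matrix is {mat.shape[0]} x {mat.shape[1]} but ID files declare "
            f"{len(obs_ids)} observations x {len(raw_genes)} genes"
        )
    gene_ids, _ = normalize_gene_symbols(raw_genes)
    return ExpressionMatrix(
        obs_ids=obs_ids, gene_ids=gene_ids, values=mat, scale=scale, obs_kind=obs_kind
    )


def write_mtx_triplet(matrix: ExpressionMatrix, matrix_path, obs_path, gene_path) -> None:
    """Write an ExpressionMatrix as MTX coordinate + ID sidecar files."""
    sparse = scipy.sparse.coo_matrix(matrix.values)
    scipy.io.mmwrite(str(matrix_path), sparse, precision=10)
    Path(obs_path).write_text("".join(f"{o}\n" for o in matrix.obs_ids))
    Path(gene_path).write_text("".join(f"{g}\n" for g in matrix.gene_ids))


def read_dense_tsv(path, scale, obs_kind) -> ExpressionMatrix:
    """Read a dense TSV: header row = gene symbols, first column = obs IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no gene columns found")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric value {raw[i, j]!r} at row "
                    f"{df.index[i]!r}, column {df.columns[j]!r}"
                ) from None
    if np.any(np.isnan(values)):
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        raise FormatError(
            f"{path}: missing value at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    gene_ids, _ = normalize_gene_symbols(list(df.columns))
    return ExpressionMatrix(
        obs_ids=list(df.index), gene_ids=gene_ids, values=values,
        scale=scale, obs_kind=obs_kind,
    )


def write_dense_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="obs_id", float_format="%.10g")


def read_signature_file(path, registry: SignatureRegistry | None = None) -> SignatureRegistry:
    """Load signatures from a TSV with columns signature_name, gene, set_role.

    set_role is ``positive`` or ``negative``.  Aggregation is inferred:
    ``sum_difference`` iff the signature has any negative rows, else
    ``mean``.  Parsing is order-independent — permuting rows yields the
    same registry.  Entries are added to ``registry`` (a fresh empty one by
    default), so signatures can be layered on top of the built-in defaults.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"signature_name", "gene", "set_role"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: expected columns {sorted(required)}, found {list(df.columns)}"
        )
    bad_roles = set(df["set_role"]) - {"positive", "negative"}
    if bad_roles:
        raise FormatError(f"{path}: unknown set_role values: {sorted(bad_roles)}")
    if registry is None:
        registry = SignatureRegistry()
    for name in sorted(df["signature_name"].unique()):
        rows = df[df["signature_name"] == name]
        pos_raw = rows.loc[rows["set_role"] == "positive", "gene"].tolist()
        neg_raw = rows.loc[rows["set_role"] == "negative", "gene"].tolist()
        pos, _ = normalize_gene_symbols(pos_raw) if pos_raw else ([], {})
        neg, _ = normalize_gene_symbols(neg_raw) if neg_raw else ([], {})
        both = set(pos) & set(neg)
        if both:
            raise ValidationError(
                f"signature {name!r}: gene(s) listed in both roles: "
                f"{', '.join(sorted(both))}"
            )
        if not pos and not neg:
            raise ValidationError(f"signature {name!r}: empty signature")
        aggregation = "sum_difference" if neg else "mean"
        # a file may redefine a built-in (e.g. a custom sEMT list); the
        # user-supplied definition wins
        registry.add(
            GeneSignature(
                name=name,
                aggregation=aggregation,
                positive_set=tuple(sorted(pos)),
                negative_set=tuple(sorted(neg)),
            ),
            replace=True,
        )
    return registry


def write_signature_file(registry: SignatureRegistry, path) -> None:
    rows = []
    for sig in registry.signatures.values():
        rows.extend({"signature_name": sig.name, "gene": g, "set_role": "positive"}
                    for g in sig.positive_set)
        rows.extend({"signature_name": sig.name, "gene": g, "set_role": "negative"}
                    for g in sig.negative_set)
    pd.DataFrame(rows, columns=["signature_name", "gene", "set_role"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotation_tsv(path) -> pd.DataFrame:
    """Read per-observation annotations: obs_id, cell_type, patient_id, subtype.

    Only obs_id and cell_type are required; returns a DataFrame indexed by
    obs_id.  Each observation must have exactly one row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "obs_id" not in df.columns or "cell_type" not in df.columns:
        raise FormatError(f"{path}: annotation needs obs_id and cell_type columns")
    if df["obs_id"].duplicated().any():
        raise DuplicateIDError("observation", df.loc[df["obs_id"].duplicated(), "obs_id"])
    return df.set_index("obs_id")


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="obs_id")


def read_methylation_tsv(path) -> MethylationTable:
    """Read a methylation TSV: sample_id, group, then one column per probe.

    Empty cells become NaN (explicitly missing, never 0); a sample with no
    available probes at all is rejected downstream, not here.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise FormatError(f"{path}: methylation table needs sample_id and group columns")
    probe_cols = [c for c in df.columns if c not in ("sample_id", "group")]
    if not probe_cols:
        raise FormatError(f"{path}: no probe columns found")
    M = df[probe_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    non_numeric = df[probe_cols].notna().to_numpy() & np.isnan(M)
    if non_numeric.any():
        i, j = map(int, np.argwhere(non_numeric)[0])
        raise FormatError(
            f"{path}: non-numeric M-value at sample {df['sample_id'].iloc[i]!r}, "
            f"probe {probe_cols[j]!r}"
        )
    return MethylationTable(
        sample_ids=df["sample_id"].tolist(),
        groups=df["group"].tolist(),
        probe_ids=probe_cols,
        M=M,
    )


def write_methylation_tsv(table: MethylationTable, path) -> None:
    df = table.to_frame()
    df.insert(0, "group", table.groups)
    df.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


def matrix_to_string_mtx(matrix: ExpressionMatrix) -> str:
    """Serialise the matrix body to a MatrixMarket string (for sidecars/tests)."""
    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, scipy.sparse.coo_matrix(matrix.values), precision=10)
    return buf.getvalue().decode()
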