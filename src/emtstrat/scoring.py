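"""Per-observation signature scores.

Two aggregation rules cover every signature in the analysis:

* ``sum_difference`` (the EMT score): score_i = sum over mesenchymal
  (positive-set) genes of x_ig minus sum over epithelial (negative-set)
  genes, so higher = more mesenchymal.  All twelve genes must be present
  unless ``allow_missing`` is set — a silently missing term would shift
  the score's scale against the fixed class boundaries (0/5 per cell,
  2,000/5,000 per bulk tumour).
* ``mean`` (invasion, stemness, angiogenesis scores): the arithmetic mean
  over the signature genes present in the matrix; absentees are recorded
  and warned about but tolerated, because published gene panels rarely
  match a matrix's gene universe exactly.

Duplicate gene columns are rejected by the matrix container itself, so a
sum can never double-count.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import MissingGeneError, ValidationError
from .types import ExpressionMatrix, GeneSignature, ScoreTable, SignatureRegistry

logger = logging.getLogger(__name__)


def score_signature(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    allow_missing: bool = False,
) -> ScoreTable:
    """Score one signature for every observation of the matrix.

    Returns a single-column :class:`ScoreTable` named after the signature,
    with metadata recording the genes used and any missing from the matrix.
    """
    present_pos = [g for g in signature.positive_set if matrix.has_gene(g)]
    present_neg = [g for g in signature.negative_set if matrix.has_gene(g)]
    missing = [g for g in signature.genes if not matrix.has_gene(g)]

    if signature.aggregation == "sum_difference":
        if missing and not allow_missing:
            raise MissingGeneError(missing, context=f"signature {signature.name!r}")
        pos_idx = [matrix.gene_ids.index(g) for g in present_pos]
        neg_idx = [matrix.gene_ids.index(g) for g in present_neg]
        score = matrix.values[:, pos_idx].sum(axis=1) - matrix.values[:, neg_idx].sum(axis=1)
    elif signature.aggregation == "mean":
        if not present_pos:
            raise MissingGeneError(
                signature.positive_set,
                context=f"signature {signature.name!r}: no signature gene present",
            )
        idx = [matrix.gene_ids.index(g) for g in present_pos]
        score = matrix.values[:, idx].mean(axis=1)
    else:  # pragma: no cover - unreachable, GeneSignature validates
        raise ValidationError(f"unknown aggregation {signature.aggregation!r}")

    if missing:
        logger.warning(
            "signature %s: %d gene(s) absent from matrix: %s",
            signature.name, len(missing), ", ".join(missing),
        )
    scores = pd.DataFrame({signature.name: score}, index=pd.Index(matrix.obs_ids, name="obs_id"))
    meta = {
        signature.name: {
            "aggregation": signature.aggregation,
            "n_genes_used": len(present_pos) + len(present_neg),
            "missing_genes": missing,
        }
    }
    return ScoreTable(scores=scores, scale=matrix.scale, obs_kind=matrix.obs_kind, meta=meta)


def score_all(
    matrix: ExpressionMatrix,
    registry: SignatureRegistry,
    allow_missing: bool = False,
) -> ScoreTable:
    """Score every registered signature; one column per signature."""
    if len(registry) == 0:
        raise ValidationError("signature registry is empty")
    columns = {}
    meta: dict[str, dict] = {}
    for name in registry.names():
        try:
            table = score_signature(matrix, registry[name], allow_missing=allow_missing)
        except MissingGeneError as exc:
            raise MissingGeneError(exc.genes, context=f"while scoring {name!r}") from exc
        columns[name] = table.scores[name]
        meta.update(table.meta)
    scores = pd.DataFrame(columns, index=pd.Index(matrix.obs_ids, name="obs_id"))
    return ScoreTable(scores=scores, scale=matrix.scale, obs_kind=matrix.obs_kind, meta=meta)


def scores_to_tsv(table: ScoreTable, path) -> None:
    """Write a score table as TSV (obs_id + one column per score)."""
    table.scores.to_csv(path, sep="\t", index_label="obs_id", float_format="%.10g")


def scores_from_tsv(path, scale: str, obs_kind: str) -> ScoreTable:
    df = pd.read_csv(path, sep="\t", index_col="obs_id")
    df.index = df.index.astype(str)
    return ScoreTable(scores=df, scale=scale, obs_kind=obs_kind)
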