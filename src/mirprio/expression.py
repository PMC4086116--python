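"""Expression-profile integration in Euclidean space.

Enrichment-derived significance, expression level and fold change are
heterogeneous quantities (reciprocal-p sums vs array intensities vs
ratios), so each component is first rescaled to [0, 1] by dividing by its
cohort maximum; the overall significance of an entity is then the
Euclidean (L2) norm of its three-component vector.  Entities missing
from the expression table contribute 0 on the expression axes, so with
no expression data at all the overall ranking collapses to the
enrichment-only ranking.

Up- and down-regulation are treated symmetrically: fold changes enter as
|log2 FC| (configurable to signed or raw).
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .io import ExpressionTable

logger = logging.getLogger(__name__)

__all__ = ["build_vectors", "overall_score", "rerank_with_expression"]

VECTOR_COLUMNS = ("sig_enrichment", "sig_expression", "sig_fold_change")


def _fold_magnitude(values: pd.Series, fold_is_log: bool, signed: bool) -> pd.Series:
    v = values.astype(float)
    if not fold_is_log:
        if (v <= 0).any():
            logger.warning(
                "non-positive fold changes found; treating column as already log-scaled"
            )
            logv = v
        else:
            logv = np.log2(v)
    else:
        logv = v
    return logv if signed else logv.abs()


def build_vectors(
    entity_scores: Mapping[str, float],
    expression: Optional[ExpressionTable] = None,
    fold_is_log: bool = False,
    signed_fold: bool = False,
) -> pd.DataFrame:
    """Per-entity significance vectors, each component max-rescaled to [0, 1].

    ``entity_scores`` are the final enrichment-derived scores (genes or
    miRs).  An all-zero component column is dropped (set to 0) with a
    warning.
    """
    entities = sorted(entity_scores)
    df = pd.DataFrame(0.0, index=pd.Index(entities, name="id"), columns=list(VECTOR_COLUMNS))
    df["sig_enrichment"] = [entity_scores[e] for e in entities]
    if expression is not None:
        rows = expression.rows
        present = [e for e in entities if e in rows.index]
        if "expression_level" in rows.columns:
            df.loc[present, "sig_expression"] = (
                rows.loc[present, "expression_level"].astype(float).fillna(0.0).to_numpy()
            )
        if "fold_change" in rows.columns:
            fc = rows.loc[present, "fold_change"]
            mask = fc.notna()
            mag = _fold_magnitude(fc[mask], fold_is_log, signed_fold)
            df.loc[mag.index, "sig_fold_change"] = mag.to_numpy()
    for col in VECTOR_COLUMNS:
        m = df[col].max()
        if m > 0:
            df[col] = df[col] / m
        elif (df[col] == 0).all():
            logger.warning("component %s is all zero and carries no signal", col)
    return df


def overall_score(vectors: pd.DataFrame) -> pd.Series:
    """Euclidean norm of each entity's significance vector."""
    arr = vectors[list(VECTOR_COLUMNS)].to_numpy(float)
    return pd.Series(np.linalg.norm(arr, axis=1), index=vectors.index, name="sig_overall")


def rerank_with_expression(
    entity_scores: Mapping[str, float],
    expression: Optional[ExpressionTable] = None,
    fold_is_log: bool = False,
    signed_fold: bool = False,
) -> pd.DataFrame:
    """Integrate expression and re-rank entities by the overall score.

    Returns a frame with the three components, ``sig_overall`` and
    ``rank`` (overall descending, id ascending on ties).
    """
    vectors = build_vectors(
        entity_scores, expression, fold_is_log=fold_is_log, signed_fold=signed_fold
    )
    vectors["sig_overall"] = overall_score(vectors)
    ordered = vectors.sort_values(
        ["sig_overall", "id"], ascending=[False, True], kind="mergesort"
    )
    vectors["rank"] = pd.Series(
        range(1, len(vectors) + 1), index=ordered.index
    ).astype(int)
    return vectors
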