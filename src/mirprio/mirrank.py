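"""miR scoring from the ranked gene table.

A miR inherits the significance of the mRNAs it targets: its score is
the sum of the final scores of its targets among the top alpha-fraction
of the ranked test-gene list (training-free mode), optionally multiplied
by the summed scores of its targets in the training set
(training-dependent mode).  The alpha cutoff focuses the sum on the
mRNAs most significant for the biological system; 0.4 is the default,
the fraction observed to perform best in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .compendium import InteractionCompendium, normalize_mir, targets_of
from .generank import GeneScoreTable

__all__ = [
    "MiRScoreTable",
    "DEFAULT_ALPHA",
    "top_fraction",
    "score_mirs_eq1",
    "score_mirs_eq2",
]

DEFAULT_ALPHA = 0.4


@dataclass(frozen=True)
class MiRScoreTable:
    """Ranked per-miR scores.

    ``table`` columns: mir, sig, n_targets_counted, mode, rank.  Ranks
    are a permutation of 1..n (sig descending, miR id ascending on
    ties); zero-score miRs are retained and ranked last so evaluation
    denominators stay fixed.
    """

    table: pd.DataFrame
    mode: str

    def __len__(self) -> int:
        return len(self.table)

    def rank_of(self, mir: str) -> int:
        m = normalize_mir(mir)
        row = self.table[self.table["mir"] == m]
        if row.empty:
            raise KeyError(f"miR {mir!r} not in table")
        return int(row["rank"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.sort_values("rank").to_csv(path, sep="\t", index=False)


def top_fraction(gene_table: GeneScoreTable, alpha: float) -> list[str]:
    """The first ceil(alpha * n) genes of the ranked list.

    The ceiling guarantees any alpha > 0 counts at least one gene.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    n = len(gene_table)
    cut = math.ceil(alpha * n)
    return gene_table.genes_by_rank[:cut]


def _assemble(rows: list[dict], mode: str) -> MiRScoreTable:
    df = pd.DataFrame(rows, columns=["mir", "sig", "n_targets_counted", "mode"])
    ordered = df.sort_values(["sig", "mir"], ascending=[False, True], kind="mergesort")
    df["rank"] = pd.Series(range(1, len(df) + 1), index=ordered.index).astype(int)
    return MiRScoreTable(table=df, mode=mode)


def score_mirs_eq1(
    mirs: Sequence[str],
    gene_table: GeneScoreTable,
    compendium: InteractionCompendium,
    alpha: float = DEFAULT_ALPHA,
) -> MiRScoreTable:
    """Training-free miR significance.

    Sig(miR) = sum of final scores of the genes in the top
    alpha-fraction of the ranked test list that the compendium lists as
    targets of the miR.
    """
    if not mirs:
        raise ValueError("empty candidate miR list")
    top = top_fraction(gene_table, alpha)
    top_set = frozenset(top)
    rows = []
    for mir in sorted({normalize_mir(m) for m in mirs}):
        counted = targets_of(compendium, mir, restrict_to=top_set)
        sig = sum(gene_table.final_score(g) for g in counted)
        rows.append(
            {"mir": mir, "sig": sig, "n_targets_counted": len(counted), "mode": "eq1"}
        )
    return _assemble(rows, mode="eq1")


def score_mirs_eq2(
    mirs: Sequence[str],
    gene_table: GeneScoreTable,
    train_table: GeneScoreTable,
    compendium: InteractionCompendium,
    alpha: float = DEFAULT_ALPHA,
) -> MiRScoreTable:
    """Training-dependent miR significance.

    Sig(miR) = (sum of final scores of the miR's targets within the
    training set) * (training-free sum over the top alpha-fraction of the
    test list).  A miR with no training-set targets scores 0 regardless
    of its test-set targets.
    """
    eq1 = score_mirs_eq1(mirs, gene_table, compendium, alpha=alpha)
    train_genes = frozenset(train_table.table.index)
    rows = []
    for row in eq1.table.itertuples():
        train_targets = targets_of(compendium, row.mir, restrict_to=train_genes)
        train_sum = sum(train_table.final_score(g) for g in train_targets)
        rows.append(
            {
                "mir": row.mir,
                "sig": train_sum * row.sig,
                "n_targets_counted": row.n_targets_counted,
                "mode": "eq2",
            }
        )
    return _assemble(rows, mode="eq2")
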