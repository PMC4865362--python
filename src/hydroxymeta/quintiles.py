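"""Expression normalisation and quintile partitioning.

Mean expression across samples is divided by each gene's total exonic length
(RNA-seq read counts scale with exonic length), and genes are split into
five near-equal lists by the normalised score. Quintile 1 is the lowest
expressed; when n is not divisible by 5 the lowest quintiles take the extra
genes, so sizes never differ by more than one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GeneModel

logger = logging.getLogger(__name__)

N_QUINTILES = 5


@dataclass
class QuintileAssignment:
    """Gene -> quintile map (1 = lowest expression) plus the scores behind it."""

    assignment: pd.Series  # gene_id -> quintile (int 1..5)
    scores: pd.Series  # gene_id -> normalised expression score

    def genes_in(self, quintile: int) -> list[str]:
        return list(self.assignment.index[self.assignment == quintile])

    @property
    def sizes(self) -> dict[int, int]:
        return {q: int((self.assignment == q).sum()) for q in range(1, N_QUINTILES + 1)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.assignment.index, "score": self.scores.reindex(self.assignment.index).values,
             "quintile": self.assignment.values}
        )


def normalize_expression(expr: pd.DataFrame, genes: list[GeneModel]) -> pd.Series:
    """Exon-length-normalised mean expression: mean over samples / exonic_length.

    Genes absent from the annotation are dropped (count logged). Returns a
    Series indexed by gene_id.
    """
    lengths = {}
    for g in genes:
        if g.exonic_length == 0:
            raise ValidationError(f"gene {g.gene_id}: exonic_length is 0")
        lengths[g.gene_id] = g.exonic_length
    known = expr.index.intersection(lengths.keys())
    n_dropped = len(expr.index) - len(known)
    if n_dropped:
        logger.info("dropping %d expressed genes missing from the annotation", n_dropped)
    mean_expr = expr.loc[known].mean(axis=1)
    lens = pd.Series({g: lengths[g] for g in known}, dtype=float)
    return (mean_expr / lens).rename("score")


def assign_quintiles(scores: pd.Series) -> QuintileAssignment:
    """Partition genes into five quintile lists by ascending score.

    Ties are broken lexicographically by gene_id so the assignment is
    invariant to input order. Base size is floor(n/5); the n mod 5 lowest
    quintiles each receive one extra gene.
    """
    n = len(scores)
    if n < N_QUINTILES:
        raise ValidationError(f"need at least {N_QUINTILES} genes, got {n}")
    order = scores.reset_index()
    order.columns = ["gene_id", "score"]
    order = order.sort_values(["score", "gene_id"], kind="mergesort")

    base, extra = divmod(n, N_QUINTILES)
    sizes = [base + (1 if q < extra else 0) for q in range(N_QUINTILES)]
    labels = np.repeat(np.arange(1, N_QUINTILES + 1), sizes)
    assignment = pd.Series(labels, index=order["gene_id"].values, name="quintile")
    return QuintileAssignment(assignment=assignment, scores=scores.copy())
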