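"""Comprehensive stability ranking: geometric mean of per-method ranks.

Each of the four stability methods produces its own gene ranking. The
comprehensive ranking aggregates them RefFinder-style: for every gene take
the geometric mean of its four rank positions (average ranks for
within-method ties) and order genes by ascending geometric mean. Rank
positions — not raw stability scores — are aggregated, so methods with
different score scales contribute equally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .stability import (
    BestkeeperResult,
    DeltaCtResult,
    GenormResult,
    NormfinderResult,
)

__all__ = ["AggregateRanking", "aggregate_ranks", "comprehensive_ranking"]

METHOD_ORDER = ["genorm", "normfinder", "bestkeeper", "deltact"]


@dataclass
class AggregateRanking:
    table: pd.DataFrame
    """Columns: gene_id, rank_<method>..., geomean, final_rank; rows ordered
    by final rank (most stable first)."""

    @property
    def final_order(self) -> list[str]:
        return list(self.table["gene_id"])


def aggregate_ranks(ranks: Mapping[str, pd.Series]) -> AggregateRanking:
    """Aggregate named per-method rank Series over an identical gene set.

    Ties in the geometric mean are broken by the ΔCt rank when a method
    named ``deltact`` is present, then by gene id, so the final order is
    deterministic.
    """
    names = list(ranks)
    if len(names) < 2:
        raise ValueError("need at least two method rankings to aggregate")
    gene_sets = {n: set(ranks[n].index) for n in names}
    universe = gene_sets[names[0]]
    for n in names[1:]:
        if gene_sets[n] != universe:
            diff = sorted(gene_sets[n] ^ universe)
            raise ValueError(
                f"method {n!r} covers a different gene set; symmetric difference: {diff}"
            )

    genes = sorted(universe)
    mat = pd.DataFrame({f"rank_{n}": ranks[n].reindex(genes) for n in names})
    mat.insert(0, "gene_id", genes)
    geomean = np.exp(np.log(mat[[f"rank_{n}" for n in names]]).mean(axis=1))
    mat["geomean"] = geomean

    tiebreak = mat["rank_deltact"] if "rank_deltact" in mat.columns else mat["geomean"]
    order = np.lexsort((mat["gene_id"], tiebreak, mat["geomean"]))
    mat = mat.iloc[order].reset_index(drop=True)
    mat["final_rank"] = np.arange(1, len(mat) + 1)
    return AggregateRanking(mat)


def comprehensive_ranking(
    genorm: GenormResult,
    normfinder: NormfinderResult,
    bestkeeper: BestkeeperResult,
    deltact: DeltaCtResult,
) -> AggregateRanking:
    """Geometric-mean aggregation of the four stability methods' ranks."""
    return aggregate_ranks(
        {
            "genorm": genorm.ranks,
            "normfinder": normfinder.ranks,
            "bestkeeper": bestkeeper.ranks,
            "deltact": deltact.ranks,
        }
    )
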