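"""Cumulative rank aggregation across methods, and the redox-stability join.

Each chemical-proteomics method contributes an ordinal protein ranking.
Per protein the ranks are summed; the lowest cumulative sum marks the
top candidate target.  Because no single method quantifies the whole
proteome, proteins missing from a method receive a penalty rank of
``n_ranked + 1`` in that method (flagged as imputed) rather than being
dropped — dropping would discard exactly the multi-evidence candidates
the aggregation is meant to surface.

The concordance join pairs significantly (de)oxidised peptides with
thermally (de)stabilised proteins: oxidation with stabilisation, or
reduction with destabilisation, counts as concordant.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .ranking import MethodRanking, ordinal_rank

__all__ = [
    "impute_missing_ranks",
    "aggregate_ranks",
    "stability_oxidation_concordance",
]

logger = logging.getLogger(__name__)


def impute_missing_ranks(
    rankings: Sequence[MethodRanking],
    universe: Sequence[str],
    policy: str = "penalty",
) -> pd.DataFrame:
    """Complete every method ranking over a common protein universe.

    Returns a frame indexed by protein_id with a ``rank_<method>`` and an
    ``imputed_<method>`` column per method.  Under the default
    ``"penalty"`` policy an absent protein gets rank ``n_ranked + 1``;
    under ``"drop"`` it keeps a missing rank and is excluded from the
    aggregate sum entirely (only fully observed proteins survive).
    """
    if policy not in ("penalty", "drop"):
        raise ValueError(f"unknown imputation policy {policy!r}")
    universe = pd.Index(sorted(set(universe)))
    for ranking in rankings:
        missing = set(ranking.entries.index) - set(universe)
        if missing:
            raise ValueError(
                f"universe lacks {len(missing)} proteins ranked by {ranking.method!r}"
            )
    out = pd.DataFrame(index=universe)
    out.index.name = "protein_id"
    for ranking in rankings:
        ranks = ranking.entries.reindex(universe)
        imputed = ranks.isna()
        if policy == "penalty":
            ranks = ranks.fillna(ranking.n_ranked + 1)
        out[f"rank_{ranking.method}"] = ranks
        out[f"imputed_{ranking.method}"] = imputed
    return out


def aggregate_ranks(
    rankings: Sequence[MethodRanking],
    universe: Sequence[str] | None = None,
    policy: str = "penalty",
    normalize: bool = False,
) -> pd.DataFrame:
    """Cumulative sum of per-method ranks, lowest sum = top candidate.

    ``universe`` defaults to the union of all ranked proteins.  With
    ``normalize=True`` each rank is divided by its method's list length
    before summing, compensating unequal method coverage; the default
    sums raw ranks.  The result has one row per scored protein with the
    per-method (possibly imputed) ranks, ``cumulative_sum`` and a final
    ordinal ``final_rank`` ascending in the sum.
    """
    if not rankings:
        raise ValueError("at least one method ranking is required")
    names = [r.method for r in rankings]
    if len(set(names)) != len(names):
        raise ValueError("method names must be unique")
    if universe is None:
        universe = set()
        for r in rankings:
            universe |= set(r.entries.index)
    completed = impute_missing_ranks(rankings, universe, policy=policy)

    rank_cols = [f"rank_{m}" for m in names]
    if policy == "drop":
        completed = completed.dropna(subset=rank_cols)
    contributions = completed[rank_cols]
    if normalize:
        divisors = {f"rank_{r.method}": float(r.n_ranked) for r in rankings}
        contributions = contributions / pd.Series(divisors)
    result = completed.copy()
    result["cumulative_sum"] = contributions.sum(axis=1)
    result = result.reset_index()
    result["final_rank"] = ordinal_rank(
        result, by=["cumulative_sum"], ascending=[True], id_col="protein_id"
    )
    for col in rank_cols:
        result[col] = result[col].astype(int)
    return result.sort_values("final_rank", kind="stable").reset_index(drop=True)


def stability_oxidation_concordance(
    shifts: pd.DataFrame,
    peptides: pd.DataFrame,
    p_threshold: float = 0.05,
    tm_threshold: float = 1.0,
) -> pd.DataFrame:
    """Join significant redox peptides to thermally shifted proteins.

    Keeps peptides with ``p_value`` strictly below ``p_threshold`` whose
    protein has ``|delta_tm| >= tm_threshold``.  A pair is concordant
    when oxidation accompanies stabilisation (delta_ox > 0, delta_tm > 0)
    or reduction accompanies destabilisation (both negative).
    """
    if p_threshold <= 0 or tm_threshold <= 0:
        raise ValueError("thresholds must be positive")
    sig = peptides[peptides["p_value"] < p_threshold]
    shifted = shifts[shifts["delta_tm"].abs() >= tm_threshold]
    joined = sig.merge(
        shifted[["protein_id", "delta_tm"]], on="protein_id", how="inner"
    )
    if joined.empty:
        logger.warning("concordance join is empty at p<%g, |dTm|>=%g",
                       p_threshold, tm_threshold)
    joined = joined.copy()
    joined["concordant"] = np.sign(joined["delta_ox"]) == np.sign(joined["delta_tm"])
    return joined.sort_values(["protein_id", "peptide_id"], kind="stable").reset_index(drop=True)
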