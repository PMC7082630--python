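"""Ordinal ranking primitives shared by all scoring stages.

Every method in the pipeline ultimately reduces to "sort proteins by a
score and hand out ranks 1..N".  Ties are always broken by identifier
(ascending) so that a ranking is a pure function of its input table and
re-runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MethodRanking", "ordinal_rank"]


def ordinal_rank(
    df: pd.DataFrame,
    by: list[str],
    ascending: list[bool],
    id_col: str,
) -> pd.Series:
    """Assign ordinal ranks 1..N to the rows of ``df``.

    Rows are ordered by the ``by`` columns (with per-column direction in
    ``ascending``); remaining ties are broken by ``id_col`` ascending, so
    the result is deterministic.  Returns an int Series aligned with
    ``df.index``.
    """
    if df.empty:
        return pd.Series([], dtype=int, index=df.index, name="rank")
    order = df.sort_values(
        by=list(by) + [id_col],
        ascending=list(ascending) + [True],
        kind="stable",
    ).index
    ranks = pd.Series(np.arange(1, len(df) + 1), index=order, name="rank")
    return ranks.reindex(df.index).astype(int)


@dataclass(frozen=True)
class MethodRanking:
    """A single method's protein ranking: ``entries`` maps protein_id to a
    1-based ordinal rank forming a permutation of 1..n_ranked."""

    method: str
    entries: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        ranks = np.sort(np.asarray(self.entries.values, dtype=int))
        if len(ranks) and not np.array_equal(ranks, np.arange(1, len(ranks) + 1)):
            raise ValueError(
                f"ranking {self.method!r}: ranks are not a permutation of 1..{len(ranks)}"
            )
        if self.entries.index.has_duplicates:
            raise ValueError(f"ranking {self.method!r}: duplicate protein ids")

    @property
    def n_ranked(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        df = self.entries.rename("rank").rename_axis("protein_id").reset_index()
        df["method"] = self.method
        return df[["method", "protein_id", "rank"]]
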