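"""Expression-proteomics target ranking across a cell-line panel.

After ~48 h of drug exposure at LC50, the proteins whose abundance
changes most consistently across cell lines are enriched for targets
and mechanistic proteins.  For each cell line the regulation score is
the mean log2 fold change of treated vs control replicates; proteins
are ranked per cell line by the magnitude of that score, and the per
cell-line ranks are summed (ascending sums win) to form the final
ranking.  Only proteins quantified in every sample of the dataset
enter the ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ranking import MethodRanking, ordinal_rank

__all__ = [
    "compute_log2fc",
    "regulation_scores",
    "rank_within_cell_line",
    "fitexp_rank",
    "rank_expression",
]

CONTROL_LABEL = "control"
DRUG_LABEL = "drug"


def compute_log2fc(treated, control) -> float:
    """Mean log2 intensity of treated replicates minus that of controls.

    Groups are unpaired; all intensities must be strictly positive.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(treated) == 0 or len(control) == 0:
        raise ValueError("both groups need at least one intensity")
    if np.any(~np.isfinite(treated)) or np.any(~np.isfinite(control)):
        raise ValueError("intensities must be finite")
    if np.any(treated <= 0) or np.any(control <= 0):
        raise ValueError("intensities must be strictly positive")
    return float(np.mean(np.log2(treated)) - np.mean(np.log2(control)))


def regulation_scores(
    expression: pd.DataFrame,
    control_label: str = CONTROL_LABEL,
    drug_label: str = DRUG_LABEL,
    median_center: bool = False,
) -> pd.DataFrame:
    """Per-protein, per-cell-line mean log2 fold change (drug vs control).

    ``expression`` is tidy: protein_id, cell_line, treatment, replicate,
    intensity.  Treatments other than the control and drug labels
    (contrast compounds run alongside) are tolerated and ignored.  A
    protein must be quantified — present, finite, positive — in every
    control and drug sample of the whole dataset to receive scores;
    anything less is dropped, which is what makes downstream rank sums
    comparable across cell lines.

    ``median_center`` optionally subtracts the per-sample median log2
    intensity first (off by default; inputs are assumed load-normalised).
    """
    df = expression[expression["treatment"].isin([control_label, drug_label])].copy()
    if df.empty:
        raise ValueError("no rows with the control/drug treatment labels")
    df["intensity"] = pd.to_numeric(df["intensity"], errors="coerce")
    df.loc[df["intensity"] <= 0, "intensity"] = np.nan
    df["log2_intensity"] = np.log2(df["intensity"])

    if median_center:
        sample_cols = ["cell_line", "treatment", "replicate"]
        med = df.groupby(sample_cols)["log2_intensity"].transform("median")
        df["log2_intensity"] = df["log2_intensity"] - med

    # complete-case over the whole control+drug dataset
    n_samples = df[["cell_line", "treatment", "replicate"]].drop_duplicates().shape[0]
    counts = df.dropna(subset=["log2_intensity"]).groupby("protein_id").size()
    complete = counts[counts == n_samples].index
    df = df[df["protein_id"].isin(complete)]

    grouped = df.groupby(["protein_id", "cell_line", "treatment"])["log2_intensity"]
    means = grouped.mean().unstack("treatment")
    ns = grouped.size().unstack("treatment")
    scores = (
        (means[drug_label] - means[control_label])
        .rename("mean_log2fc")
        .reset_index()
    )
    scores["n_replicates"] = ns.min(axis=1).values.astype(int)
    return scores


def rank_within_cell_line(scores: pd.DataFrame, signed: bool = False) -> pd.Series:
    """Rank one cell line's proteins by regulation, strongest first.

    Default ranks by ``|mean_log2fc|`` descending; ``signed=True`` ranks
    by the signed value descending (most up-regulated first).  Returns a
    Series indexed by protein_id.
    """
    if scores["protein_id"].duplicated().any():
        raise ValueError("one score per protein required")
    df = scores.copy()
    df["_key"] = df["mean_log2fc"] if signed else df["mean_log2fc"].abs()
    ranks = ordinal_rank(df, by=["_key"], ascending=[False], id_col="protein_id")
    return pd.Series(ranks.values, index=df["protein_id"].values, name="rank")


def fitexp_rank(
    per_cell_line_ranks: dict[str, pd.Series],
    method: str = "fitexp",
) -> MethodRanking:
    """Sum per-cell-line ranks and re-rank by ascending sum.

    Only proteins ranked in every cell line are eligible; an empty
    intersection is an error (it means no protein was quantified across
    the whole panel).
    """
    if not per_cell_line_ranks:
        raise ValueError("no cell-line rankings supplied")
    common = None
    for ranks in per_cell_line_ranks.values():
        ids = set(ranks.index)
        common = ids if common is None else common & ids
    if not common:
        raise ValueError(
            "no protein is ranked in every cell line: "
            f"lines = {sorted(per_cell_line_ranks)}"
        )
    ids = sorted(common)
    sums = sum(ranks.loc[ids] for ranks in per_cell_line_ranks.values())
    df = pd.DataFrame({"protein_id": ids, "rank_sum": np.asarray(sums, dtype=int)})
    final = ordinal_rank(df, by=["rank_sum"], ascending=[True], id_col="protein_id")
    return MethodRanking(method, pd.Series(final.values, index=df["protein_id"].values))


def rank_expression(
    expression: pd.DataFrame,
    signed: bool = False,
    method: str = "fitexp",
    **score_kwargs,
) -> tuple[pd.DataFrame, MethodRanking]:
    """Convenience wrapper: scores, per-cell-line ranks and final ranking."""
    scores = regulation_scores(expression, **score_kwargs)
    per_cell = {
        line: rank_within_cell_line(sub, signed=signed)
        for line, sub in scores.groupby("cell_line")
    }
    return scores, fitexp_rank(per_cell, method=method)
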