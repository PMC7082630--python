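"""Cysteine redox proteomics: oxidation ratios, differential tests, ranking.

Sequential thiol labelling puts a first isobaric tag on free thiols and,
after reduction, a second tag on the previously oxidised thiols of the
same cysteine pool.  The fraction of a peptide's signal carried by the
second label is therefore its oxidation level:

    oxidation_ratio = label2 / (label1 + label2)

Per peptide, the drug-minus-vehicle difference of mean oxidation ratios
(delta_ox) and a two-tailed equal-variance Student t-test p-value are
computed on complete cases only.  Peptides are ranked twice — by
delta_ox (most oxidised first) and by p-value (smallest first) — and
the two ranks are summed; ascending sums give the final peptide rank.
Proteins inherit the rank of their best peptide.

Benjamini-Hochberg q-values are reported as a courtesy column; they play
no role in the ranking, which uses raw p-values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ranking import MethodRanking, ordinal_rank

__all__ = [
    "oxidation_ratio",
    "add_oxidation_ratios",
    "complete_case_filter",
    "student_t_two_tailed",
    "peptide_differential_oxidation",
    "redox_dual_rank",
    "best_peptide_per_protein",
]

logger = logging.getLogger(__name__)

VEHICLE_LABEL = "vehicle"
DRUG_LABEL = "drug"


def oxidation_ratio(label1, label2):
    """Second-label share of the summed label abundances, in [0, 1].

    ``label1`` counts previously free (reduced) thiols, ``label2`` the
    previously oxidised ones.  Inputs must be non-negative; a pair that
    sums to zero has no defined ratio and comes back NaN (missing).
    Scaling both labels of a sample by any positive constant leaves the
    ratio unchanged.
    """
    l1 = np.asarray(label1, dtype=float)
    l2 = np.asarray(label2, dtype=float)
    if np.any(l1[np.isfinite(l1)] < 0) or np.any(l2[np.isfinite(l2)] < 0):
        raise ValueError("label abundances must be non-negative")
    total = l1 + l2
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, l2 / total, np.nan)
    if ratio.ndim == 0:
        return float(ratio)
    return ratio


def add_oxidation_ratios(redox: pd.DataFrame) -> pd.DataFrame:
    """Attach an ``oxidation_ratio`` column to a tidy label-pair table."""
    out = redox.copy()
    out["oxidation_ratio"] = oxidation_ratio(
        out["label1_abundance"].to_numpy(), out["label2_abundance"].to_numpy()
    )
    return out


def complete_case_filter(redox: pd.DataFrame) -> pd.DataFrame:
    """Keep peptides with a defined oxidation ratio in every sample.

    The sample universe is every (condition, replicate) pair present in
    the table; a peptide missing any one of them (or with an undefined
    ratio there) is dropped entirely.
    """
    if "oxidation_ratio" not in redox.columns:
        redox = add_oxidation_ratios(redox)
    samples = redox[["condition", "replicate"]].drop_duplicates()
    n_samples = len(samples)
    observed = redox.dropna(subset=["oxidation_ratio"])
    counts = (
        observed.drop_duplicates(["peptide_id", "condition", "replicate"])
        .groupby("peptide_id")
        .size()
    )
    keep = counts[counts == n_samples].index
    return redox[redox["peptide_id"].isin(keep)].reset_index(drop=True)


def student_t_two_tailed(group1, group2) -> float:
    """Two-tailed p-value of the equal-variance two-sample Student t-test.

    Degenerate inputs are resolved by the limit of the statistic: zero
    pooled variance with equal means gives p = 1 (no evidence), zero
    pooled variance with unequal means gives p = 0 (infinite t).
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled_var = np.var(g1, ddof=1) + np.var(g2, ddof=1)
    if pooled_var == 0.0:
        if np.mean(g1) == np.mean(g2):
            return 1.0
        logger.warning("zero variance with unequal means: p-value degenerates to 0")
        return 0.0
    import warnings

    with warnings.catch_warnings():
        # near-identical groups trip scipy's precision-loss warning; the
        # degenerate cases are already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(g1, g2, equal_var=True).pvalue)


def peptide_differential_oxidation(
    redox: pd.DataFrame,
    vehicle_label: str = VEHICLE_LABEL,
    drug_label: str = DRUG_LABEL,
) -> pd.DataFrame:
    """Collapse complete-case samples to one row per peptide.

    Returns peptide_id, protein_id, condition means, delta_ox (drug mean
    minus vehicle mean), the Student-t p-value and a Benjamini-Hochberg
    q-value column.
    """
    if "oxidation_ratio" not in redox.columns:
        redox = add_oxidation_ratios(redox)
    rows = []
    for (peptide_id, protein_id), sub in redox.groupby(["peptide_id", "protein_id"], sort=True):
        veh = sub.loc[sub["condition"] == vehicle_label, "oxidation_ratio"].to_numpy()
        drg = sub.loc[sub["condition"] == drug_label, "oxidation_ratio"].to_numpy()
        mean_veh, mean_drg = float(np.mean(veh)), float(np.mean(drg))
        rows.append(
            {
                "peptide_id": peptide_id,
                "protein_id": protein_id,
                "mean_ratio_vehicle": mean_veh,
                "mean_ratio_drug": mean_drg,
                "delta_ox": mean_drg - mean_veh,
                "p_value": student_t_two_tailed(drg, veh),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def redox_dual_rank(peptides: pd.DataFrame, absolute: bool = False) -> pd.DataFrame:
    """Rank peptides by effect and by significance, then by the rank sum.

    rank_delta orders by delta_ox descending (most drug-oxidised first;
    ``absolute=True`` switches to |delta_ox| for symmetric discovery),
    rank_p by p-value ascending.  final_rank orders the sums ascending.
    """
    df = peptides.copy()
    key = df["delta_ox"].abs() if absolute else df["delta_ox"]
    df["_key"] = key
    df["rank_delta"] = ordinal_rank(df, by=["_key"], ascending=[False], id_col="peptide_id")
    df["rank_p"] = ordinal_rank(df, by=["p_value"], ascending=[True], id_col="peptide_id")
    df["rank_sum"] = df["rank_delta"] + df["rank_p"]
    df["final_rank"] = ordinal_rank(df, by=["rank_sum"], ascending=[True], id_col="peptide_id")
    return df.drop(columns="_key")


def best_peptide_per_protein(
    ranked_peptides: pd.DataFrame, method: str = "redox"
) -> MethodRanking:
    """Protein-level ranking from each protein's best-ranked peptide.

    Proteins are ordered by their minimum peptide final_rank and then
    re-ranked ordinally so the result is again a permutation of 1..N.
    """
    best = (
        ranked_peptides.groupby("protein_id")["final_rank"].min().rename("best").reset_index()
    )
    final = ordinal_rank(best, by=["best"], ascending=[True], id_col="protein_id")
    return MethodRanking(method, pd.Series(final.values, index=best["protein_id"].values))
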