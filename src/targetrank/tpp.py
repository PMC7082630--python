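"""Thermal proteome profiling: melting-curve fits, Tm shifts and ranking.

A TPP experiment heats aliquots of drug- and vehicle-treated material
across a temperature gradient and quantifies the protein left in the
soluble fraction at each point.  Each protein/condition/replicate trace
is normalised to its lowest-temperature channel and fitted with the
three-parameter sigmoid

    f(T) = (1 - p) / (1 + exp(b - a/T)) + p

whose melting point Tm (the temperature where the fitted soluble
fraction crosses 0.5) has the closed form

    Tm = a / (b - ln(0.5 / (0.5 - p))).

The drug-minus-vehicle difference in replicate-mean Tm is the thermal
shift; proteins whose replicate Tm estimates disagree by more than a
concordance threshold (default 1 degC) or that have missing data are
excluded, and the survivors are ranked by absolute mean shift.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .ranking import MethodRanking, ordinal_rank

__all__ = [
    "DEFAULT_TEMPERATURES",
    "TemperatureGrid",
    "SolubleProfile",
    "MeltingFit",
    "UnquantifiableProfileError",
    "melting_model",
    "tm_closed_form",
    "normalize_profile",
    "fit_melting_curve",
    "fit_melting_curves",
    "compute_tm_shifts",
    "filter_concordant",
    "rank_by_tm_shift",
]

logger = logging.getLogger(__name__)

#: Standard 10-point gradient of the assay, degC.
DEFAULT_TEMPERATURES: tuple[float, ...] = (37, 41, 44, 47, 50, 53, 56, 59, 63, 67)

_MAX_PLATEAU = 0.5 - 1e-6


class UnquantifiableProfileError(ValueError):
    """Raised when a trace cannot be normalised (missing/zero reference)."""


@dataclass(frozen=True)
class TemperatureGrid:
    """Strictly increasing temperature points of the gradient, degC."""

    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if len(t) < 4:
            raise ValueError("temperature grid needs at least 4 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        if np.any(t <= 0):
            raise ValueError("temperatures must be positive (degC)")

    def __len__(self) -> int:
        return len(self.temperatures)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.temperatures, dtype=float)


@dataclass(frozen=True)
class SolubleProfile:
    """Relative soluble fraction of one protein/condition/replicate."""

    protein_id: str
    condition: str
    replicate: int
    fractions: np.ndarray
    grid: TemperatureGrid = TemperatureGrid()

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if len(f) != len(self.grid):
            raise ValueError("profile length does not match grid")
        if np.any(f[~np.isnan(f)] < 0):
            raise ValueError("soluble fractions must be non-negative")
        object.__setattr__(self, "fractions", f)


@dataclass(frozen=True)
class MeltingFit:
    """Sigmoid parameters and melting point for one fitted trace."""

    a: float
    b: float
    plateau: float
    tm: float
    r_squared: float
    converged: bool


def melting_model(T, a: float, b: float, p: float):
    """Soluble fraction at temperature ``T`` (degC) for parameters (a, b, p)."""
    T = np.asarray(T, dtype=float)
    z = np.clip(b - a / T, -700.0, 700.0)  # exp-safe; tails are flat anyway
    return (1.0 - p) / (1.0 + np.exp(z)) + p


def tm_closed_form(a: float, b: float, p: float) -> float:
    """Temperature at which the sigmoid crosses a soluble fraction of 0.5.

    Requires ``p < 0.5`` (otherwise the curve never reaches 0.5) and
    ``b > ln(0.5/(0.5 - p))`` (otherwise the crossing sits at a
    non-physical, non-positive temperature).
    """
    if p >= 0.5:
        raise ValueError("plateau >= 0.5: curve never crosses 0.5")
    denom = b - math.log(0.5 / (0.5 - p))
    if denom <= 0:
        raise ValueError("b too small: no positive-temperature 0.5 crossing")
    return a / denom


def normalize_profile(
    raw_abundances,
    grid: TemperatureGrid,
    protein_id: str = "",
    condition: str = "",
    replicate: int = 0,
) -> SolubleProfile:
    """Divide a raw abundance trace by its lowest-temperature channel.

    The first element of the result is exactly 1; missing values stay
    missing.  A missing or non-positive reference channel makes the whole
    trace unquantifiable.
    """
    raw = np.asarray(raw_abundances, dtype=float)
    if len(raw) != len(grid):
        raise ValueError("abundance vector length does not match grid")
    ref = raw[0]
    if not np.isfinite(ref) or ref <= 0:
        raise UnquantifiableProfileError(
            f"protein {protein_id!r} ({condition}, rep {replicate}): "
            "reference channel missing or non-positive"
        )
    return SolubleProfile(protein_id, condition, replicate, raw / ref, grid)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def _initial_guess(T: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # plateau from the hot tail, Tm from the first interpolated 0.5 crossing
    p0 = float(np.clip(min(y[-1], y.min()), 0.0, 0.45))
    below = np.where(y < 0.5)[0]
    if len(below) and below[0] > 0:
        i = below[0]
        frac = (y[i - 1] - 0.5) / (y[i - 1] - y[i])
        tm0 = T[i - 1] + frac * (T[i] - T[i - 1])
    elif len(below):
        tm0 = T[0]
    else:
        tm0 = T[-1]
    b0 = 10.0
    a0 = tm0 * (b0 - math.log(0.5 / (0.5 - min(p0, 0.45))))
    return a0, b0, p0


def fit_melting_curve(
    profile: SolubleProfile,
    max_restarts: int = 50,
    _restart_seed: int = 1905,
) -> MeltingFit:
    """Least-squares fit of the melting sigmoid to one soluble-fraction trace.

    Bounds: a > 0, b > 0, plateau in [0, 0.5).  The first attempt starts
    from a data-driven guess; on failure up to ``max_restarts`` jittered
    restarts (deterministically seeded) are tried before the fit is
    declared unconverged.  A fit whose curve never crosses 0.5 (flat
    trace, plateau at bound) is reported with ``converged=False``.
    """
    T = profile.grid.array
    y = profile.fractions
    ok = np.isfinite(y)
    if ok.sum() < 4:
        return MeltingFit(np.nan, np.nan, np.nan, np.nan, np.nan, False)
    T, y = T[ok], y[ok]

    a0, b0, p0 = _initial_guess(T, y)
    rng = np.random.default_rng(_restart_seed)
    bounds = ([1e-6, 1e-6, 0.0], [np.inf, np.inf, _MAX_PLATEAU])

    popt = None
    start = (a0, b0, p0)
    for attempt in range(max_restarts + 1):
        try:
            popt, _ = curve_fit(
                melting_model, T, y, p0=np.clip(start, bounds[0], bounds[1]),
                bounds=bounds, maxfev=500,
            )
            break
        except (RuntimeError, ValueError):
            start = (
                a0 * rng.uniform(0.5, 2.0),
                b0 * rng.uniform(0.5, 2.0),
                rng.uniform(0.0, 0.45),
            )

    if popt is None:
        return MeltingFit(np.nan, np.nan, np.nan, np.nan, np.nan, False)

    a, b, p = popt
    r2 = _r_squared(y, melting_model(T, a, b, p))
    try:
        tm = tm_closed_form(a, b, p)
    except ValueError:
        return MeltingFit(a, b, p, np.nan, r2, False)
    if not (T[0] - 20.0 <= tm <= T[-1] + 20.0):
        # crossing far outside the assay span: extrapolation, not a measurement
        return MeltingFit(a, b, p, tm, r2, False)
    return MeltingFit(a, b, p, tm, r2, True)


def fit_melting_curves(
    tpp_table: pd.DataFrame,
    grid: TemperatureGrid,
) -> pd.DataFrame:
    """Fit every (protein, condition, replicate) trace of a wide TPP table.

    ``tpp_table`` holds columns protein_id, condition, replicate and one
    column per grid temperature.  Returns a long table of fits with
    columns a, b, plateau, tm, r_squared, converged; unquantifiable
    traces appear with ``converged=False``.
    """
    temp_cols = [c for c in tpp_table.columns if c not in ("protein_id", "condition", "replicate")]
    if len(temp_cols) != len(grid):
        raise ValueError("table temperature columns do not match grid")
    rows = []
    for rec in tpp_table.itertuples(index=False):
        raw = np.asarray(rec[3:], dtype=float)
        key = dict(protein_id=rec[0], condition=rec[1], replicate=rec[2])
        try:
            profile = normalize_profile(raw, grid, **key)
        except UnquantifiableProfileError:
            fit = MeltingFit(np.nan, np.nan, np.nan, np.nan, np.nan, False)
        else:
            fit = fit_melting_curve(profile)
        rows.append(
            {**key, "a": fit.a, "b": fit.b, "plateau": fit.plateau,
             "tm": fit.tm, "r_squared": fit.r_squared, "converged": fit.converged}
        )
    return pd.DataFrame(rows)


def compute_tm_shifts(
    fits: pd.DataFrame,
    vehicle_label: str = "vehicle",
    drug_label: str = "drug",
    mode: str = "per_condition",
) -> pd.DataFrame:
    """Per-protein thermal shift and replicate concordance.

    delta_tm is mean(drug Tm) - mean(vehicle Tm) over replicates.  The
    discordance statistic depends on ``mode``:

    - ``"per_condition"`` (default): the largest within-condition spread
      of replicate Tm values, taken over both conditions;
    - ``"delta"``: the largest spread of per-replicate Tm shifts
      (replicates paired by index).

    Proteins with any missing or unconverged replicate trace are flagged
    via ``has_missing``; their shift is reported where computable but
    they can never pass the concordance filter.
    """
    if mode not in ("per_condition", "delta"):
        raise ValueError(f"unknown concordance mode {mode!r}")
    conditions = (vehicle_label, drug_label)
    replicates = sorted(fits["replicate"].unique())
    good = fits[fits["converged"] & np.isfinite(fits["tm"])]
    tm = good.pivot_table(
        index="protein_id", columns=["condition", "replicate"], values="tm", aggfunc="first"
    )

    rows = []
    for protein_id in sorted(fits["protein_id"].unique()):
        per_cond: dict[str, np.ndarray] = {}
        for cond in conditions:
            vals = []
            for rep in replicates:
                try:
                    v = tm.loc[protein_id, (cond, rep)]
                except KeyError:
                    v = np.nan
                vals.append(v)
            per_cond[cond] = np.asarray(vals, dtype=float)
        veh, drg = per_cond[vehicle_label], per_cond[drug_label]
        has_missing = bool(np.isnan(veh).any() or np.isnan(drg).any())
        mean_veh = float(np.mean(veh)) if not np.isnan(veh).any() else np.nan
        mean_drg = float(np.mean(drg)) if not np.isnan(drg).any() else np.nan
        if mode == "per_condition":
            spreads = [np.ptp(v[~np.isnan(v)]) if (~np.isnan(v)).sum() >= 2 else np.nan
                       for v in (veh, drg)]
            discordance = float(np.nanmax(spreads)) if not all(np.isnan(spreads)) else np.nan
        else:
            deltas = drg - veh
            deltas = deltas[~np.isnan(deltas)]
            discordance = float(np.ptp(deltas)) if len(deltas) >= 2 else np.nan
        rows.append(
            {
                "protein_id": protein_id,
                "mean_tm_vehicle": mean_veh,
                "mean_tm_drug": mean_drg,
                "delta_tm": mean_drg - mean_veh,
                "discordance": discordance,
                "has_missing": has_missing,
            }
        )
    return pd.DataFrame(rows)


def filter_concordant(shifts: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Keep proteins with complete replicate Tm sets agreeing within
    ``threshold`` degC (inclusive).  Adds/updates ``passes_filter``."""
    if threshold <= 0:
        raise ValueError("concordance threshold must be positive")
    shifts = shifts.copy()
    shifts["passes_filter"] = (
        ~shifts["has_missing"]
        & np.isfinite(shifts["discordance"])
        & (shifts["discordance"] <= threshold)
    )
    out = shifts[shifts["passes_filter"]].reset_index(drop=True)
    if out.empty:
        logger.warning("concordance filter removed every protein")
    return out


def rank_by_tm_shift(shifts: pd.DataFrame, method: str = "tpp") -> MethodRanking:
    """Rank proteins by absolute mean Tm shift, largest first."""
    df = shifts.copy()
    df["_abs"] = df["delta_tm"].abs()
    ranks = ordinal_rank(df, by=["_abs"], ascending=[False], id_col="protein_id")
    return MethodRanking(method, pd.Series(ranks.values, index=df["protein_id"].values))
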