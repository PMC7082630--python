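"""Synthetic datasets with planted drug targets for all three modalities.

The generator produces the three tables the pipeline consumes — a TPP
soluble-abundance table over a temperature gradient, an expression table
across a cell-line panel, and a redox label-pair table — together with a
ground-truth table per modality, so that every downstream stage can be
exercised and scored without external data.

A configurable subset of proteins are "targets": in TPP their drug-
condition melting temperature is shifted, in expression proteomics they
carry a consistent same-sign log2 fold change in every cell line, and in
redox proteomics one cysteine peptide per target has its oxidation
fraction shifted under drug.  Everything else is background: zero true
effect, noise only.

Noise model, in brief: melting curves get per-replicate Tm jitter and
multiplicative lognormal abundance noise per channel; expression
intensities get lognormal noise and small zero-centred background
regulation; oxidation fractions are drawn from a Beta distribution
around the true per-sample fraction (concentration ``ox_noise_kappa``;
zero switches the noise off), while abundance noise scales both labels
of a sample jointly and therefore never distorts a ratio.  Missingness
is completely at random: cell-wise for TPP and expression, label-pair-
wise for redox (one spectrum quantifies both labels of a peptide).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tpp import DEFAULT_TEMPERATURES, TemperatureGrid, melting_model

__all__ = [
    "SimulationConfig",
    "simulate_tpp_dataset",
    "simulate_fitexp_dataset",
    "simulate_redox_dataset",
]

logger = logging.getLogger(__name__)

_FRAC_EPS = 1e-9


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and effect/noise sizes for the synthetic experiments.

    Replicate structure defaults to the usual design of this kind of
    study: duplicate TPP runs and triplicate expression and redox runs.
    Effect sizes are what the drug does to a target protein: a +2 degC
    thermal shift, a one-unit |log2FC| in every cell line, and a +0.2
    shift of the oxidised fraction of one cysteine peptide.
    """

    n_proteins: int = 1000
    n_targets: int = 5
    seed: int = 0

    temperature_grid: TemperatureGrid = field(default_factory=TemperatureGrid)
    tpp_conditions: tuple[str, str] = ("vehicle", "drug")
    tpp_replicates: int = 2
    fitexp_cell_lines: tuple[str, ...] = ("HCT116", "A375", "RKO")
    fitexp_replicates: int = 3
    redox_conditions: tuple[str, str] = ("vehicle", "drug")
    redox_replicates: int = 3

    #: mean of the (1 + Poisson) peptides-per-protein count
    peptides_per_protein: float = 2.0

    # planted effect sizes
    target_delta_tm: float = 2.0      # degC, drug minus vehicle
    target_log2fc: float = 1.0        # |log2FC| in every cell line (random common sign)
    target_delta_ox: float = 0.2      # shift of the oxidised fraction, one peptide

    # noise.  Two abundance-noise scales: within a TMT plex (TPP soluble
    # fractions; technical reporter-channel noise) precision is far higher
    # than between biological replicate cultures (expression intensities,
    # redox totals), so the two get separate lognormal sigmas.
    tm_jitter_sd: float = 0.1         # degC, per replicate curve
    tpp_channel_sd: float = 0.015     # lognormal sigma per TPP channel (within-plex)
    abundance_sd: float = 0.1         # lognormal sigma, biological replicates
    ox_noise_kappa: float = 100.0     # Beta concentration; 0 = noise-free fractions
    background_log2fc_sd: float = 0.1 # background regulation per protein/cell line

    missingness_rate: float = 0.0     # per cell (TPP/expression) or per pair (redox)

    def __post_init__(self) -> None:
        if not (0 <= self.n_targets <= self.n_proteins):
            raise ValueError("need 0 <= n_targets <= n_proteins")
        if not (0.0 <= self.missingness_rate <= 1.0):
            raise ValueError("missingness_rate must be in [0, 1]")
        for name in ("target_delta_tm", "target_log2fc", "target_delta_ox"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("tm_jitter_sd", "tpp_channel_sd", "abundance_sd",
                     "ox_noise_kappa", "background_log2fc_sd",
                     "peptides_per_protein"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tpp_replicates < 1 or self.fitexp_replicates < 1 or self.redox_replicates < 1:
            raise ValueError("replicate counts must be >= 1")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _target_mask(cfg: SimulationConfig) -> np.ndarray:
    # drawn from its own stream so all three generators agree on who the
    # targets are for a given config/seed
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 99]))
    mask = np.zeros(cfg.n_proteins, dtype=bool)
    mask[rng.choice(cfg.n_proteins, size=cfg.n_targets, replace=False)] = True
    return mask


def _lognoise(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    if sd == 0.0:
        return np.ones(size)
    return np.exp(rng.normal(0.0, sd, size))


def simulate_tpp_dataset(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Soluble-abundance table over the temperature gradient, plus truth.

    Per protein a baseline melting curve is drawn (Tm ~ U(42, 60) degC,
    plateau ~ U(0, 0.2), steepness b ~ U(9, 13), so curves descend from
    near 1 to their plateau within the default gradient).  Each
    condition/replicate trace jitters the Tm, drug traces of targets add
    the planted shift, and abundances are baseline x curve x lognormal
    noise.  Missing cells are NaN.

    Returns ``(table, truth)``: the wide table with columns protein_id,
    condition, replicate and one column per temperature; the truth table
    with protein_id, is_target, true_delta_tm.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.temperature_grid
    T = grid.array
    ids = _protein_ids(cfg.n_proteins)
    is_target = _target_mask(cfg)

    base_tm = rng.uniform(42.0, 60.0, cfg.n_proteins)
    plateau = rng.uniform(0.0, 0.2, cfg.n_proteins)
    steep_b = rng.uniform(9.0, 13.0, cfg.n_proteins)
    baseline = rng.lognormal(np.log(1e6), 0.5, cfg.n_proteins)
    true_dtm = np.where(is_target, cfg.target_delta_tm, 0.0)

    rows = []
    for i, pid in enumerate(ids):
        for cond in cfg.tpp_conditions:
            shift = true_dtm[i] if cond == cfg.tpp_conditions[1] else 0.0
            for rep in range(1, cfg.tpp_replicates + 1):
                tm = base_tm[i] + shift + (
                    rng.normal(0.0, cfg.tm_jitter_sd) if cfg.tm_jitter_sd else 0.0
                )
                a = tm * (steep_b[i] - np.log(0.5 / (0.5 - plateau[i])))
                curve = melting_model(T, a, steep_b[i], plateau[i])
                abund = baseline[i] * curve * _lognoise(rng, cfg.tpp_channel_sd, len(T))
                if cfg.missingness_rate:
                    abund = np.where(
                        rng.random(len(T)) < cfg.missingness_rate, np.nan, abund
                    )
                rows.append([pid, cond, rep, *abund])

    columns = ["protein_id", "condition", "replicate"] + [f"{t:g}" for t in T]
    table = pd.DataFrame(rows, columns=columns)
    truth = pd.DataFrame(
        {"protein_id": ids, "is_target": is_target, "true_delta_tm": true_dtm}
    )
    return table, truth


def simulate_fitexp_dataset(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression table across the cell-line panel, plus truth.

    Targets carry a common-sign log2FC of magnitude ``target_log2fc`` in
    every cell line; background proteins draw independent zero-centred
    effects of SD ``background_log2fc_sd`` per cell line.  Intensities
    are lognormal around a per-protein/cell-line baseline.

    Returns ``(table, truth)``: tidy columns protein_id, cell_line,
    treatment (control|drug), replicate, intensity; truth is tidy with
    protein_id, cell_line, is_target, true_log2fc.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    ids = _protein_ids(cfg.n_proteins)
    is_target = _target_mask(cfg)
    sign = np.where(rng.random(cfg.n_proteins) < 0.5, 1.0, -1.0)

    rows = []
    truth_rows = []
    for line in cfg.fitexp_cell_lines:
        base_log2 = rng.normal(20.0, 2.0, cfg.n_proteins)
        bg = (
            rng.normal(0.0, cfg.background_log2fc_sd, cfg.n_proteins)
            if cfg.background_log2fc_sd
            else np.zeros(cfg.n_proteins)
        )
        true_fc = np.where(is_target, sign * cfg.target_log2fc, bg)
        true_fc = np.where(is_target & (cfg.target_log2fc == 0.0), 0.0, true_fc)
        for treatment, effect in (("control", 0.0), ("drug", 1.0)):
            for rep in range(1, cfg.fitexp_replicates + 1):
                log2_int = base_log2 + effect * true_fc
                intensity = np.exp2(log2_int) * _lognoise(
                    rng, cfg.abundance_sd, cfg.n_proteins
                )
                if cfg.missingness_rate:
                    intensity = np.where(
                        rng.random(cfg.n_proteins) < cfg.missingness_rate,
                        np.nan,
                        intensity,
                    )
                rows.append(
                    pd.DataFrame(
                        {
                            "protein_id": ids,
                            "cell_line": line,
                            "treatment": treatment,
                            "replicate": rep,
                            "intensity": intensity,
                        }
                    )
                )
        truth_rows.append(
            pd.DataFrame(
                {
                    "protein_id": ids,
                    "cell_line": line,
                    "is_target": is_target,
                    "true_log2fc": true_fc,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table = table.dropna(subset=["intensity"]).reset_index(drop=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    return table, truth


def simulate_redox_dataset(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label-pair peptide table for the sequential-labelling assay, plus truth.

    Each protein contributes 1 + Poisson(peptides_per_protein - 1)
    cysteine peptides with a baseline oxidised fraction ~ U(0.05, 0.5).
    Per sample the realised fraction is Beta-distributed around the true
    fraction (drug samples of a target's first peptide get the planted
    shift, clipped to [0, 1] with a warning); the peptide's total
    abundance splits into label2 = total x fraction (previously
    oxidised) and label1 = the remainder.  Missingness removes both
    labels of a sample jointly.

    Returns ``(table, truth)``: tidy columns peptide_id, protein_id,
    condition, replicate, label1_abundance, label2_abundance; truth with
    peptide_id, protein_id, is_target, true_delta_ox.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    ids = _protein_ids(cfg.n_proteins)
    is_target = _target_mask(cfg)

    mean_extra = max(cfg.peptides_per_protein - 1.0, 0.0)
    n_peptides = 1 + rng.poisson(mean_extra, cfg.n_proteins)

    samples = [
        (cond, rep)
        for cond in cfg.redox_conditions
        for rep in range(1, cfg.redox_replicates + 1)
    ]
    drug_label = cfg.redox_conditions[1]

    clipped = 0
    rows = []
    truth_rows = []
    for i, pid in enumerate(ids):
        for j in range(1, n_peptides[i] + 1):
            pep = f"{pid}_pep{j}"
            base_frac = rng.uniform(0.05, 0.5)
            dox = cfg.target_delta_ox if (is_target[i] and j == 1) else 0.0
            baseline = rng.lognormal(np.log(1e5), 0.5)
            truth_rows.append((pep, pid, bool(is_target[i] and j == 1), dox))
            for cond, rep in samples:
                frac = base_frac + (dox if cond == drug_label else 0.0)
                if frac < 0.0 or frac > 1.0:
                    clipped += 1
                    frac = float(np.clip(frac, 0.0, 1.0))
                if cfg.ox_noise_kappa > 0:
                    mu = float(np.clip(frac, _FRAC_EPS, 1.0 - _FRAC_EPS))
                    frac = rng.beta(
                        mu * cfg.ox_noise_kappa, (1.0 - mu) * cfg.ox_noise_kappa
                    )
                total = baseline * float(_lognoise(rng, cfg.abundance_sd, ()))
                if cfg.missingness_rate and rng.random() < cfg.missingness_rate:
                    label1 = label2 = np.nan
                else:
                    label2 = total * frac
                    label1 = total * (1.0 - frac)
                rows.append((pep, pid, cond, rep, label1, label2))
    if clipped:
        logger.warning(
            "oxidation fraction clipped to [0, 1] in %d peptide-samples", clipped
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "peptide_id", "protein_id", "condition", "replicate",
            "label1_abundance", "label2_abundance",
        ],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["peptide_id", "protein_id", "is_target", "true_delta_ox"]
    )
    return table, truth
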