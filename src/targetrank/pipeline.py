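"""End-to-end pipeline driver: simulate (or load), score, rank, aggregate.

``run_pipeline`` executes the full analysis — TPP melting-curve fits and
Tm-shift ranking, expression-panel ranking, redox oxidation ranking,
cumulative rank aggregation and the redox-stability concordance join —
and writes every intermediate and final table as TSV plus a JSON run
manifest (configuration echo, seed, library versions, row counts).  The
run is a pure function of the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__, aggregate, fitexp, io, redox, tpp
from .simulate import (
    SimulationConfig,
    simulate_fitexp_dataset,
    simulate_redox_dataset,
    simulate_tpp_dataset,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Everything a run needs: inputs (paths or simulation), thresholds,
    ranking policy and output location."""

    out_dir: str = "targetrank_out"
    simulate: bool = True
    sim: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    tpp_path: str | None = None
    expression_path: str | None = None
    redox_path: str | None = None

    replicate_tm_threshold: float = 1.0   # degC, replicate concordance filter
    concordance_mode: str = "per_condition"  # or "delta"
    concordance_p_threshold: float = 0.05
    concordance_tm_threshold: float = 1.0  # degC
    fitexp_signed: bool = False
    redox_absolute: bool = False
    imputation_policy: str = "penalty"    # or "drop"
    normalize_rank_sums: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("replicate_tm_threshold", "concordance_p_threshold",
                     "concordance_tm_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if isinstance(self.sim, dict):
            raw = dict(self.sim)
            grid = raw.get("temperature_grid")
            if isinstance(grid, (list, tuple)):
                from .tpp import TemperatureGrid

                raw["temperature_grid"] = TemperatureGrid(tuple(grid))
            for key in ("tpp_conditions", "fitexp_cell_lines", "redox_conditions"):
                if key in raw and isinstance(raw[key], list):
                    raw[key] = tuple(raw[key])
            self.sim = SimulationConfig(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        raw.update(overrides)
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sim"]["temperature_grid"] = list(
            self.sim.temperature_grid.temperatures
        )
        return d


def _sim_with_seed(cfg: PipelineConfig) -> SimulationConfig:
    # the pipeline seed wins over the one embedded in the simulation block
    return cfg.sim.with_seed(cfg.seed)


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run every stage and write the output bundle under ``cfg.out_dir``.

    Returns a dict of the in-memory results keyed by stage name; the
    same tables land on disk as TSVs.  With ``cfg.simulate`` the three
    input tables (and their ground truth) are generated first and also
    written, and a truth-vs-rank report joins the planted targets to
    their final aggregate ranks.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.simulate:
        sim = _sim_with_seed(cfg)
        tpp_table, tpp_truth = simulate_tpp_dataset(sim)
        expr_table, expr_truth = simulate_fitexp_dataset(sim)
        redox_table, redox_truth = simulate_redox_dataset(sim)
        grid = sim.temperature_grid
        io.write_tpp_table(tpp_table, out / "input_tpp.tsv")
        io.write_expression_table(expr_table, out / "input_expression.tsv")
        io.write_redox_table(redox_table, out / "input_redox.tsv")
        io.write_table(tpp_truth, out / "truth_tpp.tsv")
        io.write_table(expr_truth, out / "truth_expression.tsv")
        io.write_table(redox_truth, out / "truth_redox.tsv")
    else:
        if not (cfg.tpp_path and cfg.expression_path and cfg.redox_path):
            raise ValueError("need all three input paths when not simulating")
        tpp_table, grid = io.read_tpp_table(cfg.tpp_path)
        expr_table = io.read_expression_table(cfg.expression_path)
        redox_table = io.read_redox_table(cfg.redox_path)
        tpp_truth = expr_truth = redox_truth = None

    # --- thermal proteome profiling ---
    logger.info("TPP: fitting %d traces", len(tpp_table))
    fits = tpp.fit_melting_curves(tpp_table, grid)
    shifts = tpp.compute_tm_shifts(
        fits,
        vehicle_label="vehicle",
        drug_label="drug",
        mode=cfg.concordance_mode,
    )
    concordant = tpp.filter_concordant(shifts, threshold=cfg.replicate_tm_threshold)
    tpp_ranking = tpp.rank_by_tm_shift(concordant, method="tpp")
    io.write_table(fits, out / "tpp_fits.tsv")
    io.write_table(shifts, out / "tpp_shifts.tsv")
    io.write_table(tpp_ranking.to_frame(), out / "ranking_tpp.tsv")

    # --- expression proteomics ---
    logger.info("expression: scoring %d rows", len(expr_table))
    scores, fitexp_ranking = fitexp.rank_expression(
        expr_table, signed=cfg.fitexp_signed, method="fitexp"
    )
    io.write_table(scores, out / "fitexp_scores.tsv")
    io.write_table(fitexp_ranking.to_frame(), out / "ranking_fitexp.tsv")

    # --- redox proteomics ---
    logger.info("redox: %d label-pair rows", len(redox_table))
    with_ratios = redox.add_oxidation_ratios(redox_table)
    complete = redox.complete_case_filter(with_ratios)
    peptides = redox.peptide_differential_oxidation(complete)
    ranked_peptides = redox.redox_dual_rank(peptides, absolute=cfg.redox_absolute)
    redox_ranking = redox.best_peptide_per_protein(ranked_peptides, method="redox")
    io.write_table(ranked_peptides, out / "redox_peptides.tsv")
    io.write_table(redox_ranking.to_frame(), out / "ranking_redox.tsv")

    # --- aggregation + concordance ---
    rankings = [tpp_ranking, fitexp_ranking, redox_ranking]
    result = aggregate.aggregate_ranks(
        rankings, policy=cfg.imputation_policy, normalize=cfg.normalize_rank_sums
    )
    io.write_table(result, out / "aggregate.tsv")
    conc = aggregate.stability_oxidation_concordance(
        concordant,
        ranked_peptides,
        p_threshold=cfg.concordance_p_threshold,
        tm_threshold=cfg.concordance_tm_threshold,
    )
    io.write_table(conc, out / "concordance.tsv")

    report = None
    if cfg.simulate:
        targets = tpp_truth.loc[tpp_truth["is_target"], ["protein_id"]]
        report = targets.merge(
            result[["protein_id", "cumulative_sum", "final_rank"]],
            on="protein_id",
            how="left",
        ).sort_values("final_rank", kind="stable")
        io.write_table(report, out / "target_report.tsv")

    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "versions": {
            "targetrank": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "row_counts": {
            "tpp_input": int(len(tpp_table)),
            "expression_input": int(len(expr_table)),
            "redox_input": int(len(redox_table)),
            "tpp_fits": int(len(fits)),
            "tpp_ranked": int(tpp_ranking.n_ranked),
            "fitexp_ranked": int(fitexp_ranking.n_ranked),
            "redox_peptides_ranked": int(len(ranked_peptides)),
            "redox_ranked": int(redox_ranking.n_ranked),
            "aggregate": int(len(result)),
            "concordance_pairs": int(len(conc)),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "fits": fits,
        "shifts": shifts,
        "tpp_ranking": tpp_ranking,
        "scores": scores,
        "fitexp_ranking": fitexp_ranking,
        "peptides": ranked_peptides,
        "redox_ranking": redox_ranking,
        "aggregate": result,
        "concordance": conc,
        "target_report": report,
        "manifest": manifest,
    }
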