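"""Convenience driver: simulate -> process -> stratify -> fit -> aggregate."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .census import ReferencePopulation, build_reference_population
from .model import ModelConfig, PosteriorDraws, build_design, fit_excess_model
from .poststrat import ExcessEstimate, age_specific_excess, aggregate_excess
from .simulate import PopulationTable, SimConfig, simulate_survey, to_tables
from .strata import build_strata, census_weights


@dataclass
class PipelineResult:
    population: PopulationTable
    tables: dict
    reference: ReferencePopulation
    cells: pd.DataFrame
    weights: pd.DataFrame
    draws: PosteriorDraws
    excess: ExcessEstimate
    excess_by_age: dict = field(default_factory=dict)


def run_pipeline(sim_config: SimConfig,
                 model_config: ModelConfig,
                 by_age: bool = False) -> PipelineResult:
    """Run the full synthetic pipeline and return every intermediate."""
    pop = simulate_survey(sim_config)
    tables = to_tables(pop)
    ref = build_reference_population(
        tables["census"], tables["round1"], tables["round2"])
    cells = build_strata(ref)
    weights = census_weights(tables["census"])
    inputs = build_design(cells, model_config)
    draws = fit_excess_model(inputs, model_config)
    est = aggregate_excess(draws, weights)
    by_age_est = age_specific_excess(draws, weights) if by_age else {}
    return PipelineResult(population=pop, tables=tables, reference=ref,
                          cells=cells, weights=weights, draws=draws,
                          excess=est, excess_by_age=by_age_est)
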