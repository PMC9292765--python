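"""End-to-end orchestration: ranks -> frequency table -> matching -> balance -> effects."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .balance import asb_table, balance_summary, diagnostics
from .effects import atenc_all
from .errors import ConfigurationError
from .matching import (
    FrequencyTable,
    MatchReport,
    MatchedDataset,
    build_frequency_table,
    match,
    matched_to_table,
)
from .poset import (
    RankTable,
    VariableSpec,
    assign_unit_ranks,
    average_rank,
    build_relation,
    encode_profiles,
)


@dataclass
class PipelineResult:
    """Everything one run of the matching pipeline produces."""

    rank_table: RankTable
    unit_ars: np.ndarray
    frequency_table: FrequencyTable
    matched: MatchedDataset
    report: MatchReport
    matched_table: pd.DataFrame
    balance_before: pd.DataFrame
    balance_after: pd.DataFrame
    summary_before: dict
    summary_after: dict
    diagnostics: dict
    effects: pd.DataFrame | None = None


def run_pipeline(
    data: pd.DataFrame,
    specs: list[VariableSpec],
    treatment_col: str,
    id_col: str | None = None,
    outcome_col: str | None = None,
    estimator: str = "lpom0",
    fr_rule: str = "median",
    caliper_multiplier: float = 0.25,
    seed: int = 0,
    n_boot: int = 1000,
    estimator_kwargs: dict | None = None,
) -> PipelineResult:
    """Run the full method on a unit table.

    ``data`` needs one row per unit with the declared confounder columns
    and a treatment label; ``id_col`` defaults to the positional index.
    When ``outcome_col`` is given (binary 0/1), per-treatment
    treatment-vs-rest effects are estimated on the matched population.
    """
    if treatment_col not in data.columns:
        raise ConfigurationError(f"treatment column {treatment_col!r} not in data")
    if outcome_col is not None and outcome_col not in data.columns:
        raise ConfigurationError(f"outcome column {outcome_col!r} not in data")
    data = data.reset_index(drop=True)
    ids = (
        data[id_col].to_numpy()
        if id_col is not None
        else np.arange(len(data))
    )

    poset, unit_profiles = encode_profiles(data, specs)
    build_relation(poset)
    kwargs = dict(estimator_kwargs or {})
    if estimator == "sampled":
        kwargs.setdefault("n_samples", 10_000)
        kwargs.setdefault("seed", seed)
    rank_table = average_rank(poset, estimator, **kwargs)
    unit_ars = assign_unit_ranks(rank_table, unit_profiles)

    freq = build_frequency_table(
        unit_ars,
        data[treatment_col].to_numpy(),
        fr_rule=fr_rule,
        caliper_multiplier=caliper_multiplier,
    )
    matched, report = match(
        freq, ids, unit_ars, data[treatment_col].to_numpy(), seed=seed
    )

    work = data.rename(columns={treatment_col: "treatment"})
    balance_before = asb_table(work, specs, "treatment", "before")
    matched_table = matched_to_table(matched, work)
    balance_after = asb_table(matched_table, specs, "treatment", "after")

    effects = None
    if outcome_col is not None:
        matched_table = matched_table.rename(columns={outcome_col: "outcome"})
        effects = atenc_all(
            matched_table,
            outcome_col="outcome",
            treatment_col="treatment",
            source_col="source_unit_id",
            n_boot=n_boot,
            seed=seed,
        )

    return PipelineResult(
        rank_table=rank_table,
        unit_ars=unit_ars,
        frequency_table=freq,
        matched=matched,
        report=report,
        matched_table=matched_table,
        balance_before=balance_before,
        balance_after=balance_after,
        summary_before=balance_summary(balance_before["asb_pct"].to_numpy()),
        summary_after=balance_summary(balance_after["asb_pct"].to_numpy()),
        diagnostics=diagnostics(matched, report),
        effects=effects,
    )
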