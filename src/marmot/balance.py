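"""Covariate balance via the absolute standardized bias (ASB).

Every confounder level becomes a 0/1 dummy, and for each treatment group t
and dummy X the ASB is

    ASB = 100 * |mean_t(X) - mean(X)| / sqrt((var_t(X) + var(X)) / 2)

with sample variances (denominator n-1) and the overall mean/variance taken
over the whole analysis population — the raw units before matching, or the
matched artificial population (repetitions counted) after.  Summaries
follow the standard eight-statistic layout: min, quartiles, max, mean, and
the counts of ASB values strictly over 5% and over 10%.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .matching import MatchedDataset, MatchReport
from .poset import VariableSpec


def asb(group_values, all_values) -> float:
    """ASB (in percent) of one dummy in one treatment group vs the population.

    Returns 0 when both variances vanish with equal means, and ``inf``
    (with a warning) when they vanish with unequal means — a degenerate
    dummy constant at different values in group and population.
    """
    g = np.asarray(group_values, dtype=float)
    a = np.asarray(all_values, dtype=float)
    if g.size == 0 or a.size == 0:
        raise DataError("empty value vector in ASB computation")
    mg, ma = g.mean(), a.mean()
    vg = g.var(ddof=1) if g.size > 1 else 0.0
    va = a.var(ddof=1) if a.size > 1 else 0.0
    pooled = (vg + va) / 2.0
    if pooled == 0.0:
        if mg == ma:
            return 0.0
        warnings.warn(
            "zero variance in both group and population with unequal means; "
            "reporting infinite ASB"
        )
        return float("inf")
    return 100.0 * abs(mg - ma) / np.sqrt(pooled)


def dummy_matrix(data: pd.DataFrame, specs: Sequence[VariableSpec]) -> pd.DataFrame:
    """0/1 indicator for every declared level of every declared confounder."""
    cols = {}
    for spec in specs:
        col = data[spec.name]
        for lev in spec.levels:
            cols[f"{spec.name}={lev}"] = (col == lev).astype(np.int64)
    return pd.DataFrame(cols, index=data.index)


def asb_table(
    data: pd.DataFrame,
    specs: Sequence[VariableSpec],
    treatment_col: str,
    stage: str,
) -> pd.DataFrame:
    """Long-format ASB table: one row per (treatment, confounder level).

    Columns: ``stage, treatment, variable, level, asb_pct``.
    """
    dummies = dummy_matrix(data, specs)
    t = data[treatment_col].to_numpy()
    labels = np.unique(t)
    X = dummies.to_numpy(dtype=float)
    n = X.shape[0]
    mean_all = X.mean(axis=0)
    var_all = X.var(axis=0, ddof=1) if n > 1 else np.zeros(X.shape[1])

    rows = []
    names = [c.split("=", 1) for c in dummies.columns]
    for lab in labels:
        mask = t == lab
        Xg = X[mask]
        mg = Xg.mean(axis=0)
        vg = Xg.var(axis=0, ddof=1) if Xg.shape[0] > 1 else np.zeros(X.shape[1])
        pooled = (vg + var_all) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = 100.0 * np.abs(mg - mean_all) / np.sqrt(pooled)
        vals = np.where(pooled == 0.0, np.where(mg == mean_all, 0.0, np.inf), vals)
        for (var, lev), v in zip(names, vals):
            rows.append((stage, lab, var, lev, float(v)))
    return pd.DataFrame(
        rows, columns=["stage", "treatment", "variable", "level", "asb_pct"]
    )


_SUMMARY_KEYS = (
    "min", "first_quartile", "median", "third_quartile",
    "max", "mean", "n_over_5", "n_over_10",
)


def balance_summary(asb_values) -> dict:
    """Eight-statistic summary of a collection of ASB values (percent scale).

    Quartiles use linear interpolation between order statistics; the over-5
    and over-10 counts are strict and inclusive (over-10 is a subset of
    over-5).
    """
    v = np.asarray(asb_values, dtype=float)
    if v.size == 0:
        raise DataError("no ASB values to summarize")
    return {
        "min": float(v.min()),
        "first_quartile": float(np.quantile(v, 0.25)),
        "median": float(np.quantile(v, 0.5)),
        "third_quartile": float(np.quantile(v, 0.75)),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "n_over_5": int((v > 5.0).sum()),
        "n_over_10": int((v > 10.0).sum()),
    }


def per_treatment_over_counts(asb_long: pd.DataFrame) -> pd.DataFrame:
    """Counts of ASB values over 5% / 10% within each treatment group."""
    g = asb_long.groupby("treatment")["asb_pct"]
    return pd.DataFrame(
        {
            "n_over_5": g.apply(lambda s: int((s > 5.0).sum())),
            "n_over_10": g.apply(lambda s: int((s > 10.0).sum())),
        }
    ).reset_index()


def diagnostics(matched: MatchedDataset, report: MatchReport) -> dict:
    """The five matching diagnostics: inclusion %, repetition mean/max, sizes.

    Recomputed from the matched records themselves (the report's values are
    cross-checked by tests against this independent pass).
    """
    if len(matched) == 0:
        raise DataError("empty matched dataset")
    rec = matched.records
    reps = rec["source_index"].value_counts()
    sizes = rec["treatment"].value_counts()
    return {
        "inclusion_pct": report.inclusion_pct,
        "rep_mean": float(reps.mean()),
        "rep_max": int(reps.max()),
        "group_size": int(sizes.iloc[0]),
        "population_size": int(len(rec)),
    }
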