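"""Treatment-effect estimation on the matched population.

The headline estimand is the ATENC — the average treatment effect of one
group against the unweighted average of all the others ("this neighborhood
versus the rest of the city"):

    ATENC_t = E[ Y(t) - (1/(K-1)) * sum_{c != t} Y(c) ]

estimated on the matched records by plain group means (exact AR-level
balance makes covariate weighting redundant).  Grouped contrasts between
two disjoint treatment subsets generalize this.  Standard errors account
for the repetitions the matching introduces by a cluster bootstrap that
resamples *source units* (with all their matched copies) within treatment;
p-values are two-sided normal, and multiplicity is handled by
Benjamini-Hochberg flags at FDR 1% / 5% / 10%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError

BH_THRESHOLDS = (0.01, 0.05, 0.10)


def atenc_from_means(group_means) -> np.ndarray:
    """ATENC vector from per-treatment outcome means (pure algebra).

    ``atenc_t = m_t - mean of the other K-1 group means``; sums to zero
    and satisfies ``atenc_a - atenc_b = K/(K-1) * (m_a - m_b)``.
    """
    m = np.asarray(group_means, dtype=float)
    K = m.size
    if K < 2:
        raise ConfigurationError("need at least 2 treatment groups")
    return (m * K - m.sum()) / (K - 1)


def group_means(table: pd.DataFrame, outcome_col: str, treatment_col: str) -> pd.Series:
    y = table[outcome_col]
    if y.isna().any():
        raise DataError(f"missing outcome values in column {outcome_col!r}")
    return table.groupby(treatment_col)[y.name].mean()


def bh_adjust(p_values, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up: flag discoveries at FDR level ``q``.

    Flags the largest i with p_(i) <= (i/m) q and every smaller p-value.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = (np.arange(1, m + 1) / m) * q
    passed = np.flatnonzero(p[order] <= thresh)
    flags = np.zeros(m, dtype=bool)
    if passed.size:
        flags[order[: passed[-1] + 1]] = True
    return flags


@dataclass
class GroupContrast:
    """Mean-outcome contrast between two disjoint treatment subsets."""

    s1: tuple
    s2: tuple
    estimate: float
    se: float | None = None
    p_value: float | None = None


def group_ate(
    table: pd.DataFrame,
    s1,
    s2,
    outcome_col: str = "outcome",
    treatment_col: str = "treatment",
) -> GroupContrast:
    """Unweighted-over-treatments contrast between subsets ``s1`` and ``s2``."""
    s1, s2 = tuple(s1), tuple(s2)
    if not s1 or not s2:
        raise ConfigurationError("both treatment subsets must be non-empty")
    if set(s1) & set(s2):
        raise ConfigurationError("treatment subsets must be disjoint")
    means = group_means(table, outcome_col, treatment_col)
    missing = (set(s1) | set(s2)) - set(means.index)
    if missing:
        raise ConfigurationError(f"treatments not present in data: {sorted(missing)}")
    est = float(means.loc[list(s1)].mean() - means.loc[list(s2)].mean())
    return GroupContrast(s1, s2, est)


def _cluster_arrays(table, outcome_col, treatment_col, source_col):
    """Collapse matched records to (copies, unit outcome) per source unit, by group."""
    agg = (
        table.groupby([treatment_col, source_col])[outcome_col]
        .agg(["size", "mean"])
        .reset_index()
    )
    out = {}
    for lab, sub in agg.groupby(treatment_col):
        out[lab] = (
            sub["size"].to_numpy(dtype=float),
            sub["mean"].to_numpy(dtype=float),
        )
    return out


def cluster_bootstrap_atenc(
    table: pd.DataFrame,
    outcome_col: str = "outcome",
    treatment_col: str = "treatment",
    source_col: str = "source_unit_id",
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Bootstrap the ATENC vector by resampling source units within treatment.

    Each draw resamples, within every treatment group, the distinct source
    units with replacement; a resampled unit brings its full set of matched
    copies (its repetition count acts as a weight).  Returns the point
    estimates and a DataFrame of per-treatment SEs and two-sided normal
    p-values.  Because the matched outcome is unit-level, records collapse
    to (copies, outcome) pairs per unit, making each draw a weighted mean.
    """
    if n_boot < 50:
        warnings.warn(f"n_boot={n_boot} is small; standard errors will be noisy")
    means = group_means(table, outcome_col, treatment_col)
    labels = list(means.index)
    est = pd.Series(atenc_from_means(means.to_numpy()), index=labels, name="atenc")

    clusters = _cluster_arrays(table, outcome_col, treatment_col, source_col)
    rng = np.random.default_rng(seed)
    K = len(labels)
    boot_means = np.empty((n_boot, K))
    for k, lab in enumerate(labels):
        w, y = clusters[lab]
        n_u = w.size
        wy = w * y
        idx = rng.integers(0, n_u, size=(n_boot, n_u))
        num = wy[idx].sum(axis=1)
        den = w[idx].sum(axis=1)
        boot_means[:, k] = num / den
    boot_atenc = np.apply_along_axis(atenc_from_means, 1, boot_means)
    se = boot_atenc.std(axis=0, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est.to_numpy() / se, 0.0)
    p = np.where(
        se > 0,
        2.0 * stats.norm.sf(np.abs(z)),
        np.where(est.to_numpy() == 0.0, 1.0, 0.0),
    )
    detail = pd.DataFrame({"treatment": labels, "se": se, "p_value": p})
    return est, detail


def atenc_all(
    table: pd.DataFrame,
    outcome_col: str = "outcome",
    treatment_col: str = "treatment",
    source_col: str = "source_unit_id",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """ATENC for every treatment with repetition-aware SEs and FDR flags.

    Returns a DataFrame with columns
    ``treatment, atenc, atenc_x100, se, p_value, bh_01, bh_05, bh_10``
    (estimates on the probability scale; the x100 column is display only).
    """
    if table[outcome_col].isna().any():
        raise DataError("outcome contains missing values")
    vals = set(pd.unique(table[outcome_col]))
    if not vals <= {0, 1}:
        raise DataError(f"outcome must be binary 0/1, found values {sorted(vals)[:5]}")
    n_groups = table[treatment_col].nunique()
    if n_groups < 2:
        raise ConfigurationError("ATENC requires at least 2 treatment groups")

    est, detail = cluster_bootstrap_atenc(
        table, outcome_col, treatment_col, source_col, n_boot=n_boot, seed=seed
    )
    out = detail.copy()
    out.insert(1, "atenc", est.to_numpy())
    out.insert(2, "atenc_x100", est.to_numpy() * 100.0)
    for q in BH_THRESHOLDS:
        out[f"bh_{int(q * 100):02d}"] = bh_adjust(out["p_value"].to_numpy(), q)
    return out
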