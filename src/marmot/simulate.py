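"""Synthetic populations for validating the matching pipeline.

Real applications of this method draw on administrative registries that
cannot be redistributed, so validation runs on generated populations that
mirror that setting: a handful of categorical confounders (2-5 levels
each), many treatment groups (tens of "neighborhoods") allocated by a
multinomial logistic model whose coefficients are freshly perturbed in
every replication, and a rare binary outcome (prevalence around 1%) with
known injected per-group risk differences so that effect recovery can be
checked against an analytic truth.

The confounders are fixed across replications of a study (only treatment
and outcome are redrawn), so the poset and the average ranks are computed
once per study, exactly as one would on observed registry data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .balance import asb_table, balance_summary, diagnostics
from .errors import ConfigurationError, MarmotError
from .matching import build_frequency_table, match, matched_to_table
from .poset import (
    VariableSpec,
    assign_unit_ranks,
    average_rank,
    build_relation,
    encode_profiles,
)
from .effects import atenc_from_means, group_means

#: the base scenario: five confounders with 3-4 levels each (324 theoretical
#: profiles), mimicking the demographic registers such studies draw on.  All
#: five are declared ordered: applied poset studies code every confounder as
#: an ordered factor (assigning a working order to levels like region of
#: birth), because a poset whose nominal variables are dummy-expanded
#: decomposes into identical components whose average ranks tie by symmetry,
#: leaving too few distinct rank values to match on.  The dummy-expansion
#: pathway remains available via ``kind="nominal"`` for data where no
#: working order is acceptable.
DEFAULT_VARIABLES = (
    VariableSpec("age_class", "ordered", ("60-69", "70-79", "80-89", "90+")),
    VariableSpec("education", "ordered", ("primary", "secondary", "tertiary")),
    VariableSpec("household", "ordered", ("alone", "couple", "larger")),
    VariableSpec("occupation", "ordered", ("manual", "clerical", "home")),
    VariableSpec("region_birth", "ordered", ("north", "south", "abroad")),
)

DEFAULT_MARGINALS = {
    "age_class": (0.40, 0.32, 0.22, 0.06),
    "education": (0.45, 0.38, 0.17),
    "household": (0.30, 0.45, 0.25),
    "occupation": (0.44, 0.33, 0.23),
    "region_birth": (0.52, 0.34, 0.14),
}


@dataclass
class ScenarioConfig:
    """Full description of one simulated study.

    ``scenario`` selects the treatment-allocation design: ``additive`` uses
    main-effect dummies only (coefficients perturbed by U(-0.01, 0.01) each
    replication); ``interactions`` adds all pairwise interactions between
    the variables' dummies (perturbation U(-0.1, 0.1)).  Perturbed
    coefficients are rounded to 3 decimals.  ``coef_scale`` sets the spread
    of the base allocation coefficients (drawn once per study when not
    supplied); 0 gives completely random, balanced allocation.
    """

    n_units: int = 20_000
    variables: Sequence[VariableSpec] = DEFAULT_VARIABLES
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    dependence: float = 0.25
    n_treatments: int = 23
    scenario: str = "additive"
    base_coefficients: np.ndarray | None = None
    coef_scale: float = 0.3
    intercept_scale: float = 0.3
    perturbation_halfwidth: float | None = None  # default set per scenario
    round_decimals: int = 3
    outcome_base_rate: float = 0.009
    outcome_coefficients: np.ndarray | None = None
    outcome_coef_scale: float = 0.002
    injected_effects: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in ("additive", "interactions"):
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.perturbation_halfwidth is None:
            self.perturbation_halfwidth = 0.01 if self.scenario == "additive" else 0.1
        if self.perturbation_halfwidth <= 0:
            raise ConfigurationError("perturbation_halfwidth must be > 0")
        if not 0.0 < self.outcome_base_rate < 1.0:
            raise ConfigurationError("outcome_base_rate must lie in (0, 1)")
        if self.injected_effects is None:
            self.injected_effects = np.zeros(self.n_treatments)
        self.injected_effects = np.asarray(self.injected_effects, dtype=float)
        if self.injected_effects.size != self.n_treatments:
            raise ConfigurationError("injected_effects must have one entry per treatment")
        for spec in self.variables:
            probs = np.asarray(self.marginals[spec.name], dtype=float)
            if probs.size != len(spec.levels) or not np.isclose(probs.sum(), 1.0):
                raise ConfigurationError(
                    f"marginals for {spec.name!r} must have one probability per level "
                    "and sum to 1"
                )

    @property
    def treatment_labels(self) -> np.ndarray:
        return np.arange(1, self.n_treatments + 1)


# ---------------------------------------------------------------------------
# generation

def generate_confounders(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw a unit table of categorical confounders.

    The joint distribution over full profiles is the product of the
    declared marginals, log-linearly tilted by
    ``exp(dependence * sum_{i<j} z_i z_j)`` where ``z`` is the standardized
    level index of each variable — zero ``dependence`` gives independent
    confounders, positive values the mild positive association
    demographic variables typically show.
    """
    specs = list(config.variables)
    shapes = [len(s.levels) for s in specs]
    grids = np.meshgrid(*[np.arange(k) for k in shapes], indexing="ij")
    codes = np.stack([g.ravel() for g in grids], axis=1)  # (cells, n_vars)

    logp = np.zeros(codes.shape[0])
    zs = []
    for j, spec in enumerate(specs):
        probs = np.asarray(config.marginals[spec.name], dtype=float)
        logp += np.log(probs)[codes[:, j]]
        idx = np.arange(len(spec.levels), dtype=float)
        z = (idx - idx.mean()) / (idx.std() if idx.std() > 0 else 1.0)
        zs.append(z[codes[:, j]])
    if config.dependence != 0.0:
        for a in range(len(specs)):
            for b in range(a + 1, len(specs)):
                logp += config.dependence * zs[a] * zs[b]
    p = np.exp(logp - logp.max())
    p /= p.sum()

    cells = rng.choice(codes.shape[0], size=config.n_units, p=p)
    data = {}
    for j, spec in enumerate(specs):
        levels = np.asarray(spec.levels, dtype=object)
        data[spec.name] = levels[codes[cells, j]]
    df = pd.DataFrame(data)
    df.insert(0, "unit_id", np.arange(config.n_units))
    return df


def _main_dummies(df: pd.DataFrame, specs: Sequence[VariableSpec]) -> np.ndarray:
    """Drop-first dummy coding of every variable (multinomial-logit design)."""
    cols = []
    for spec in specs:
        col = df[spec.name].to_numpy()
        for lev in spec.levels[1:]:
            cols.append((col == lev).astype(float))
    return np.column_stack(cols)


def design_matrix(df: pd.DataFrame, config: ScenarioConfig) -> np.ndarray:
    """Intercept + main-effect dummies, plus all pairwise interactions
    between dummies of different variables under the ``interactions`` scenario."""
    specs = list(config.variables)
    D = _main_dummies(df, specs)
    blocks = [np.ones((len(df), 1)), D]
    if config.scenario == "interactions":
        # which variable owns each dummy column
        owner = np.concatenate(
            [[j] * (len(s.levels) - 1) for j, s in enumerate(specs)]
        )
        inter = [
            D[:, a] * D[:, b]
            for a in range(D.shape[1])
            for b in range(a + 1, D.shape[1])
            if owner[a] != owner[b]
        ]
        if inter:
            blocks.append(np.column_stack(inter))
    return np.concatenate(blocks, axis=1)


def base_coefficients(config: ScenarioConfig, n_features: int, rng) -> np.ndarray:
    """The study's (K-1) x p base allocation coefficients.

    User-supplied when given; otherwise drawn once from centered Gaussians
    (``intercept_scale`` for intercepts, ``coef_scale`` elsewhere).  The
    last treatment is the multinomial reference with all-zero coefficients.
    """
    if config.base_coefficients is not None:
        B = np.asarray(config.base_coefficients, dtype=float)
        if B.shape != (config.n_treatments - 1, n_features):
            raise ConfigurationError(
                f"base_coefficients must have shape {(config.n_treatments - 1, n_features)}, "
                f"got {B.shape}"
            )
        return B
    B = rng.normal(0.0, config.coef_scale, size=(config.n_treatments - 1, n_features))
    B[:, 0] = rng.normal(0.0, config.intercept_scale, size=config.n_treatments - 1)
    return B


def allocate_treatment(
    df: pd.DataFrame,
    config: ScenarioConfig,
    rng: np.random.Generator,
    coefficients: np.ndarray | None = None,
) -> np.ndarray:
    """Assign each unit a treatment label by multinomial logit.

    The base coefficients are perturbed by U(-h, +h) and rounded to
    ``round_decimals`` before computing the linear predictors; the last
    treatment is the reference category (linear predictor 0).
    """
    X = design_matrix(df, config)
    B = coefficients if coefficients is not None else base_coefficients(config, X.shape[1], rng)
    h = config.perturbation_halfwidth
    Bp = np.round(B + rng.uniform(-h, h, size=B.shape), config.round_decimals)
    eta = X @ Bp.T  # (n, K-1)
    if not np.all(np.isfinite(eta)):
        bad = np.argwhere(~np.isfinite(Bp))
        raise ConfigurationError(f"non-finite linear predictor; coefficient index {bad[:1]}")
    eta = np.concatenate([eta, np.zeros((len(df), 1))], axis=1)
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random((len(df), 1))
    choice = (p.cumsum(axis=1) < u).sum(axis=1)
    return config.treatment_labels[choice]


def outcome_coefficients(config: ScenarioConfig, n_dummies: int, rng) -> np.ndarray:
    if config.outcome_coefficients is not None:
        c = np.asarray(config.outcome_coefficients, dtype=float)
        if c.size != n_dummies:
            raise ConfigurationError("outcome_coefficients shape mismatch")
        return c
    return rng.normal(0.0, config.outcome_coef_scale, size=n_dummies)


def generate_outcome(
    df: pd.DataFrame,
    treatments: np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator,
    coefficients: np.ndarray | None = None,
) -> np.ndarray:
    """Bernoulli outcome: base rate + confounder shift + injected group effect.

    ``P(Y=1 | x, t) = clip(base_rate + x'gamma + delta_t, 0, 1)``; warns if
    clipping touches more than 1% of units (effects too large for the rare
    base rate).
    """
    D = _main_dummies(df, list(config.variables))
    gamma = coefficients if coefficients is not None else outcome_coefficients(
        config, D.shape[1], rng
    )
    t_index = np.searchsorted(config.treatment_labels, treatments)
    p_raw = config.outcome_base_rate + D @ gamma + config.injected_effects[t_index]
    p = np.clip(p_raw, 0.0, 1.0)
    clipped = np.mean(p != p_raw)
    if clipped > 0.01:
        import warnings

        warnings.warn(
            f"outcome probability clipped for {100 * clipped:.1f}% of units; "
            "injected effects are large relative to the base rate"
        )
    return (rng.random(len(df)) < p).astype(np.int64)


def true_atenc(config: ScenarioConfig) -> np.ndarray:
    """Analytic ATENC truth implied by the injected additive effects.

    Additive effects shift every unit's potential outcome by ``delta_t``,
    so the confounder contribution cancels from every contrast (assuming
    no clipping) and the truth is the ATENC algebra applied to the deltas.
    """
    return atenc_from_means(config.injected_effects)


# ---------------------------------------------------------------------------
# replication driver

@dataclass
class ReplicationResult:
    """Per-replication records plus study-level aggregates."""

    per_replication: pd.DataFrame
    aggregate: dict
    atenc_estimates: pd.DataFrame | None = None
    atenc_truth: np.ndarray | None = None


def run_replications(
    config: ScenarioConfig,
    n_reps: int,
    estimator: str = "lpom0",
    compute_effects: bool = False,
    fr_rule: str = "median",
    caliper_multiplier: float = 0.25,
) -> ReplicationResult:
    """Generate once, then replicate allocation -> matching -> diagnostics.

    Confounders (hence the poset and the ARs) are generated once per study;
    each replication redraws the coefficient perturbation, the treatment
    assignment and (when effects are requested) the outcome, then runs the
    full matching pipeline and records before/after balance summaries and
    matching diagnostics.  Failures of single replications are recorded,
    not fatal.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    master = np.random.SeedSequence(config.seed)
    rng_pop = np.random.default_rng(master.spawn(1)[0])
    df = generate_confounders(config, rng_pop)
    specs = list(config.variables)

    poset, unit_profiles = encode_profiles(df, specs)
    build_relation(poset)
    kwargs = {"n_samples": 10_000, "seed": int(rng_pop.integers(2**31))} if estimator == "sampled" else {}
    rank_table = average_rank(poset, estimator, **kwargs)
    unit_ars = assign_unit_ranks(rank_table, unit_profiles)

    X = design_matrix(df, config)
    B = base_coefficients(config, X.shape[1], rng_pop)
    D_cols = _main_dummies(df, specs).shape[1]
    gamma = outcome_coefficients(config, D_cols, rng_pop)
    truth = true_atenc(config) if compute_effects else None

    rows = []
    est_rows = []
    rep_seeds = master.spawn(n_reps)
    for rep, ss in enumerate(rep_seeds):
        rng = np.random.default_rng(ss)
        try:
            t = allocate_treatment(df, config, rng, coefficients=B)
            work = df.copy()
            work["treatment"] = t
            before = asb_table(work, specs, "treatment", "before")
            s_before = balance_summary(before["asb_pct"].to_numpy())

            freq = build_frequency_table(
                unit_ars, t, fr_rule=fr_rule, caliper_multiplier=caliper_multiplier
            )
            matched, report = match(
                freq, df["unit_id"].to_numpy(), unit_ars, t,
                seed=int(rng.integers(2**31)),
            )
            mtab = matched_to_table(matched, work)
            after = asb_table(mtab, specs, "treatment", "after")
            s_after = balance_summary(after["asb_pct"].to_numpy())
            diag = diagnostics(matched, report)

            row = {"replication": rep, "failed": False}
            row.update({f"before_{k}": v for k, v in s_before.items()})
            row.update({f"after_{k}": v for k, v in s_after.items()})
            row.update(diag)
            rows.append(row)

            if compute_effects:
                y = generate_outcome(df, t, config, rng, coefficients=gamma)
                mtab["outcome"] = y[matched.records["source_index"].to_numpy()]
                means = group_means(mtab, "outcome", "treatment")
                est = atenc_from_means(means.to_numpy())
                est_rows.append(
                    {"replication": rep, **{str(l): e for l, e in zip(means.index, est)}}
                )
        except MarmotError as exc:  # pragma: no cover - defensive
            rows.append({"replication": rep, "failed": True, "error": str(exc)})

    per_rep = pd.DataFrame(rows)
    ok = per_rep[~per_rep["failed"]]
    agg = {"n_replications": n_reps, "n_failed": int(per_rep["failed"].sum())}
    for col in ok.columns:
        if col in ("replication", "failed", "error"):
            continue
        agg[f"mean_{col}"] = float(ok[col].mean())
    est_df = pd.DataFrame(est_rows) if compute_effects else None
    if compute_effects and len(est_df):
        est_means = est_df.drop(columns="replication").mean()
        agg["atenc_bias"] = {
            lab: float(est_means[str(lab)] - tr)
            for lab, tr in zip(config.treatment_labels, truth)
        }
    return ReplicationResult(per_rep, agg, est_df, truth)
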