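"""Average-rank frequency table and the equal-representation matching step.

After every unit carries an average rank (AR), units are cross-tabulated
into an R x K frequency table (distinct AR values by treatment group).  For
each AR row a reference frequency ``f_r`` — by default the row median,
floored at 1 — fixes how many records that AR value must contribute to
*every* treatment in the balanced artificial population.  Rows for which
some treatment has no unit within the caliper (a quarter of the AR sample
standard deviation) are discarded in all treatments, preserving overlap.

Filling is a two-pass procedure: a feasibility pass decides which rows
survive, then a fill pass copies or resamples units so every retained row
is represented exactly ``f_r`` times per treatment.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, EmptyOverlapError
from .poset import AR_DECIMALS

_FR_RULES = ("median", "min", "max")


def reference_frequency(row_counts, rule: str = "median") -> int:
    """Target per-treatment count for one AR row.

    ``median`` (the default rule): the median of the K counts, floored at 1
    so that no profile present in the data is dropped merely for having a
    zero-median row.  With an even number of treatments the midpoint of the
    two central order statistics is rounded up, keeping the target integral
    and favouring retention.  ``min`` and ``max`` are the sensitivity-axis
    alternatives; ``min`` is not floored (a zero minimum yields quota 0).
    """
    counts = np.asarray(row_counts)
    if counts.size < 2:
        raise ConfigurationError("need counts for K >= 2 treatments")
    if (counts < 0).any():
        raise ConfigurationError("counts must be non-negative")
    if rule == "median":
        med = _ceil_median(counts)
        return max(med, 1)
    if rule == "min":
        return int(counts.min())
    if rule == "max":
        return int(counts.max())
    raise ConfigurationError(f"unknown fr rule {rule!r}; choose from {_FR_RULES}")


def _ceil_median(counts: np.ndarray) -> int:
    s = np.sort(counts)
    k = s.size
    if k % 2:
        return int(s[k // 2])
    return int(math.ceil((int(s[k // 2 - 1]) + int(s[k // 2])) / 2))


@dataclass
class FrequencyTable:
    """R x K table of unit counts per (AR value, treatment) with row targets.

    ``ar_values`` are the sorted distinct unit-level ARs (rounded to the
    shared 9-decimal convention), ``counts[r, k]`` the number of units with
    AR ``ar_values[r]`` in treatment ``treatments[k]``, ``reference[r]`` the
    target frequency ``f_r``, ``sar`` the sample standard deviation of the
    unit-level ARs and ``caliper`` the matching tolerance.
    """

    ar_values: np.ndarray
    treatments: np.ndarray
    counts: np.ndarray
    reference: np.ndarray
    sar: float
    caliper: float
    fr_rule: str = "median"

    @property
    def n_rows(self) -> int:
        return self.ar_values.size

    @property
    def n_treatments(self) -> int:
        return self.treatments.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.treatments))
        df.insert(0, "ar", self.ar_values)
        df["f_r"] = self.reference
        return df


def build_frequency_table(
    unit_ars,
    treatments,
    fr_rule: str = "median",
    caliper_multiplier: float = 0.25,
) -> FrequencyTable:
    """Cross-tabulate unit ARs by treatment and fix per-row targets.

    ``caliper_multiplier`` scales the AR sample standard deviation (default
    1/4, the usual propensity-caliper heuristic transplanted to the AR).
    """
    ars = np.round(np.asarray(unit_ars, dtype=float), AR_DECIMALS)
    t = np.asarray(treatments)
    if ars.size != t.size:
        raise DataError("unit_ars and treatments must have equal length")
    if ars.size == 0:
        raise DataError("no units")
    if caliper_multiplier <= 0:
        raise ConfigurationError("caliper_multiplier must be > 0")
    t_labels, t_idx = np.unique(t, return_inverse=True)
    K = t_labels.size
    if K < 2:
        raise ConfigurationError(f"need at least 2 treatment groups, got {K}")
    ar_values, row_idx = np.unique(ars, return_inverse=True)
    counts = np.zeros((ar_values.size, K), dtype=np.int64)
    np.add.at(counts, (row_idx, t_idx), 1)
    reference = np.array([reference_frequency(row, fr_rule) for row in counts])
    sar = float(np.std(ars, ddof=1)) if ars.size > 1 else 0.0
    return FrequencyTable(
        ar_values=ar_values,
        treatments=t_labels,
        counts=counts,
        reference=reference,
        sar=sar,
        caliper=sar * caliper_multiplier,
        fr_rule=fr_rule,
    )


@dataclass
class MatchedDataset:
    """The balanced artificial population produced by matching.

    ``records`` has one row per matched record with columns
    ``source_index`` (positional index of the source unit),
    ``source_unit_id``, ``treatment``, ``target_ar_row`` (the AR value the
    record fills), ``own_ar`` and ``copy_index`` (1..reps of that unit).
    """

    records: pd.DataFrame

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


@dataclass
class MatchReport:
    """Diagnostics of one matching run (inclusion, repetitions, sizes)."""

    retained_rows: int
    discarded_rows: list = field(default_factory=list)
    inclusion_pct: float = 0.0
    rep_mean: float = 0.0
    rep_max: int = 0
    group_size: int = 0
    population_size: int = 0

    def to_dict(self) -> dict:
        return {
            "retained_rows": self.retained_rows,
            "discarded_rows": self.discarded_rows,
            "inclusion_pct": self.inclusion_pct,
            "rep_mean": self.rep_mean,
            "rep_max": self.rep_max,
            "group_size": self.group_size,
            "population_size": self.population_size,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def match(
    freq: FrequencyTable,
    unit_ids,
    unit_ars,
    treatments,
    seed: int,
    without_replacement_downsample: bool = False,
    donor_strategy: str = "uniform",
) -> tuple[MatchedDataset, MatchReport]:
    """Fill the balanced population row by row, treatment by treatment.

    Feasibility pass: a row is discarded iff some treatment has *no* unit
    with AR inside ``[AR_r - caliper, AR_r + caliper]``; discarding removes
    the row's quota from every treatment.  Fill pass, per retained row and
    treatment with count ``c`` and target ``f_r``:

    * ``c == f_r`` — copy each unit once;
    * ``c > 0`` and ``c != f_r`` — draw ``f_r`` with replacement from the
      row's own units in that treatment (optionally a without-replacement
      downsample when ``c > f_r``);
    * ``c == 0`` — draw ``f_r`` with replacement from the treatment's
      in-caliper donors (uniformly, or nearest-first with
      ``donor_strategy="nearest"``).

    Deterministic under a fixed ``seed``.
    """
    if donor_strategy not in ("uniform", "nearest"):
        raise ConfigurationError(f"unknown donor_strategy {donor_strategy!r}")
    ids = np.asarray(unit_ids)
    ars = np.round(np.asarray(unit_ars, dtype=float), AR_DECIMALS)
    t = np.asarray(treatments)
    R, K = freq.n_rows, freq.n_treatments
    cal = freq.caliper
    rng = np.random.default_rng(seed)

    t_idx = np.searchsorted(freq.treatments, t)
    row_idx = np.searchsorted(freq.ar_values, ars)

    # per-treatment views sorted by AR (donor pools via binary search)
    by_t_ar: list[np.ndarray] = []  # unit positions, ar-sorted, per treatment
    for k in range(K):
        members = np.flatnonzero(t_idx == k)
        by_t_ar.append(members[np.argsort(ars[members], kind="stable")])

    # ---- pass 1: feasibility --------------------------------------------
    feasible = np.ones((R, K), dtype=bool)
    for k in range(K):
        a = ars[by_t_ar[k]]
        lo = np.searchsorted(a, freq.ar_values - cal, side="left")
        hi = np.searchsorted(a, freq.ar_values + cal, side="right")
        feasible[:, k] = hi > lo
    retained = feasible.all(axis=1)
    # rows with a zero quota (fr==0 under the min rule) contribute nothing
    active = retained & (freq.reference > 0)

    discarded = []
    for r in np.flatnonzero(~retained):
        discarded.append(
            {
                "ar": float(freq.ar_values[r]),
                "missing_treatments": [
                    str(freq.treatments[k]) for k in np.flatnonzero(~feasible[r])
                ],
            }
        )
    if not active.any():
        diag = {
            str(freq.treatments[k]): int((~feasible[:, k]).sum()) for k in range(K)
        }
        raise EmptyOverlapError(
            "no AR row has support in every treatment within the caliper",
            diagnostics=diag,
        )

    # ---- pass 2: fill ----------------------------------------------------
    # unit positions grouped by (row, treatment)
    order = np.lexsort((row_idx, t_idx))
    cell_of = t_idx[order] * np.int64(R) + row_idx[order]
    boundaries = np.flatnonzero(np.diff(cell_of)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [order.size]))
    cell_slices = {int(cell_of[s]): (s, e) for s, e in zip(starts, ends)}

    picked: list[np.ndarray] = []
    rec_row: list[np.ndarray] = []
    rec_t: list[np.ndarray] = []
    for k in range(K):
        pool = by_t_ar[k]
        pool_ars = ars[pool]
        for r in np.flatnonzero(active):
            f_r = int(freq.reference[r])
            c = int(freq.counts[r, k])
            key = k * R + r
            if c == f_r:
                sel = order[slice(*cell_slices[key])]
            elif c > 0:
                cell = order[slice(*cell_slices[key])]
                if without_replacement_downsample and c > f_r:
                    sel = rng.choice(cell, size=f_r, replace=False)
                else:
                    sel = rng.choice(cell, size=f_r, replace=True)
            else:
                lo = np.searchsorted(pool_ars, freq.ar_values[r] - cal, side="left")
                hi = np.searchsorted(pool_ars, freq.ar_values[r] + cal, side="right")
                donors = pool[lo:hi]
                if donor_strategy == "nearest":
                    dist = np.abs(ars[donors] - freq.ar_values[r])
                    donors = donors[dist == dist.min()]
                sel = rng.choice(donors, size=f_r, replace=True)
            picked.append(sel)
            rec_row.append(np.full(sel.size, freq.ar_values[r]))
            rec_t.append(np.full(sel.size, freq.treatments[k]))

    src = np.concatenate(picked)
    records = pd.DataFrame(
        {
            "source_index": src,
            "source_unit_id": ids[src],
            "treatment": np.concatenate(rec_t),
            "target_ar_row": np.concatenate(rec_row),
            "own_ar": ars[src],
        }
    )
    records["copy_index"] = records.groupby("source_index").cumcount() + 1

    reps = records["source_index"].value_counts()
    n_active = int(active.sum())
    group_size = int(freq.reference[active].sum())
    report = MatchReport(
        retained_rows=n_active,
        discarded_rows=discarded,
        inclusion_pct=100.0 * reps.size / ids.size,
        rep_mean=float(reps.mean()),
        rep_max=int(reps.max()),
        group_size=group_size,
        population_size=group_size * K,
    )
    return MatchedDataset(records), report


def matched_to_table(
    matched: MatchedDataset, units: pd.DataFrame
) -> pd.DataFrame:
    """One output row per matched record, carrying all original unit columns.

    ``units`` is the original unit table; records reference it positionally
    through ``source_index``.
    """
    rec = matched.records
    if len(rec) == 0:
        cols = list(units.columns) + [
            "source_unit_id", "target_ar_row", "own_ar", "copy_index",
        ]
        return pd.DataFrame(columns=cols)
    base = units.iloc[rec["source_index"].to_numpy()].reset_index(drop=True)
    extra = rec[
        ["source_unit_id", "target_ar_row", "own_ar", "copy_index"]
    ].reset_index(drop=True)
    out = pd.concat([base, extra], axis=1)
    # treatment of the record equals the source unit's treatment by design;
    # keep the record's own label authoritative
    out["treatment"] = rec["treatment"].to_numpy()
    return out
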