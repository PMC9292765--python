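# marmot — poset-based average-rank matching for many treatment groups

`marmot` balances categorical confounders across **many** treatment groups
at once — the setting of neighborhood-effect studies, where tens of city
areas must be made comparable before their health outcomes can be
contrasted. Propensity-score methods strain when the number of groups K
reaches the tens; `marmot` instead summarizes each unit's confounders into
a single scalar derived from the partial order of confounder profiles, and
rebuilds the population so that scalar is equally represented everywhere.

## The method in brief

1. **Average rank.** Units sharing confounder values form a *profile*;
   profiles are partially ordered by componentwise dominance. The
   **average rank** AR(x) of a profile is its mean position over all
   linear extensions of that poset — a scalar confounder summary playing
   the role of a propensity score. Estimators: exact enumeration, the
   LPOM0 closed form `AR(x) = (s(x)+1)(P+1)/(P+1−u(x))` (default), or
   Monte-Carlo sampling of extensions.
2. **Matching.** Cross-tabulate units into an R × K table of AR values by
   treatment. Each row gets a reference frequency
   `f_r = max(median(f_r,1..f_r,K), 1)`, and the matched population gives
   every retained AR value exactly `f_r` records in *every* treatment —
   copying, resampling with replacement, or borrowing donors within a
   caliper of S_AR/4 (a quarter of the AR standard deviation). Rows some
   treatment cannot reach within the caliper are discarded everywhere,
   enforcing overlap.
3. **Balance.** Before/after balance is measured per treatment and
   confounder level by the absolute standardized bias
   `ASB = 100·|X̄_t − X̄| / sqrt((S_t²+S²)/2)`.
4. **Effects.** On the matched population, each group's effect versus the
   rest, `ATENC_t = E[Y(t)] − mean_{c≠t} E[Y(c)]`, is estimated by group
   means, with cluster-bootstrap standard errors over source units
   (repetitions are not independent) and Benjamini–Hochberg FDR flags.

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

```python
import numpy as np
import marmot
from marmot.simulate import (ScenarioConfig, generate_confounders,
                             allocate_treatment, generate_outcome)

# a synthetic registry: 20 000 units, 6 areas, 5 categorical confounders,
# outcome risk raised by 3 percentage points in area 3
cfg = ScenarioConfig(n_units=20_000, n_treatments=6, seed=7,
                     injected_effects=[0, 0, 0.03, 0, 0, 0],
                     outcome_base_rate=0.05)
rng = np.random.default_rng(cfg.seed)
df = generate_confounders(cfg, rng)
df["area"] = allocate_treatment(df, cfg, rng)
df["fracture"] = generate_outcome(df, df["area"].to_numpy(), cfg, rng)

res = marmot.run_pipeline(df, list(cfg.variables), "area",
                          id_col="unit_id", outcome_col="fracture",
                          seed=1, n_boot=500)
```

Output of the run above:

```
distinct profiles: 318
mean ASB before: 5.74%  after: 2.14%
ASB > 10%: before 14, after 1
inclusion: 62.3%  rep_max: 8  group size: 3344
 treatment  atenc_x100     se  p_value  bh_05
         1     -0.5263 0.0060   0.3812  False
         2     -0.0598 0.0065   0.9262  False
         3      3.1340 0.0086   0.0003   True
         4     -0.8493 0.0055   0.1240  False
         5     -1.1005 0.0055   0.0442  False
         6     -0.5981 0.0068   0.3775  False
```

Reading it: matching cut the mean absolute standardized bias from 5.7% to
2.1% and nearly eliminated badly unbalanced confounder levels (14 → 1 over
10%), while keeping 62% of units (each repeated at most 8 times) and
giving every area an identical matched size of 3344. On that balanced
population, area 3's excess risk is estimated at +3.13 outcomes per 100
residents versus the rest of the city (truth: +3.0, the injected risk
difference, since no other area carries one), the only contrast surviving FDR control
at 5% (`se` is on the probability scale; `atenc_x100` is display only).

## Command line

```bash
marmot run --input units.csv --config config.yaml --out results/ --seed 1
marmot simulate --scenario scenario.yaml --reps 100 --out sim/ --seed 1
```

`config.yaml` declares the variables (`name`, `kind: ordered|nominal`,
`levels`) and the treatment / id / optional outcome columns; `run` writes
the rank table, matched dataset, match report, balance tables, effect
table and a run log. `simulate` drives the synthetic replication study and
writes per-replication and aggregate balance tables.

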