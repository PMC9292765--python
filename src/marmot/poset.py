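"""Confounder posets and average-rank estimation.

Units are reduced to *profiles* — vectors of coded confounder levels — and
profiles are partially ordered by componentwise dominance (the product
order).  The average rank (AR) of a profile is its mean 1-based position
over all linear extensions of that poset; it plays the role a propensity
score plays in two-treatment matching: a scalar summary of the confounders
that nearby units share.

Three AR estimators are provided:

``exact``
    full enumeration of linear extensions (small posets only);
``lpom0``
    the local-partial-order closed form
    ``AR(x) = (s(x) + 1) * (P + 1) / (P + 1 - u(x))``,
    where ``s(x)`` counts elements strictly below ``x`` and ``u(x)`` counts
    elements incomparable to ``x``;
``sampled``
    Monte-Carlo over linear extensions (uniform whenever exact counting is
    tractable, approximately uniform via random topological sorts otherwise).

Ordered variables contribute one integer coordinate (their level index);
nominal variables are dummy-expanded into one binary coordinate per level,
so that the product order stays well defined for unordered categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError, OracleInfeasibleError

#: two profiles belong to the same AR row downstream iff their average ranks
#: agree after rounding to this many decimals
AR_DECIMALS = 9

_KINDS = ("ordered", "nominal")


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one confounder: its name, kind and level labels.

    For ``ordered`` variables the order of ``levels`` is the dominance
    order (first level is lowest).  For ``nominal`` variables the levels
    carry no order and are dummy-expanded into binary poset coordinates.
    """

    name: str
    kind: str
    levels: tuple

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigurationError(
                f"variable {self.name!r}: kind must be one of {_KINDS}, got {self.kind!r}"
            )
        levels = tuple(self.levels)
        if not levels:
            raise ConfigurationError(f"variable {self.name!r}: levels must be non-empty")
        if len(set(levels)) != len(levels):
            raise ConfigurationError(f"variable {self.name!r}: duplicate level labels")
        object.__setattr__(self, "levels", levels)

    @property
    def n_coords(self) -> int:
        return 1 if self.kind == "ordered" else len(self.levels)


def load_variable_specs(source) -> list[VariableSpec]:
    """Read a list of VariableSpec from a YAML/JSON file path or a mapping.

    Expected shape: ``{"variables": [{"name":..., "kind":..., "levels": [...]}, ...]}``
    (a bare list is also accepted).
    """
    if isinstance(source, (str,)) or hasattr(source, "read"):
        with open(source) if isinstance(source, str) else source as fh:  # type: ignore[arg-type]
            source = yaml.safe_load(fh)
    if isinstance(source, Mapping):
        source = source.get("variables", source)
    if not isinstance(source, Sequence):
        raise ConfigurationError("variable spec must be a list of mappings")
    return [VariableSpec(v["name"], v["kind"], tuple(v["levels"])) for v in source]


@dataclass
class Poset:
    """Distinct profiles with multiplicities and (optionally) their order relation.

    ``coords`` is a ``(P, d)`` integer array, one row per distinct profile;
    ``below`` (filled by :func:`build_relation`) is a ``(P, P)`` boolean
    matrix with ``below[i, j]`` true iff profile ``i`` is strictly below
    profile ``j`` in the product order.
    """

    coords: np.ndarray
    multiplicity: np.ndarray
    below: np.ndarray | None = None

    @property
    def n_profiles(self) -> int:
        return self.coords.shape[0]

    @property
    def n_units(self) -> int:
        return int(self.multiplicity.sum())

    def incomparabilities(self) -> np.ndarray:
        """Number of profiles incomparable to each profile (requires relation)."""
        self._require_relation()
        comparable = self.below.sum(axis=0) + self.below.sum(axis=1)
        return self.n_profiles - 1 - comparable

    def _require_relation(self):
        if self.below is None:
            raise ConfigurationError("poset relation not built; call build_relation first")


def encode_profiles(
    data: pd.DataFrame, specs: Sequence[VariableSpec]
) -> tuple[Poset, np.ndarray]:
    """Encode unit-level confounders into a deduplicated profile poset.

    Returns the poset (without its relation) and, for every unit, the row
    index of its profile in ``poset.coords``.  Coordinate order follows the
    declaration order of ``specs``; nominal dummies follow level order.
    """
    n = len(data)
    if n == 0:
        raise DataError("empty input table")
    columns = []
    for spec in specs:
        if spec.name not in data.columns:
            raise ConfigurationError(f"variable {spec.name!r} not found in data columns")
        col = data[spec.name]
        if col.isna().any():
            row = int(col.index[col.isna()][0])
            raise DataError(f"missing value for variable {spec.name!r} at row {row}")
        level_index = {lev: i for i, lev in enumerate(spec.levels)}
        codes = col.map(level_index)
        if codes.isna().any():
            bad = col[codes.isna()].iloc[0]
            raise ConfigurationError(
                f"unknown level {bad!r} for variable {spec.name!r}"
            )
        codes = codes.to_numpy(dtype=np.int64)
        if spec.kind == "ordered":
            columns.append(codes)
        else:
            for i in range(len(spec.levels)):
                columns.append((codes == i).astype(np.int64))
    full = np.column_stack(columns)
    uniq, inverse, counts = np.unique(
        full, axis=0, return_inverse=True, return_counts=True
    )
    poset = Poset(coords=uniq, multiplicity=counts)
    return poset, inverse.ravel()


def build_relation(poset: Poset) -> Poset:
    """Fill the strict product-order dominance relation in place (and return it).

    ``x`` is below ``y`` iff ``x.coords <= y.coords`` componentwise and the
    profiles differ; all remaining distinct pairs are incomparable.
    """
    c = poset.coords
    # (P, P) pairwise componentwise comparison; profiles are distinct, so
    # "all <=" excludes equality automatically off the diagonal
    le = (c[:, None, :] <= c[None, :, :]).all(axis=2)
    np.fill_diagonal(le, False)
    poset.below = le
    return poset


# ---------------------------------------------------------------------------
# linear extensions

def _below_masks(poset: Poset) -> list[int]:
    """Bitmask of elements strictly below each element."""
    poset._require_relation()
    P = poset.n_profiles
    masks = []
    for j in range(P):
        m = 0
        for i in np.flatnonzero(poset.below[:, j]):
            m |= 1 << int(i)
        masks.append(m)
    return masks


def count_linear_extensions(poset: Poset) -> int:
    """Exact number of linear extensions, by memoized recursion over up-sets."""
    P = poset.n_profiles
    masks = _below_masks(poset)
    full = (1 << P) - 1
    memo: dict[int, int] = {full: 1}

    def count(placed: int) -> int:
        if placed in memo:
            return memo[placed]
        total = 0
        remaining = full & ~placed
        r = remaining
        while r:
            low = r & -r
            j = low.bit_length() - 1
            r ^= low
            if masks[j] & ~placed == 0:
                total += count(placed | low)
        memo[placed] = total
        return total

    return count(0)


def enumerate_linear_extensions(poset: Poset, cap: int = 100_000) -> list[tuple[int, ...]]:
    """All linear extensions as tuples of profile indices, in a deterministic order.

    Counts first; if the count exceeds ``cap`` raises
    :class:`OracleInfeasibleError` rather than truncating silently.
    """
    P = poset.n_profiles
    n_ext = count_linear_extensions(poset)
    if n_ext > cap:
        raise OracleInfeasibleError(
            f"poset has {n_ext} linear extensions, exceeding cap={cap}; "
            "use the lpom0 or sampled estimator instead"
        )
    masks = _below_masks(poset)
    full = (1 << P) - 1
    out: list[tuple[int, ...]] = []
    prefix: list[int] = []

    def rec(placed: int):
        if placed == full:
            out.append(tuple(prefix))
            return
        for j in range(P):
            bit = 1 << j
            if placed & bit or masks[j] & ~placed:
                continue
            prefix.append(j)
            rec(placed | bit)
            prefix.pop()

    rec(0)
    return out


# ---------------------------------------------------------------------------
# rank tables

@dataclass
class RankTable:
    """Average ranks of the distinct profiles of a poset.

    ``average_rank`` lives in ``[1, P]``; ``normalized_rank`` maps it onto
    ``[0, 1]`` via ``(AR - 1) / (P - 1)`` (0 when ``P == 1``).
    """

    poset: Poset
    average_rank: np.ndarray
    estimator: str
    n_extensions_or_samples: int | None = None
    normalized_rank: np.ndarray = field(init=False)

    def __post_init__(self):
        P = self.poset.n_profiles
        if P > 1:
            self.normalized_rank = (self.average_rank - 1.0) / (P - 1.0)
        else:
            self.normalized_rank = np.zeros(P)

    def to_frame(self) -> pd.DataFrame:
        coords = [",".join(map(str, row)) for row in self.poset.coords]
        return pd.DataFrame(
            {
                "profile_id": np.arange(self.poset.n_profiles),
                "coords": coords,
                "multiplicity": self.poset.multiplicity,
                "average_rank": self.average_rank,
                "normalized_rank": self.normalized_rank,
                "estimator": self.estimator,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def average_rank_exact(poset: Poset, cap: int = 100_000) -> RankTable:
    """Exact AR: mean 1-based position over every linear extension."""
    exts = enumerate_linear_extensions(poset, cap=cap)
    P = poset.n_profiles
    pos_sum = np.zeros(P)
    for ext in exts:
        for pos, j in enumerate(ext, start=1):
            pos_sum[j] += pos
    ar = pos_sum / len(exts)
    return RankTable(poset, ar, "exact", len(exts))


def average_rank_lpom0(poset: Poset) -> RankTable:
    """Closed-form local-partial-order approximation of the AR.

    ``AR(x) = (s(x) + 1)(P + 1) / (P + 1 - u(x))`` with ``s`` the count of
    elements strictly below ``x`` and ``u`` the count incomparable to ``x``.
    Exact on chains; cheap on the large product-order posets real data give.
    """
    poset._require_relation()
    P = poset.n_profiles
    s = poset.below.sum(axis=0).astype(float)
    u = poset.incomparabilities().astype(float)
    ar = (s + 1.0) * (P + 1.0) / (P + 1.0 - u)
    return RankTable(poset, ar, "lpom0", None)


def average_rank_sampled(
    poset: Poset, n_samples: int, seed: int, enumerate_limit: int = 50_000
) -> RankTable:
    """Monte-Carlo AR over sampled linear extensions.

    Sampling is exactly uniform when the extension count is tractable:
    either by enumerating all extensions and drawing indices (count ≤
    ``enumerate_limit``) or by the sequential counting sampler (P ≤ 20).
    For larger posets extensions are drawn as random topological sorts with
    uniformly chosen minimal elements, which is only approximately uniform.
    """
    if n_samples < 1:
        raise ConfigurationError("n_samples must be >= 1")
    poset._require_relation()
    P = poset.n_profiles
    rng = np.random.default_rng(seed)

    if P <= 20:
        n_ext = count_linear_extensions(poset)
        if n_ext <= enumerate_limit:
            exts = np.array(enumerate_linear_extensions(poset, cap=enumerate_limit))
            # ranks[e, j] = position of element j in extension e
            ranks = np.empty_like(exts)
            rows = np.arange(exts.shape[0])[:, None]
            ranks[rows, exts] = np.arange(1, P + 1)[None, :]
            idx = rng.integers(0, exts.shape[0], size=n_samples)
            ar = ranks[idx].mean(axis=0).astype(float)
            return RankTable(poset, ar, "sampled", n_samples)
        sampler = _counting_sampler(poset)
    else:
        sampler = _topo_sampler(poset)

    pos_sum = np.zeros(P)
    for _ in range(n_samples):
        ext = sampler(rng)
        for pos, j in enumerate(ext, start=1):
            pos_sum[j] += pos
    return RankTable(poset, pos_sum / n_samples, "sampled", n_samples)


def _counting_sampler(poset: Poset):
    """Exactly uniform sequential sampler via memoized extension counts."""
    P = poset.n_profiles
    masks = _below_masks(poset)
    full = (1 << P) - 1
    memo: dict[int, int] = {full: 1}

    def count(placed: int) -> int:
        if placed in memo:
            return memo[placed]
        total = 0
        r = full & ~placed
        while r:
            low = r & -r
            j = low.bit_length() - 1
            r ^= low
            if masks[j] & ~placed == 0:
                total += count(placed | low)
        memo[placed] = total
        return total

    def sample(rng: np.random.Generator) -> list[int]:
        placed = 0
        ext = []
        for _ in range(P):
            avail = []
            weights = []
            r = full & ~placed
            while r:
                low = r & -r
                j = low.bit_length() - 1
                r ^= low
                if masks[j] & ~placed == 0:
                    avail.append(j)
                    weights.append(count(placed | low))
            w = np.asarray(weights, dtype=float)
            j = avail[rng.choice(len(avail), p=w / w.sum())]
            ext.append(j)
            placed |= 1 << j
        return ext

    return sample


def _topo_sampler(poset: Poset):
    """Random topological sorts, uniform over current minimal elements."""
    P = poset.n_profiles
    n_below = poset.below.sum(axis=0).astype(np.int64)
    above = [np.flatnonzero(poset.below[j, :]) for j in range(P)]

    def sample(rng: np.random.Generator) -> list[int]:
        remaining = n_below.copy()
        minimal = list(np.flatnonzero(remaining == 0))
        ext = []
        for _ in range(P):
            k = int(rng.integers(len(minimal)))
            j = minimal.pop(k)
            ext.append(j)
            for a in above[j]:
                remaining[a] -= 1
                if remaining[a] == 0:
                    minimal.append(int(a))
        return ext

    return sample


_ESTIMATORS = {
    "exact": average_rank_exact,
    "lpom0": average_rank_lpom0,
    "sampled": average_rank_sampled,
}


def average_rank(poset: Poset, estimator: str = "lpom0", **kwargs) -> RankTable:
    """Dispatch to one of the AR estimators by name."""
    try:
        fn = _ESTIMATORS[estimator]
    except KeyError:
        raise ConfigurationError(
            f"unknown estimator {estimator!r}; choose from {sorted(_ESTIMATORS)}"
        ) from None
    return fn(poset, **kwargs)


def assign_unit_ranks(rank_table: RankTable, unit_profiles: np.ndarray) -> np.ndarray:
    """Broadcast profile-level ARs back to the units (units share their profile's AR)."""
    unit_profiles = np.asarray(unit_profiles)
    P = rank_table.poset.n_profiles
    if unit_profiles.size and (unit_profiles.min() < 0 or unit_profiles.max() >= P):
        raise DataError("unit→profile map references a profile outside the rank table")
    return rank_table.average_rank[unit_profiles]


def check_transitivity(poset: Poset, max_profiles: int = 200) -> bool:
    """Triple-enumeration guard used by tests: the relation must be transitive.

    Product order is transitive by construction; this catches encoding bugs.
    """
    poset._require_relation()
    P = poset.n_profiles
    if P > max_profiles:
        raise ConfigurationError(f"transitivity check limited to P <= {max_profiles}")
    b = poset.below
    # b[i,j] and b[j,k] must imply b[i,k]
    implied = (b.astype(np.int8) @ b.astype(np.int8)) > 0
    return bool(np.all(~implied | b))
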