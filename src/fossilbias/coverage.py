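"""Coverage estimation and coverage-based rarefaction/extrapolation for
incidence-frequency data.

Sampling units are fossil collections; a species' incidence frequency Y_i is
the number of collections containing it.  Sample coverage (completeness in
the Good-Turing sense) is estimated at the reference sample with the
improved Good's u estimator, which corrects the classical 1 - Q1/U using
both singleton (Q1) and doubleton (Q2) frequencies:

    C_hat = 1 - (Q1/U) * [(T-1)*Q1 / ((T-1)*Q1 + 2*Q2)]

Richness is standardized to a target coverage ("quorum", conventionally
0.8) by exact interpolation over uniform subsets of sampling units, or by
Chao2-anchored extrapolation beyond the reference sample — the shareholder
quorum subsampling / coverage-based rarefaction family of estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "IncidenceFrequencyTable",
    "CoverageEstimate",
    "StandardizedDiversity",
    "NotViableError",
    "goods_u",
    "chao2",
    "bootstrap_coverage_ci",
    "interpolated_richness",
    "interpolated_coverage",
    "extrapolate",
    "diversity_at_quorum",
]


class NotViableError(ValueError):
    """Raised when a cell is too sparse for coverage standardization."""


@dataclass(frozen=True)
class IncidenceFrequencyTable:
    """Sampling-unit count T plus per-species incidence counts Y_i.

    ``matrix`` (species x unit boolean incidence, optional) preserves the
    raw unit composition needed for sampling-unit bootstraps.
    """

    T: int
    Y: tuple[int, ...]
    matrix: np.ndarray | None = None

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("need at least one sampling unit")
        if any(y < 1 or y > self.T for y in self.Y):
            raise ValueError("incidence counts must satisfy 1 <= Y_i <= T")
        if self.matrix is not None and self.matrix.shape != (len(self.Y), self.T):
            raise ValueError("matrix shape must be (n_species, T)")

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "IncidenceFrequencyTable":
        m = np.asarray(matrix, dtype=bool)
        y = m.sum(axis=1)
        keep = y > 0
        return cls(T=m.shape[1], Y=tuple(int(v) for v in y[keep]), matrix=m[keep])

    @classmethod
    def from_incidences(
        cls, pairs: Sequence[tuple[str, str]]
    ) -> "IncidenceFrequencyTable":
        """Build from (species, sampling_unit_id) pairs."""
        species = sorted({s for s, _ in pairs})
        units = sorted({u for _, u in pairs})
        m = np.zeros((len(species), len(units)), dtype=bool)
        s_ix = {s: i for i, s in enumerate(species)}
        u_ix = {u: j for j, u in enumerate(units)}
        for s, u in pairs:
            m[s_ix[s], u_ix[u]] = True
        return cls.from_matrix(m)

    @property
    def U(self) -> int:
        return int(sum(self.Y))

    @property
    def Q1(self) -> int:
        return sum(1 for y in self.Y if y == 1)

    @property
    def Q2(self) -> int:
        return sum(1 for y in self.Y if y == 2)

    @property
    def S_obs(self) -> int:
        return len(self.Y)


@dataclass(frozen=True)
class CoverageEstimate:
    point: float
    ci_low: float | None
    ci_high: float | None
    B: int
    seed: int | None


@dataclass(frozen=True)
class StandardizedDiversity:
    q: float
    D_q: float
    t_star: float
    mode: str  # "interpolated" | "extrapolated"
    beyond_double_reference: bool
    ci_low: float | None = None
    ci_high: float | None = None


def goods_u(table: IncidenceFrequencyTable) -> float:
    """Improved Good's u coverage estimate at the reference sample."""
    U = table.U
    if U < 1:
        raise ValueError("empty table: coverage undefined")
    Q1, Q2, T = table.Q1, table.Q2, table.T
    if Q1 == 0:
        return 1.0
    denom = (T - 1) * Q1 + 2 * Q2
    if denom == 0:
        # only reachable at T = 1: fall back to the classical estimator
        return 1.0 - Q1 / U
    return 1.0 - (Q1 / U) * ((T - 1) * Q1 / denom)


def chao2(table: IncidenceFrequencyTable) -> float:
    """Chao2 asymptotic richness (bias-corrected form when Q2 = 0)."""
    return table.S_obs + _q0_hat(table)


def _q0_hat(table: IncidenceFrequencyTable) -> float:
    T, Q1, Q2 = table.T, table.Q1, table.Q2
    if T <= 1:
        return 0.0 if Q1 == 0 else (Q1 * (Q1 - 1)) / 2.0
    factor = (T - 1) / T
    if Q2 > 0:
        return factor * Q1 * Q1 / (2.0 * Q2)
    return factor * Q1 * (Q1 - 1) / 2.0


def _subset_miss_prob(T: int, Y: np.ndarray, t: int) -> np.ndarray:
    """C(T - Y_i, t) / C(T, t) for each species, computed as the stable
    product prod_{j<Y_i}(T - t - j)/(T - j); zero when T - Y_i < t."""
    out = np.ones(len(Y), dtype=float)
    zero = (T - Y) < t
    out[zero] = 0.0
    for j in range(int(Y.max(initial=0))):
        active = (Y > j) & ~zero
        out[active] *= (T - t - j) / (T - j)
    return out


def interpolated_richness(table: IncidenceFrequencyTable, t: int) -> float:
    """Exact expected species count in a uniform random subset of t units."""
    if not 1 <= t <= table.T:
        raise ValueError(f"t must lie in [1, T={table.T}]")
    Y = np.asarray(table.Y)
    return float(table.S_obs - _subset_miss_prob(table.T, Y, t).sum())


def interpolated_coverage(table: IncidenceFrequencyTable, t: int) -> float:
    """Exact expected coverage (reference-frequency-weighted detected
    fraction) of a uniform random subset of t units.

    At the reference point t = T the improved Good's u estimate supersedes
    the naive within-sample value.
    """
    if not 1 <= t <= table.T:
        raise ValueError(f"t must lie in [1, T={table.T}]")
    if t == table.T:
        return goods_u(table)
    Y = np.asarray(table.Y)
    miss = _subset_miss_prob(table.T, Y, t)
    return float(1.0 - (Y / table.U * miss).sum())


def extrapolate(
    table: IncidenceFrequencyTable, t_extra: float
) -> tuple[float, float]:
    """(richness, coverage) at effort T + t_extra beyond the reference
    sample, anchored on the Chao2 estimate of undetected richness."""
    if t_extra < 0:
        raise ValueError("t_extra must be non-negative")
    T, Q1, Q2, U, S = table.T, table.Q1, table.Q2, table.U, table.S_obs
    if Q1 == 0:
        return float(S), 1.0
    q0 = _q0_hat(table)
    if q0 == 0.0:
        rich = float(S)
    else:
        rich = S + q0 * (1.0 - (1.0 - Q1 / (Q1 + T * q0)) ** t_extra)
    denom = (T - 1) * Q1 + 2 * Q2
    bracket = (T - 1) * Q1 / denom if denom > 0 else 0.0
    cov = 1.0 - (Q1 / U) * bracket ** (t_extra + 1)
    return float(rich), float(cov)


def bootstrap_coverage_ci(
    matrix: np.ndarray,
    B: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> CoverageEstimate:
    """Percentile bootstrap CI for improved Good's u, resampling sampling
    units (columns) with replacement."""
    table = IncidenceFrequencyTable.from_matrix(matrix)
    point = goods_u(table)
    if table.T < 2:
        return CoverageEstimate(point, None, None, 0, seed)
    rng = np.random.default_rng(seed)
    m = np.asarray(matrix, dtype=bool)
    T = m.shape[1]
    reps = np.empty(B)
    for b in range(B):
        cols = rng.integers(0, T, size=T)
        reps[b] = goods_u(IncidenceFrequencyTable.from_matrix(m[:, cols]))
    lo, hi = _recentred_interval(reps, point, alpha)
    lo, hi = max(0.0, min(lo, point)), min(1.0, max(hi, point))
    return CoverageEstimate(point, float(lo), float(hi), B, seed)


def _recentred_interval(
    reps: np.ndarray, point: float, alpha: float = 0.05
) -> tuple[float, float]:
    """Percentile interval recentred on the point estimate.

    Resampling T units with replacement duplicates units, which shifts the
    whole bootstrap distribution of coverage-standardized quantities; the
    shift is removed by translating the percentile interval so its mean
    sits at the point estimate, keeping the bootstrap's spread.
    """
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    shift = point - float(np.mean(reps))
    return float(lo + shift), float(hi + shift)


def _invert_quorum(table: IncidenceFrequencyTable, q: float) -> StandardizedDiversity:
    T = table.T
    c_ref = goods_u(table)
    if q <= c_ref:
        # interpolation: bracket q by the largest integer effort t with
        # coverage(t) <= q, then interpolate richness linearly to t + 1.
        # Efforts below one sampling unit are not meaningful, so a quorum
        # already attained at t = 1 reports the single-unit expectation.
        cov = [interpolated_coverage(table, t) for t in range(1, T + 1)]
        below = [t for t in range(1, T + 1) if cov[t - 1] <= q]
        if not below:
            return StandardizedDiversity(
                q=q, D_q=interpolated_richness(table, 1), t_star=1.0,
                mode="interpolated", beyond_double_reference=False,
            )
        t = below[-1]
        if t == T:
            return StandardizedDiversity(
                q=q, D_q=float(table.S_obs), t_star=float(T),
                mode="interpolated", beyond_double_reference=False,
            )
        c1, c2 = cov[t - 1], cov[t]
        r1 = interpolated_richness(table, t)
        r2 = interpolated_richness(table, t + 1)
        frac = 0.0 if c2 <= c1 else (q - c1) / (c2 - c1)
        return StandardizedDiversity(
            q=q, D_q=float(r1 + frac * (r2 - r1)), t_star=t + frac,
            mode="interpolated", beyond_double_reference=False,
        )
    # extrapolation: solve the closed-form coverage for the required effort
    Q1, Q2, U = table.Q1, table.Q2, table.U
    denom = (T - 1) * Q1 + 2 * Q2
    bracket = (T - 1) * Q1 / denom if denom > 0 else 0.0
    if Q1 == 0 or bracket <= 0.0 or bracket >= 1.0:
        # coverage cannot be raised by further sampling; report the asymptote
        rich = chao2(table)
        return StandardizedDiversity(
            q=q, D_q=float(rich), t_star=math.inf,
            mode="extrapolated", beyond_double_reference=True,
        )
    t_extra = math.log((1.0 - q) * U / Q1) / math.log(bracket) - 1.0
    t_extra = max(t_extra, 0.0)
    rich, _ = extrapolate(table, t_extra)
    t_star = T + t_extra
    return StandardizedDiversity(
        q=q, D_q=float(rich), t_star=float(t_star),
        mode="extrapolated", beyond_double_reference=t_star > 2 * T,
    )


def diversity_at_quorum(
    table: IncidenceFrequencyTable,
    q: float = 0.8,
    B: int = 0,
    seed: int | None = None,
    min_incidences: int = 3,
) -> StandardizedDiversity:
    """Standardized richness at target coverage q, with an optional
    sampling-unit bootstrap CI (requires the raw incidence matrix).

    Cells with fewer than ``min_incidences`` total incidences are rejected
    as non-viable: coverage estimation is meaninglessly noisy there.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("quorum must lie in (0, 1)")
    if table.U < min_incidences:
        raise NotViableError(
            f"table has {table.U} incidences; need >= {min_incidences}"
        )
    result = _invert_quorum(table, q)
    if B <= 0:
        return result
    if table.matrix is None:
        raise ValueError("bootstrap CI needs the raw incidence matrix")
    rng = np.random.default_rng(seed)
    m = table.matrix
    reps = []
    for _ in range(B):
        cols = rng.integers(0, table.T, size=table.T)
        boot = IncidenceFrequencyTable.from_matrix(m[:, cols])
        if boot.S_obs == 0 or boot.U < min_incidences:
            continue
        reps.append(_invert_quorum(boot, q).D_q)
    if len(reps) < max(20, B // 5):
        return result
    lo, hi = _recentred_interval(np.asarray(reps), result.D_q)
    return StandardizedDiversity(
        q=result.q, D_q=result.D_q, t_star=result.t_star, mode=result.mode,
        beyond_double_reference=result.beyond_double_reference,
        ci_low=float(min(lo, result.D_q)), ci_high=float(max(hi, result.D_q)),
    )
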