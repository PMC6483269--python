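"""Application graphs: imperfect drug penetration (mono- and combination
therapy), resistance routes in chronic myeloid leukemia, and bacterial
multidrug resistance.

Each builder returns an ordinary :class:`~evopaths.graph.TransitionGraph`
so the generic analytics and simulator apply unchanged; the closed-form
shortcuts exposed here are the same formulas specialised to the scenario
graph and agree with the generic pipeline to floating-point accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .analytics import (
    HittingTimeApprox,
    MedianResult,
    median_hitting_time,
    path_probability,
    time_advantage,
    weight_table,
)
from .graph import TransitionGraph, VertexParams, enumerate_paths

__all__ = [
    "MonotherapyParams",
    "CombinationParams",
    "TwoPathMDRParams",
    "build_monotherapy",
    "monotherapy_order_probability",
    "monotherapy_median",
    "SwitchDecision",
    "drug_switch_condition",
    "build_combination",
    "stepwise_paths",
    "direct_paths",
    "combination_metrics",
    "cml_analysis",
    "build_two_step_mdr",
    "mdr_two_path_analysis",
]


# ---------------------------------------------------------------------------
# monotherapy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MonotherapyParams:
    """Sanctuary wild type (alpha, beta), per-cell mutation rate nu and
    migration rate m, resistance cost s and drug cost d (both added to the
    death rate), and z initial sanctuary cells."""

    alpha: float
    beta: float
    nu: float
    m: float
    s: float
    d: float
    z: int = 1

    def __post_init__(self) -> None:
        if not (self.s > 0 and self.d > 0):
            raise ValueError("fitness costs s and d must be positive")
        if not self.lam > 0:
            raise ValueError("sanctuary growth rate alpha - beta must be positive")

    @property
    def lam(self) -> float:
        return self.alpha - self.beta


def build_monotherapy(p: MonotherapyParams) -> TransitionGraph:
    """Four-state penetration graph: sanctuary/drug compartment x
    sensitive/resistant.  Two root-to-target paths: mutation-migration
    (through the resistant sanctuary state, cost s) with weight nu*m/s,
    and migration-mutation (through the sensitive drug-compartment state,
    cost d) with weight nu*m/d."""
    a, b = p.alpha, p.beta
    vertices = [
        VertexParams("S_sensitive", a, b),
        VertexParams("S_resistant", a, b + p.s),
        VertexParams("D_sensitive", a, b + p.d),
        VertexParams("D_resistant", a, b + p.s),
    ]
    edges = [
        ("S_sensitive", "S_resistant", p.nu),
        ("S_sensitive", "D_sensitive", p.m),
        ("S_resistant", "D_resistant", p.m),
        ("D_sensitive", "D_resistant", p.nu),
    ]
    return TransitionGraph.build(vertices, edges, root="S_sensitive", target="D_resistant", z=p.z)


def monotherapy_order_probability(p: MonotherapyParams) -> float:
    """P(mutation-migration seeds resistance first) = d / (s + d)."""
    return p.d / (p.s + p.d)


def monotherapy_median(p: MonotherapyParams) -> MedianResult:
    """Median resistance time from the two-path weight total nu*m*(1/s + 1/d)."""
    phi = p.nu * p.m * (1.0 / p.s + 1.0 / p.d)
    h = HittingTimeApprox(z=p.z, alpha=p.alpha, beta=p.beta, phi_N=phi)
    return median_hitting_time(h)


@dataclass(frozen=True)
class SwitchDecision:
    switch: bool
    margin: float  # t_1/2 under drug B minus under drug A (positive favours B)
    threshold: float  # RHS of the sanctuary-size ratio condition
    limit_threshold: float  # d_B -> infinity limit (1 + s/d_A)^-1


def drug_switch_condition(
    p_a: MonotherapyParams, p_b: MonotherapyParams
) -> SwitchDecision:
    """Switch from drug A to drug B iff z_A/z_B > (1 + s/d_B)/(1 + s/d_A).

    Assumes the two regimens share s, nu, m and the wild-type rates; the
    drugs differ in efficacy d and in penetration (hence sanctuary size z).
    The margin is the median-resistance-time gain of B over A.
    """
    for attr in ("alpha", "beta", "nu", "m", "s"):
        if getattr(p_a, attr) != getattr(p_b, attr):
            raise ValueError(f"drug comparison assumes shared {attr}")
    s = p_a.s
    threshold = (1.0 + s / p_b.d) / (1.0 + s / p_a.d)
    ratio = p_a.z / p_b.z
    margin = monotherapy_median(p_b).value - monotherapy_median(p_a).value
    return SwitchDecision(
        switch=bool(ratio > threshold),
        margin=margin,
        threshold=threshold,
        limit_threshold=1.0 / (1.0 + s / p_a.d),
    )


# ---------------------------------------------------------------------------
# combination therapy
# ---------------------------------------------------------------------------

_REGIONS = ("S", "D", "DD")
_DRUGS_IN = {"S": (), "D": ("A",), "DD": ("A", "B")}
_GENOTYPES = ("00", "A", "B", "AB")
_MUTS = {"00": frozenset(), "A": frozenset("A"), "B": frozenset("B"), "AB": frozenset("AB")}


@dataclass(frozen=True)
class CombinationParams:
    """Monotherapy parameters plus region capacities.

    The drug-B penetration profile is nested inside drug A's, so the three
    regions are sanctuary (capacity n_S), drug-A-only (n_D) and double
    drug (n_DD), with n_Tot = n_S + n_D + n_DD.  The initial sanctuary
    population is z = gamma * n_S with occupancy fraction 0 < gamma << 1.
    """

    alpha: float
    beta: float
    nu: float
    m: float
    s: float
    d: float
    n_S: float
    n_D: float
    n_DD: float
    gamma: float = 1e-3

    def __post_init__(self) -> None:
        if not (self.s > 0 and self.d > 0):
            raise ValueError("fitness costs s and d must be positive")
        if not self.lam > 0:
            raise ValueError("sanctuary growth rate must be positive")
        if min(self.n_S, self.n_D, self.n_DD) <= 0:
            raise ValueError("region capacities must be positive")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")

    @property
    def lam(self) -> float:
        return self.alpha - self.beta

    @property
    def n_tot(self) -> float:
        return self.n_S + self.n_D + self.n_DD

    @property
    def z(self) -> int:
        return max(1, round(self.gamma * self.n_S))


def _state_cost(region: str, genotype: str, s: float, d: float) -> float:
    muts = _MUTS[genotype]
    unblocked = [drug for drug in _DRUGS_IN[region] if drug not in muts]
    return s * len(muts) + d * len(unblocked)


def build_combination(p: CombinationParams, geometry: str = "nested") -> TransitionGraph:
    """12-state graph: 3 regions x 4 resistance genotypes.

    Vertex labels are ``region:genotype`` (e.g. ``"D:A"``); the label's
    death-rate increment is s per resistance mutation plus d per drug
    present in the region that the cell is not resistant to.  Mutations
    (rate nu) act within a region; migration leaves a region at total rate
    m and lands in a destination with probability proportional to its
    capacity, e.g. sanctuary → double-drug at m*n_DD/(n_D + n_DD).  Back
    migrations are omitted (forward-only: S→D, S→DD, D→DD), matching the
    no-back-transition convention of the analysis.  Root ``"S:00"``,
    target ``"DD:AB"``; exactly 18 root-to-target paths (6 direct, 12
    stepwise).  Only the nested geometry is supported.
    """
    if geometry != "nested":
        raise ValueError(
            f"unsupported geometry {geometry!r}: only the nested drug-B-inside-drug-A layout is modelled"
        )
    a, b = p.alpha, p.beta
    vertices = [
        VertexParams(f"{r}:{g}", a, b + _state_cost(r, g, p.s, p.d))
        for r in _REGIONS
        for g in _GENOTYPES
    ]
    edges: list[tuple[str, str, float]] = []
    for r in _REGIONS:
        for g, nxt in (("00", "A"), ("00", "B"), ("A", "AB"), ("B", "AB")):
            edges.append((f"{r}:{g}", f"{r}:{nxt}", p.nu))
    mig = {
        ("S", "D"): p.m * p.n_D / (p.n_D + p.n_DD),
        ("S", "DD"): p.m * p.n_DD / (p.n_D + p.n_DD),
        ("D", "DD"): p.m * p.n_DD / (p.n_S + p.n_DD),
    }
    for (r1, r2), rate in mig.items():
        for g in _GENOTYPES:
            edges.append((f"{r1}:{g}", f"{r2}:{g}", rate))
    edges = [(x, y, nu) for x, y, nu in edges if x != "DD:AB"]  # target is a sink
    return TransitionGraph.build(vertices, edges, root="S:00", target="DD:AB", z=p.z)


def stepwise_paths(g: TransitionGraph) -> list:
    """Root-to-target paths passing through the single-drug region."""
    return [p for p in enumerate_paths(g) if any(str(v).startswith("D:") for v in p.seq)]


def direct_paths(g: TransitionGraph) -> list:
    """Root-to-target paths migrating straight from sanctuary to double drug."""
    return [p for p in enumerate_paths(g) if not any(str(v).startswith("D:") for v in p.seq)]


@dataclass(frozen=True)
class CombinationMetrics:
    t_half: MedianResult
    acceleration_condition: bool  # (n_S + n_D)/n_Tot > s/m
    worst_case_ratio: float  # n_D/n_S minimising the median, s << d form
    stepwise_probability_approx: float  # [1 + s(n_DD + n_S)/(m n_D)]^-1
    stepwise_probability_exact: float  # summed normalised weights, 12 paths
    most_probable_stepwise_path: tuple


def combination_metrics(p: CombinationParams) -> CombinationMetrics:
    """Median time to double resistance and the stepwise-vs-direct split.

    The closed forms hold for s << d and (n_S + n_D) << n_Tot; the exact
    counterparts are computed on the full 12-state graph so the quality of
    those limits can be inspected directly.
    """
    g = build_combination(p)
    table = weight_table(g)
    h = HittingTimeApprox.from_graph(g, table)
    sw = stepwise_paths(g)
    exact = path_probability(table, sw)
    approx = 1.0 / (1.0 + p.s * (p.n_DD + p.n_S) / (p.m * p.n_D))
    best = max(sw, key=lambda q: table.log_w[q.seq])
    return CombinationMetrics(
        t_half=median_hitting_time(h),
        acceleration_condition=bool((p.n_S + p.n_D) / p.n_tot > p.s / p.m),
        worst_case_ratio=1.0 - 2.0 * p.s * p.n_tot / (p.m * (p.n_S + p.n_D)),
        stepwise_probability_approx=approx,
        stepwise_probability_exact=exact,
        most_probable_stepwise_path=best.seq,
    )


def combination_median_curve(
    p: CombinationParams, ratios: Iterable[float]
) -> pd.DataFrame:
    """t_1/2 as a function of n_D/n_S with n_Tot and n_DD held fixed.

    For each ratio r the non-double-drug capacity n_S + n_D is split as
    n_S = (n_Tot - n_DD)/(1 + r), n_D = r * n_S, and the sanctuary is
    re-seeded via z = gamma * n_S.
    """
    rows = []
    free = p.n_tot - p.n_DD
    for r in ratios:
        n_s = free / (1.0 + r)
        q = CombinationParams(
            alpha=p.alpha, beta=p.beta, nu=p.nu, m=p.m, s=p.s, d=p.d,
            n_S=n_s, n_D=r * n_s, n_DD=p.n_DD, gamma=p.gamma,
        )
        m = combination_metrics(q)
        rows.append({"nD_over_nS": r, "t_half": m.t_half.value,
                     "stepwise_probability": m.stepwise_probability_exact})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chronic myeloid leukemia
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CMLResult:
    p_point_mutation_first: float  # single-event competition nu_pm/(nu_pm + nu_ga)
    p_point_mutation_first_adjusted: float  # survival-weighted competition
    p_point_mutation_two_step: float  # vs two sequential amplifications
    s_threshold_vs_half: float  # s above which two-step prob exceeds 1/2
    s_threshold_vs_single: float  # s above which it exceeds the single-event value


def cml_analysis(
    nu_pm: float,
    nu_ga: float,
    s: float,
    rho_pm: float = 1.0,
    rho_ga: float = 1.0,
) -> CMLResult:
    """Point mutation versus gene amplification as the route to imatinib
    resistance.

    With both routes a single transition from the root, the seeding race
    reduces to a rate competition nu_pm/(nu_pm + nu_ga).  Weighting each
    route by the average survival probability of the founded population
    (the successful-seeding rescaling nu ↦ nu * rho) gives the adjusted
    competition: point mutations win more often than not iff
    nu_pm * rho_pm > nu_ga * rho_ga.  If instead resistance by
    amplification needs two sequential amplifications, each costing s on
    the death rate, the two-step route has weight nu_ga^2/s and the
    point-mutation probability becomes nu_pm/(nu_pm + nu_ga^2/s).
    """
    if min(nu_pm, nu_ga, s) <= 0:
        raise ValueError("rates and cost must be positive")
    if not (0 <= rho_pm <= 1 and 0 <= rho_ga <= 1):
        raise ValueError("survival probabilities must lie in [0, 1]")
    plain = nu_pm / (nu_pm + nu_ga)
    wa, wb = nu_pm * rho_pm, nu_ga * rho_ga
    adjusted = wa / (wa + wb) if (wa + wb) > 0 else math.nan
    two_step = nu_pm / (nu_pm + nu_ga**2 / s)
    return CMLResult(
        p_point_mutation_first=plain,
        p_point_mutation_first_adjusted=adjusted,
        p_point_mutation_two_step=two_step,
        s_threshold_vs_half=nu_ga**2 / nu_pm,
        s_threshold_vs_single=nu_ga,  # two-step weight nu_ga^2/s below the single-event nu_ga
    )


# ---------------------------------------------------------------------------
# bacterial multidrug resistance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoPathMDRParams:
    """Two-drug, two-order resistance accumulation in a growing colony.

    ``r_1``/``r_2`` are the single-resistant strains' growth rates
    relative to the wild type (in (0, 1)), so the fitness costs are
    lam * (1 - r_i); ``nu_1``/``nu_2`` are the mutation rates toward
    resistance 1 and 2.
    """

    alpha: float
    beta: float
    nu_1: float
    nu_2: float
    r_1: float
    r_2: float
    z: int = 1

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("wild-type growth rate must be positive")
        if min(self.nu_1, self.nu_2) <= 0:
            raise ValueError("mutation rates must be positive")
        if not (0 < self.r_1 < 1 and 0 < self.r_2 < 1):
            raise ValueError("relative growth rates must lie in (0, 1)")

    @property
    def lam(self) -> float:
        return self.alpha - self.beta

    def cost(self, i: int) -> float:
        return self.lam * (1.0 - (self.r_1 if i == 1 else self.r_2))


def build_two_step_mdr(p: TwoPathMDRParams) -> TransitionGraph:
    """Diamond graph: wild type → single-resistant (1 or 2) → double
    resistant, with mutation rates crossed over the two orders."""
    a, b, lam = p.alpha, p.beta, p.lam
    vertices = [
        VertexParams("wt", a, b),
        VertexParams("res1", a, b + p.cost(1)),
        VertexParams("res2", a, b + p.cost(2)),
        VertexParams("res12", a, b + p.cost(1) + p.cost(2)),
    ]
    edges = [
        ("wt", "res1", p.nu_1),
        ("wt", "res2", p.nu_2),
        ("res1", "res12", p.nu_2),
        ("res2", "res12", p.nu_1),
    ]
    return TransitionGraph.build(vertices, edges, root="wt", target="res12", z=p.z)


@dataclass(frozen=True)
class MDRResult:
    p_first_order: float  # P(resistance 1 acquired before resistance 2)
    p_hit_by_t: float  # P(T <= t), symmetric-cost closed form
    mu: float
    relative_probability: float  # lineage comparison P(T_a <= t)/P(T_b <= t)
    small_time_limit: float  # limiting ratio nu_1a*nu_2a/(nu_1b*nu_2b)
    limit_form_valid: bool


def mdr_two_path_analysis(
    p: TwoPathMDRParams,
    t: float,
    lineage_rates: tuple[tuple[float, float], tuple[float, float]] | None = None,
    s: float | None = None,
) -> MDRResult:
    """Order of resistance acquisition and the time to double resistance.

    The order probability follows from the seeding race between the two
    length-2 paths: the path through strain 1 has weight
    nu_1 nu_2 / cost(1), so P(order 1 first) = cost(2)/(cost(1)+cost(2))
    — the mutation rates cancel.  The time law uses the symmetric-cost
    total weight phi = 2 nu_1 nu_2 / s (``s`` defaults to the mean of the
    two costs).  ``lineage_rates`` optionally gives ((nu_1, nu_2) for two
    strains/lineages) whose relative probability of resistance by time t
    is reported, together with its small-time limit — valid only while
    nu_1 nu_2 e^{lam t} << 1, which is flagged.
    """
    c1, c2 = p.cost(1), p.cost(2)
    order = c2 / (c1 + c2)
    s_eff = s if s is not None else 0.5 * (c1 + c2)
    phi = 2.0 * p.nu_1 * p.nu_2 / s_eff
    h = HittingTimeApprox(z=p.z, alpha=p.alpha, beta=p.beta, phi_N=phi)
    lam = p.lam
    u = math.exp(min(lam * (t - h.mu), 709.0))
    p_hit = 1.0 - ((lam / p.alpha) / (1.0 + u) + p.beta / p.alpha)

    valid = p.nu_1 * p.nu_2 * math.exp(lam * t) < 1e-2
    if lineage_rates is None:
        rel = 1.0
        limit = 1.0
    else:
        (na1, na2), (nb1, nb2) = lineage_rates
        ka = 2.0 * na1 * na2 * math.exp(lam * t) * p.alpha / (lam**2 * s_eff)
        kb = 2.0 * nb1 * nb2 * math.exp(lam * t) * p.alpha / (lam**2 * s_eff)
        rel = (na1 * na2) / (nb1 * nb2) * (1.0 + kb) / (1.0 + ka)
        limit = (na1 * na2) / (nb1 * nb2)
    return MDRResult(
        p_first_order=order,
        p_hit_by_t=p_hit,
        mu=h.mu,
        relative_probability=rel,
        small_time_limit=limit,
        limit_form_valid=valid,
    )
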