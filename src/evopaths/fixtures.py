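"""Canonical example graphs and seeded random fixtures.

The named builders reproduce the worked systems used throughout the
documentation and tests: a 4-vertex path graph (sequential mutation
accumulation), the two-path fitness-valley system, a small cyclic system
where a walk can out-compete a path, and the drug-penetration scenarios.
``random_dag`` draws reproducible layered DAGs that always satisfy the
root-fittest assumption, for property testing.
"""

from __future__ import annotations

import numpy as np

from .graph import TransitionGraph, VertexParams
from .scenarios import (
    CombinationParams,
    MonotherapyParams,
    build_combination,
    build_monotherapy,
)

__all__ = [
    "path_graph",
    "standard_path_graph",
    "valley_graph",
    "cycle_graph",
    "random_dag",
    "make_fixture",
    "FIXTURE_KINDS",
]


def path_graph(
    n: int,
    alphas: list[float],
    betas: list[float],
    nus: list[float],
    z: int = 1,
) -> TransitionGraph:
    """Path graph 1 → 2 → ... → n with explicit rates."""
    if not (len(alphas) == len(betas) == n and len(nus) == n - 1):
        raise ValueError("need n alphas/betas and n-1 edge rates")
    vertices = [VertexParams(i + 1, alphas[i], betas[i]) for i in range(n)]
    edges = [(i + 1, i + 2, nus[i]) for i in range(n - 1)]
    return TransitionGraph.build(vertices, edges, root=1, target=n, z=z)


def standard_path_graph(nu: float = 0.05, z: int = 1) -> TransitionGraph:
    """The standard 4-vertex path-graph example: alpha = 1 everywhere,
    beta = 0.4 at the root, 1.3 at the two intermediates, 0.6 at the
    target, and a common transition rate nu."""
    return path_graph(
        4,
        alphas=[1.0, 1.0, 1.0, 1.0],
        betas=[0.4, 1.3, 1.3, 0.6],
        nus=[nu, nu, nu],
        z=z,
    )


def valley_graph(
    alpha: float = 0.9,
    beta: float = 0.3,
    alpha2: float = 0.2,
    beta2: float = 0.4,
    nu: float = 0.1,
    z: int = 1,
) -> TransitionGraph:
    """Two competing routes to the target: an indirect path (1, 2, 3)
    through a fitness valley (lam(2) < 0 by default) with per-edge rate
    nu, and a direct edge (1, 3) at rate nu^2.  The target inherits the
    root's division/death rates (its fitness is unconstrained)."""
    vertices = [
        VertexParams(1, alpha, beta),
        VertexParams(2, alpha2, beta2),
        VertexParams(3, alpha, beta),
    ]
    edges = [(1, 2, nu), (2, 3, nu), (1, 3, nu * nu)]
    return TransitionGraph.build(vertices, edges, root=1, target=3, z=z)


def cycle_graph(
    nu1: float = 0.01,
    nu2: float = 0.3,
    nu_out: float = 0.01,
    beta2: float = 1.1,
    beta3: float = 1.2,
) -> TransitionGraph:
    """Four vertices with a 2↔3 cycle: edges (1,2) at nu1, (2,3) and
    (3,2) at nu2, (2,4) at nu_out.  The walk (1,2,3,2,4) competes with
    the path (1,2,4) when nu2 is large."""
    vertices = [
        VertexParams(1, 1.0, 0.4),
        VertexParams(2, 1.0, beta2),
        VertexParams(3, 1.0, beta3),
        VertexParams(4, 1.0, 0.6),
    ]
    edges = [(1, 2, nu1), (2, 3, nu2), (3, 2, nu2), (2, 4, nu_out)]
    return TransitionGraph.build(vertices, edges, root=1, target=4, z=1)


def random_dag(
    n: int,
    density: float = 0.5,
    seed: int = 0,
    rate_bounds: tuple[float, float] = (1e-3, 1e-1),
) -> TransitionGraph:
    """Seeded random DAG on vertices 1..n (root 1, target n).

    The chain 1 → 2 → ... → n is always present (so the target is
    reachable); every other forward pair gains an edge with probability
    ``density``.  Edge rates are log-uniform within ``rate_bounds``;
    intermediate vertices draw death rates above the root's so the
    root-fittest assumption always holds.
    """
    if n < 2:
        raise ValueError("need at least root and target")
    rng = np.random.default_rng(seed)
    alpha, beta_root = 1.0, 0.4
    lam = alpha - beta_root
    vertices = [VertexParams(1, alpha, beta_root)]
    for i in range(2, n):
        # beta in (beta_root, alpha + 1): growth rate strictly below root's
        vertices.append(VertexParams(i, alpha, float(beta_root + rng.uniform(0.05, 1.0 + lam))))
    vertices.append(VertexParams(n, alpha, float(rng.uniform(0.0, 1.0))))

    lo, hi = np.log(rate_bounds[0]), np.log(rate_bounds[1])

    def draw_rate() -> float:
        return float(np.exp(rng.uniform(lo, hi)))

    edges = [(i, i + 1, draw_rate()) for i in range(1, n)]
    for i in range(1, n):
        for j in range(i + 2, n + 1):
            if rng.random() < density:
                edges.append((i, j, draw_rate()))
    return TransitionGraph.build(vertices, edges, root=1, target=n, z=1)


FIXTURE_KINDS = (
    "path_graph",
    "valley",
    "cycle_walk",
    "monotherapy",
    "combination",
    "random_dag",
)


def make_fixture(kind: str, seed: int = 0, **params) -> TransitionGraph:
    """Dispatch by fixture kind (see :data:`FIXTURE_KINDS`)."""
    if kind == "path_graph":
        n = int(params.pop("n", 4))
        if n == 4 and not params:
            return standard_path_graph()
        return path_graph(n, **params) if params else standard_path_graph()
    if kind == "valley":
        return valley_graph(**params)
    if kind == "cycle_walk":
        return cycle_graph(**params)
    if kind == "monotherapy":
        defaults = dict(alpha=1.0, beta=0.4, nu=1e-6, m=0.05, s=5e-3, d=1e-2, z=100)
        defaults.update(params)
        return build_monotherapy(MonotherapyParams(**defaults))
    if kind == "combination":
        n_tot = float(params.pop("n_tot", 1e7))
        defaults = dict(
            alpha=0.7, beta=0.3, nu=1e-6, m=0.05, s=1e-3, d=0.9,
            n_S=0.05 * n_tot, n_D=0.05 * n_tot, n_DD=0.9 * n_tot, gamma=1e-3,
        )
        defaults.update(params)
        return build_combination(CombinationParams(**defaults))
    if kind == "random_dag":
        return random_dag(int(params.pop("n", 6)), seed=seed, **params)
    raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
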