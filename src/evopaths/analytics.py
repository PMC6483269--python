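"""Small-transition-rate analytics: path weights, hitting-time laws,
medians, and the distribution over seeding paths.

The central object is the weight of a root-to-target sequence
(path or walk) p = (p_1, ..., p_{l+1}),

    w(p) = nu(p_1, p_2) * prod_{i=2..l} nu(p_i, p_{i+1}) / (lam - lam(p_i)),

the product of transition rates along p divided by the fitness costs
``lam - lam(p_i)`` of its internal vertices (empty product = 1).  In the
limit of small target-seeding rates:

* the target hitting time T satisfies
  P(T > t) ≈ ((lam/alpha) / (1 + e^{lam t} phi_N alpha / lam^2) + beta/alpha)^z
  with phi_N the total weight of the target;
* the probability that a given path seeds the target is w(p) / phi_N;
* exp(-lam t) Z_x(t) → W * Phi_x almost surely, with W a binomial-Erlang
  mixture and Phi_x = phi_x / (lam - lam(x)).

All weights are computed and accumulated in log space (application rates
span 1e-8 .. 1e-1); linear values are exposed on demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .graph import PathSeq, TransitionGraph, VertexId, enumerate_paths

__all__ = [
    "sequence_weight",
    "sequence_log_weight",
    "WeightTable",
    "weight_table",
    "HittingTimeApprox",
    "hitting_survival",
    "conditional_hitting",
    "median_hitting_time",
    "MedianResult",
    "path_probability",
    "time_advantage",
    "sample_W",
]


def _as_seq(p) -> tuple[VertexId, ...]:
    return tuple(p.seq) if isinstance(p, PathSeq) else tuple(p)


def sequence_log_weight(g: TransitionGraph, p: PathSeq | Sequence[VertexId]) -> float:
    """log w(p) for a path or walk in ``g`` starting at the root.

    Internal vertices (counted with repeats for walks) must have growth
    rate strictly below the root's, else the weight is undefined in the
    small-rate regime and a ValueError is raised.
    """
    seq = _as_seq(p)
    if len(seq) < 2:
        raise ValueError("sequence needs at least one edge")
    lam = g.root_lam
    log_w = 0.0
    for x, y in zip(seq, seq[1:]):
        if (x, y) not in g.edges:
            raise ValueError(f"({x!r}, {y!r}) is not an edge of the graph")
        log_w += math.log(g.nu(x, y))
    for v in seq[1:-1]:
        cost = lam - g.lam(v)
        if cost <= 0:
            raise ValueError(
                f"internal vertex {v!r} has growth rate {g.lam(v)} >= root's {lam}; "
                "weight undefined in the small-rate regime"
            )
        log_w -= math.log(cost)
    return log_w


def sequence_weight(g: TransitionGraph, p: PathSeq | Sequence[VertexId]) -> float:
    """w(p); see :func:`sequence_log_weight`."""
    return math.exp(sequence_log_weight(g, p))


@dataclass(frozen=True)
class WeightTable:
    """Weights of root-to-target sequences plus per-vertex totals.

    ``log_w`` maps each sequence to log w(p); ``log_phi`` maps each
    non-target vertex x to log phi_x = log sum of weights of root-to-x
    paths; ``Phi`` holds Phi_x = phi_x / (lam - lam(x)) with Phi_root = 1.
    """

    graph: TransitionGraph
    sequences: tuple[PathSeq, ...]
    log_w: Mapping[tuple[VertexId, ...], float]
    log_phi: Mapping[VertexId, float]
    Phi: Mapping[VertexId, float]

    @property
    def log_phi_target(self) -> float:
        return logsumexp([self.log_w[s.seq] for s in self.sequences])

    @property
    def phi_target(self) -> float:
        return float(math.exp(self.log_phi_target))

    def weight(self, p) -> float:
        return math.exp(self.log_w[_as_seq(p)])

    def phi(self, x: VertexId) -> float:
        return float(math.exp(self.log_phi[x]))


def weight_table(
    g: TransitionGraph,
    sequences: Iterable[PathSeq] | None = None,
) -> WeightTable:
    """Build the weight table for ``g``.

    ``sequences`` defaults to all simple root→target paths; a finite walk
    set may be supplied instead (cyclic extension).  phi_x totals are
    always over simple root→x paths.  Raises if the target set is empty.
    """
    seqs = tuple(sequences) if sequences is not None else tuple(enumerate_paths(g))
    if not seqs:
        raise ValueError("no root-to-target sequences: target unreachable")
    for s in seqs:
        if s.seq[0] != g.root or s.seq[-1] != g.target:
            raise ValueError(f"sequence {s.seq} is not root-to-target")
    log_w = {s.seq: sequence_log_weight(g, s) for s in seqs}

    lam = g.root_lam
    log_phi: dict[VertexId, float] = {}
    Phi: dict[VertexId, float] = {g.root: 1.0}
    for x in g.vertices:
        if x == g.target or x == g.root:
            continue
        paths_to_x = enumerate_paths(g, g.root, x)
        if not paths_to_x:
            continue  # unreachable intermediate: no weight entries
        log_phi[x] = float(logsumexp([sequence_log_weight(g, p) for p in paths_to_x]))
        cost = lam - g.lam(x)
        if cost > 0:
            Phi[x] = math.exp(log_phi[x] - math.log(cost))
    return WeightTable(graph=g, sequences=seqs, log_w=log_w, log_phi=log_phi, Phi=Phi)


@dataclass(frozen=True)
class HittingTimeApprox:
    """Parameters of the approximate target-hitting-time law.

    Only root-vertex parameters (z, alpha, beta) and the total target
    weight phi_N enter; everything else about the graph is bundled into
    phi_N.  ``mu`` is the time-centring constant
    (1/lam) log(lam^2 / (alpha phi_N)).
    """

    z: int
    alpha: float
    beta: float
    phi_N: float

    def __post_init__(self) -> None:
        if not self.phi_N > 0:
            raise ValueError(f"phi_N must be positive, got {self.phi_N}")
        if not self.lam > 0:
            raise ValueError("root growth rate must be positive")
        if self.z < 1:
            raise ValueError("z must be a positive integer")

    @property
    def lam(self) -> float:
        return self.alpha - self.beta

    @property
    def mu(self) -> float:
        return math.log(self.lam**2 / (self.alpha * self.phi_N)) / self.lam

    @property
    def extinction_atom(self) -> float:
        """(beta/alpha)^z — probability the target is never reached."""
        return (self.beta / self.alpha) ** self.z

    @property
    def ever_hit(self) -> float:
        """P(T < infinity) ≈ 1 - (beta/alpha)^z."""
        return 1.0 - self.extinction_atom

    @property
    def h_z(self) -> float:
        """Asymptotic initial-size shift: h(1) = 0, h(z) ~ (1/lam) log(z lam/alpha)."""
        if self.z == 1:
            return 0.0
        return math.log(self.z * self.lam / self.alpha) / self.lam

    @classmethod
    def from_graph(cls, g: TransitionGraph, table: WeightTable | None = None) -> "HittingTimeApprox":
        table = weight_table(g) if table is None else table
        return cls(z=g.z, alpha=g.alpha(g.root), beta=g.beta(g.root), phi_N=table.phi_target)


def hitting_survival(h: HittingTimeApprox, t) -> np.ndarray | float:
    """P(T > t) ≈ ((lam/alpha)/(1 + e^{lam t} phi_N alpha/lam^2) + beta/alpha)^z.

    Identical to the limit law ((lam/alpha)/(1+e^{lam s}) + beta/alpha)^z
    evaluated at s = t - mu, since e^{lam mu} = lam^2/(alpha phi_N).
    Handles t = ±inf via limits: 1 and (beta/alpha)^z respectively.
    """
    t_arr = np.asarray(t, dtype=float)
    lam, a, b = h.lam, h.alpha, h.beta
    # exp(lam*t)*phi*a/lam^2 = exp(lam*(t-mu)), computed in log space
    u = np.exp(np.clip(lam * (t_arr - h.mu), -745.0, 709.0))
    s = ((lam / a) / (1.0 + u) + b / a) ** h.z
    s = np.where(np.isneginf(t_arr), 1.0, s)
    s = np.where(np.isposinf(t_arr), (b / a) ** h.z, s)
    return float(s) if np.isscalar(t) or np.ndim(t) == 0 else s


def conditional_hitting(h: HittingTimeApprox, t) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Survival and density of T conditioned on the root population surviving.

    Built from the unconditional law by removing the extinction atom:
    (S(t)^... - (b/a)^z) / (1 - (b/a)^z) with S the per-lineage survival
    factor; for z = 1 this is the logistic 1/(1 + e^{lam (t - mu)}).
    Requires beta < alpha (else the conditioning event is null).
    """
    if h.beta >= h.alpha:
        raise ValueError("conditioning on survival requires beta < alpha")
    t_arr = np.asarray(t, dtype=float)
    lam, a, b, z = h.lam, h.alpha, h.beta, h.z
    atom = (b / a) ** z
    x = np.clip(lam * (t_arr - h.mu), -745.0, 709.0)
    u = np.exp(x)
    S1 = (lam / a) / (1.0 + u) + b / a  # per-lineage survival factor
    surv = (S1**z - atom) / (1.0 - atom)
    # d/dt S1 = -(lam/a) * lam*u/(1+u)^2, evaluated in log space for stability
    dS1 = (lam / a) * lam * np.exp(x - 2.0 * np.logaddexp(0.0, x))
    dens = z * S1 ** (z - 1) * dS1 / (1.0 - atom)
    surv = np.where(np.isneginf(t_arr), 1.0, surv)
    surv = np.where(np.isposinf(t_arr), 0.0, surv)
    dens = np.where(np.isinf(t_arr), 0.0, dens)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(surv), float(dens)
    return surv, dens


@dataclass(frozen=True)
class MedianResult:
    value: float
    regime: str  # "z=1 (exact mu)" or "large-z asymptotic"

    def __float__(self) -> float:
        return self.value


def median_hitting_time(h: HittingTimeApprox) -> MedianResult:
    """Approximate median of T given survival: t_1/2 ≈ mu - h(z).

    For z = 1 the shift vanishes and the median is exactly mu (of the
    approximate law).  For z > 1 the large-z form
    t_1/2 ≈ (1/lam) log(lam / (z phi_N)) is used; for small z > 1 this is
    a documented approximation (the exact shift is not implemented) and
    the regime string says which branch was taken.
    """
    if h.z == 1:
        return MedianResult(h.mu, "z=1 (exact mu)")
    value = math.log(h.lam / (h.z * h.phi_N)) / h.lam
    return MedianResult(value, "large-z asymptotic")


def path_probability(table: WeightTable, p) -> float:
    """P(target seeded via p) ≈ w(p) / phi_N; ``p`` may be a single
    sequence or an iterable of sequences (summed normalised weight)."""
    if isinstance(p, PathSeq) or (
        isinstance(p, (tuple, list)) and p and not isinstance(p[0], (PathSeq, tuple, list))
    ):
        keys = [_as_seq(p)]
    else:
        keys = [_as_seq(q) for q in p]
    for k in keys:
        if k not in table.log_w:
            raise KeyError(f"sequence {k} not in weight table")
    log_tot = table.log_phi_target
    return float(np.exp(logsumexp([table.log_w[k] for k in keys]) - log_tot))


def time_advantage(table: WeightTable, p, t: float) -> float:
    """P(T(not p) - T(p) > t) ≈ w(p) / (w(p) + e^{lam t} sum_{q != p} w(q)).

    At t = 0 this reduces to :func:`path_probability`.  The table's
    sequence set defines the competing collection (paths by default, or a
    finite walk set in the cyclic extension).
    """
    key = _as_seq(p)
    if key not in table.log_w:
        raise KeyError(f"sequence {key} not in weight table")
    lam = table.graph.root_lam
    others = [lw for k, lw in table.log_w.items() if k != key]
    if not others:
        return 1.0
    log_wp = table.log_w[key]
    log_rest = logsumexp(others) + lam * t
    return float(np.exp(log_wp - np.logaddexp(log_wp, log_rest)))


def sample_W(
    z: int,
    alpha: float,
    beta: float,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw n i.i.d. copies of the almost-sure growth limit W.

    W is the sum of K independent Exponential(lam/alpha) variables with
    K ~ Binomial(z, lam/alpha); equivalently Erlang with binomial shape.
    E[W] = z and P(W = 0) = (beta/alpha)^z.  Requires lam = alpha - beta > 0.
    """
    lam = alpha - beta
    if not lam > 0:
        raise ValueError(f"growth rate alpha - beta = {lam} must be positive")
    if z < 0:
        raise ValueError("z must be a non-negative integer")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if z == 0:
        return np.zeros(n)
    k = rng.binomial(z, lam / alpha, size=n)
    return rng.gamma(shape=k.astype(float), scale=alpha / lam)
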