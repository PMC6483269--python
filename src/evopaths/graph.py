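"""State graphs for multitype branching processes.

A growing cell population is modelled on a finite simple directed graph
G = (V, E).  Each vertex is a cell state (genotype, spatial compartment,
or both) carrying a division rate ``alpha`` and a death rate ``beta``;
each directed edge (x, y) carries a transition rate ``nu`` at which a
vertex-x cell produces a vertex-y cell alongside itself.  The process
starts with ``z`` cells at a distinguished *root* vertex and the quantity
of interest is the first arrival of a cell at a distinguished *target*
vertex, which must be a sink.  The analytic machinery in
:mod:`evopaths.analytics` assumes the root has the strictly highest
growth rate ``lam = alpha - beta`` among non-target vertices; this module
flags (but does not forbid) violations of that modelling assumption.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Hashable, Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

VertexId = Hashable

__all__ = [
    "VertexParams",
    "TransitionGraph",
    "PathSeq",
    "FitnessMixture",
    "Violation",
    "GraphStructureError",
    "PathCountExceeded",
    "validate_graph",
    "enumerate_paths",
    "enumerate_walks",
    "expand_fitness_distribution",
    "successful_seeding_adjustment",
    "rate_matrix_and_eigencheck",
    "EigenCheck",
]


class GraphStructureError(ValueError):
    """A graph cannot be built or used because of a structural defect."""


class PathCountExceeded(RuntimeError):
    """Path/walk enumeration exceeded the configured cap."""


@dataclass(frozen=True)
class VertexParams:
    """Per-state cell rates: division ``alpha``, death ``beta`` (per unit time)."""

    id: VertexId
    alpha: float
    beta: float

    @property
    def lam(self) -> float:
        """Growth rate alpha - beta (never stored independently)."""
        return self.alpha - self.beta


@dataclass(frozen=True)
class PathSeq:
    """An ordered vertex sequence from one vertex to another.

    ``kind`` is ``"path"`` when all entries are distinct and ``"walk"``
    when revisits are allowed; in both cases consecutive entries must
    differ (the vertex-lineage convention).
    """

    seq: tuple[VertexId, ...]
    kind: str = "path"

    def __post_init__(self) -> None:
        if self.kind not in ("path", "walk"):
            raise ValueError(f"kind must be 'path' or 'walk', got {self.kind!r}")
        if len(self.seq) < 1:
            raise ValueError("empty sequence")
        for a, b in zip(self.seq, self.seq[1:]):
            if a == b:
                raise ValueError(f"consecutive repeat {a!r} in sequence")
        if self.kind == "path" and len(set(self.seq)) != len(self.seq):
            raise ValueError("kind='path' requires all vertices distinct")
        object.__setattr__(self, "seq", tuple(self.seq))

    @property
    def length(self) -> int:
        """Number of edges."""
        return len(self.seq) - 1

    @property
    def internal(self) -> tuple[VertexId, ...]:
        """Vertices strictly between the endpoints (with repeats, for walks)."""
        return self.seq[1:-1]

    def __iter__(self) -> Iterator[VertexId]:
        return iter(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FitnessMixture:
    """Finite distribution of fitness effects for one intermediate vertex.

    Each component is (alpha_i, beta_i, pi_i); a transitioning cell adopts
    component i's rates with probability pi_i.  Both alpha and beta are
    required (not just the growth rate): two states with equal growth rate
    but different turnover have different stochastic behaviour.
    """

    components: tuple[tuple[float, float, float], ...]
    target_vertex: VertexId
    prob_tol: float = 1e-12

    def __post_init__(self) -> None:
        comps = tuple((float(a), float(b), float(p)) for a, b, p in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValueError("mixture needs at least one component")
        total = math.fsum(p for _, _, p in comps)
        if abs(total - 1.0) > self.prob_tol:
            raise ValueError(f"mixture probabilities sum to {total}, not 1")
        if any(p <= 0 for _, _, p in comps):
            raise ValueError("mixture probabilities must be positive")


def _sort_key(seq: Sequence[VertexId]):
    return tuple((type(v).__name__, str(v)) for v in seq)


def _sorted_ids(ids: Iterable[VertexId]) -> list[VertexId]:
    return sorted(ids, key=lambda v: (type(v).__name__, str(v)))


@dataclass(frozen=True)
class TransitionGraph:
    """The full model: vertices with rates, directed rate-carrying edges,
    a root (source), a target (sink) and an initial root cell count ``z``."""

    vertices: dict[VertexId, VertexParams]
    edges: dict[tuple[VertexId, VertexId], float]
    root: VertexId
    target: VertexId
    z: int = 1

    @classmethod
    def build(
        cls,
        vertices: Iterable[VertexParams | tuple],
        edges: Iterable[tuple[VertexId, VertexId, float]],
        root: VertexId,
        target: VertexId,
        z: int = 1,
    ) -> "TransitionGraph":
        vparams: dict[VertexId, VertexParams] = {}
        for v in vertices:
            vp = v if isinstance(v, VertexParams) else VertexParams(*v)
            if vp.id in vparams:
                raise GraphStructureError(f"duplicate vertex id {vp.id!r}")
            vparams[vp.id] = vp
        emap: dict[tuple[VertexId, VertexId], float] = {}
        for x, y, nu in edges:
            if (x, y) in emap:
                raise GraphStructureError(f"parallel edge ({x!r}, {y!r})")
            emap[(x, y)] = float(nu)
        return cls(vertices=vparams, edges=emap, root=root, target=target, z=int(z))

    # -- convenience accessors -------------------------------------------------

    def alpha(self, x: VertexId) -> float:
        return self.vertices[x].alpha

    def beta(self, x: VertexId) -> float:
        return self.vertices[x].beta

    def lam(self, x: VertexId) -> float:
        return self.vertices[x].lam

    @property
    def root_lam(self) -> float:
        return self.vertices[self.root].lam

    def nu(self, x: VertexId, y: VertexId) -> float:
        return self.edges[(x, y)]

    def out_edges(self, x: VertexId) -> list[tuple[VertexId, float]]:
        return [(y, nu) for (u, y), nu in self.edges.items() if u == x]

    def in_edges(self, y: VertexId) -> list[tuple[VertexId, float]]:
        return [(x, nu) for (x, v), nu in self.edges.items() if v == y]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for v in self.vertices.values():
            g.add_node(v.id, alpha=v.alpha, beta=v.beta)
        for (x, y), nu in self.edges.items():
            g.add_edge(x, y, nu=nu)
        return g

    @property
    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def with_edges(self, edges: dict[tuple[VertexId, VertexId], float]) -> "TransitionGraph":
        return replace(self, edges=dict(edges))


@dataclass(frozen=True)
class Violation:
    severity: str  # "error" (structural) or "warning" (model assumption)
    code: str
    message: str


def validate_graph(g: TransitionGraph) -> list[Violation]:
    """Check structural and model-assumption invariants; never mutates ``g``.

    Structural defects (bad ids, non-sink target, non-source root,
    unreachable target, non-positive rates, ...) come back with severity
    ``"error"``; violations of the analytic regime (an intermediate vertex
    at least as fit as the root, a non-growing root) come back as
    ``"warning"`` — the simulator still runs on such graphs but the
    small-rate formulas are outside their proven regime.
    """
    out: list[Violation] = []

    def err(code: str, msg: str) -> None:
        out.append(Violation("error", code, msg))

    def warn(code: str, msg: str) -> None:
        out.append(Violation("warning", code, msg))

    ids = set(g.vertices)
    for x, y in g.edges:
        if x not in ids or y not in ids:
            err("dangling-edge", f"edge ({x!r}, {y!r}) references unknown vertex")
        if x == y:
            err("self-loop", f"self-loop at {x!r}")
    for (x, y), nu in g.edges.items():
        if not nu > 0:
            err("nonpositive-rate", f"edge ({x!r}, {y!r}) has rate {nu} (zero-rate edges must be omitted)")
    for v in g.vertices.values():
        if v.alpha < 0 or v.beta < 0:
            err("negative-rate", f"vertex {v.id!r} has negative alpha/beta")
    if g.root not in ids:
        err("missing-root", f"root {g.root!r} is not a vertex")
    if g.target not in ids:
        err("missing-target", f"target {g.target!r} is not a vertex")
    if g.z < 1:
        err("bad-initial-count", f"initial count z={g.z} must be a positive integer")
    if out and any(v.code in ("missing-root", "missing-target", "dangling-edge") for v in out):
        return out

    if any(x == g.target for (x, _y) in g.edges):
        err("target-not-sink", "target has outgoing edges; it must be a sink")
    if any(y == g.root for (_x, y) in g.edges):
        err("root-not-source", "root has incoming edges; it must be a source")
    nxg = g.to_networkx()
    if g.root in nxg and g.target in nxg and not nx.has_path(nxg, g.root, g.target):
        err("target-unreachable", "no directed path from root to target")

    lam_root = g.root_lam
    if not lam_root > 0:
        warn("root-not-growing", f"root growth rate {lam_root} is not positive")
    for v in g.vertices.values():
        if v.id in (g.root, g.target):
            continue  # target fitness deliberately unconstrained
        if v.lam >= lam_root:
            warn(
                "intermediate-fitness",
                f"intermediate vertex {v.id!r} has growth rate {v.lam} >= root's {lam_root}; "
                "small-rate approximations assume strict inequality",
            )
    return out


def require_valid(g: TransitionGraph) -> None:
    """Raise GraphStructureError on the first structural error."""
    errors = [v for v in validate_graph(g) if v.severity == "error"]
    if errors:
        raise GraphStructureError("; ".join(v.message for v in errors))


def enumerate_paths(
    g: TransitionGraph,
    source: VertexId | None = None,
    to: VertexId | None = None,
    max_paths: int = 100_000,
) -> list[PathSeq]:
    """All simple paths from ``source`` to ``to``, lexicographic by vertex ids.

    Defaults to root → target.  Returns [] when no path exists.  Raises
    :class:`PathCountExceeded` beyond ``max_paths`` (combinatorial guard).
    """
    source = g.root if source is None else source
    to = g.target if to is None else to
    if source == to:
        return [PathSeq((source,), kind="path")]
    nxg = g.to_networkx()
    paths: list[tuple[VertexId, ...]] = []
    for p in nx.all_simple_paths(nxg, source, to):
        paths.append(tuple(p))
        if len(paths) > max_paths:
            raise PathCountExceeded(f"more than {max_paths} simple paths {source!r}->{to!r}")
    paths.sort(key=_sort_key)
    return [PathSeq(p, kind="path") for p in paths]


def enumerate_walks(
    g: TransitionGraph,
    source: VertexId | None = None,
    to: VertexId | None = None,
    max_len: int = 6,
    max_walks: int = 100_000,
) -> list[PathSeq]:
    """All walks of length <= ``max_len`` with no immediate backtrack
    (q_i != q_{i+1}), sorted by (length, lexicographic).  Simple paths of
    admissible length are included.  Self-loops cannot occur (simple
    digraph), so every edge-walk automatically satisfies the no-repeat
    rule; cycles through >=2 vertices are allowed.
    """
    source = g.root if source is None else source
    to = g.target if to is None else to
    shortest = _shortest_path_len(g, source, to)
    if shortest is None:
        return []
    if max_len < shortest:
        warnings.warn(
            f"max_len={max_len} below shortest path length {shortest}; no walks returned",
            stacklevel=2,
        )
        return []
    adj: dict[VertexId, list[VertexId]] = {v: [] for v in g.vertices}
    for x, y in g.edges:
        adj[x].append(y)
    for v in adj:
        adj[v] = _sorted_ids(adj[v])

    walks: list[tuple[VertexId, ...]] = []
    stack: list[tuple[VertexId, ...]] = [(source,)]
    while stack:
        w = stack.pop()
        last = w[-1]
        if last == to:
            walks.append(w)
            if len(walks) > max_walks:
                raise PathCountExceeded(f"more than {max_walks} walks")
            continue  # target is a sink; nothing extends past it
        if len(w) - 1 >= max_len:
            continue
        for y in adj[last]:
            stack.append(w + (y,))
    walks.sort(key=lambda w: (len(w), _sort_key(w)))
    return [
        PathSeq(w, kind="path" if len(set(w)) == len(w) else "walk") for w in walks
    ]


def _shortest_path_len(g: TransitionGraph, source: VertexId, to: VertexId) -> int | None:
    try:
        return nx.shortest_path_length(g.to_networkx(), source, to)
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return None


def expand_fitness_distribution(g: TransitionGraph, mix: FitnessMixture) -> TransitionGraph:
    """Replace one intermediate vertex by one vertex per mixture component.

    A transition into the original vertex y at rate nu becomes transitions
    into the new vertices at rates nu * pi_i; outgoing edges of y are
    copied to every new vertex unchanged.  New ids are ``f"{y}:{i}"`` with
    i = 1..k.  The input graph is not modified.
    """
    y = mix.target_vertex
    if y not in g.vertices:
        raise GraphStructureError(f"vertex {y!r} not in graph")
    if y in (g.root, g.target):
        raise GraphStructureError("cannot expand the root or the target vertex")
    new_ids = [f"{y}:{i + 1}" for i in range(len(mix.components))]
    clash = set(new_ids) & set(g.vertices)
    if clash:
        raise GraphStructureError(f"expansion ids already present: {sorted(clash)}")

    vertices = [vp for vid, vp in g.vertices.items() if vid != y]
    vertices += [
        VertexParams(nid, a, b) for nid, (a, b, _p) in zip(new_ids, mix.components)
    ]
    edges: list[tuple[VertexId, VertexId, float]] = []
    for (x, v), nu in g.edges.items():
        if v == y:
            edges += [
                (x, nid, nu * p) for nid, (_a, _b, p) in zip(new_ids, mix.components)
            ]
        elif x == y:
            edges += [(nid, v, nu) for nid in new_ids]
        else:
            edges.append((x, v, nu))
    return TransitionGraph.build(vertices, edges, root=g.root, target=g.target, z=g.z)


def successful_seeding_adjustment(g: TransitionGraph) -> TransitionGraph:
    """Rescale target-incoming rates nu(x, N) by lam(N)/alpha(N).

    After this mapping the hitting time refers to the first *successful*
    target cell — one whose progeny survives forever — rather than the
    first target cell.  Requires a supercritical target (lam(N) > 0,
    alpha(N) > 0); otherwise no target lineage survives and the adjusted
    hitting time is almost surely infinite.
    """
    aN = g.alpha(g.target)
    lN = g.lam(g.target)
    if not (aN > 0 and lN > 0):
        raise ValueError(
            f"target alpha={aN}, lam={lN}: successful-cell hitting time is "
            "almost surely infinite (no surviving target lineage)"
        )
    factor = lN / aN
    edges = {
        (x, y): (nu * factor if y == g.target else nu) for (x, y), nu in g.edges.items()
    }
    return g.with_edges(edges)


@dataclass(frozen=True)
class EigenCheck:
    """Rate matrix over non-target vertices and its spectral condition."""

    matrix: np.ndarray
    order: tuple[VertexId, ...]
    lam_star: float
    condition_ok: bool
    eigenvalues: np.ndarray
    eigenvector: np.ndarray  # right eigenvector for lam_star

    def __iter__(self):  # unpacks as (A, lam_star, flag)
        return iter((self.matrix, self.lam_star, self.condition_ok))


def rate_matrix_and_eigencheck(
    g: TransitionGraph,
    tol: float = 1e-9,
    gap_tol: float = 1e-9,
) -> EigenCheck:
    """Build the (N-1)x(N-1) matrix A with a_ii = lam(i), a_ij = nu(j, i).

    Rows/columns run over non-target vertices: root first, then the rest
    in sorted-id order.  Returns the largest real eigenvalue lam* and a
    flag that is true iff lam* equals the root growth rate and is simple
    (within tolerances) — the condition under which the cyclic-graph
    versions of the hitting-time and long-run growth results hold.  For
    acyclic graphs A is similar to a triangular matrix, its spectrum is
    {lam(i)}, and the flag reduces to the root-fitness assumption.
    """
    order = [g.root] + [v for v in _sorted_ids(g.vertices) if v not in (g.root, g.target)]
    idx = {v: i for i, v in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for v, i in idx.items():
        A[i, i] = g.lam(v)
    for (x, y), nu in g.edges.items():
        if y == g.target or x == g.target:
            continue
        A[idx[y], idx[x]] = nu
    try:
        evals, evecs = np.linalg.eig(A)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise RuntimeError(f"eigen-solver failure on rate matrix: {exc}") from exc
    # A is Metzler (non-negative off-diagonal), so the spectral bound is
    # attained by a real eigenvalue.
    reals = np.sort(evals.real)[::-1]
    lam_star = float(reals[0])
    simple = n == 1 or (reals[0] - reals[1]) > gap_tol
    lam = g.root_lam
    ok = bool(abs(lam_star - lam) <= tol * max(1.0, abs(lam)) and simple)
    k = int(np.argmax(evals.real))
    vec = np.real_if_close(evecs[:, k])
    return EigenCheck(A, tuple(order), lam_star, ok, evals, np.asarray(vec))
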