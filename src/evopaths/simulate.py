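"""Exact continuous-time simulation of the branching process with
vertex-lineage tracking.

The population is partitioned into *lineage classes*: all cells sharing a
vertex lineage q (the sequence of distinct consecutive vertices in their
ancestry) form one class.  A class at vertex x with n cells produces
events at total rate n * (alpha(x) + beta(x) + sum_y nu(x, y)); division
adds one cell to the class, death removes one, and a transition x → y
leaves the class untouched and adds one cell to class q + (y,) — the
(x) → (x), (y) rule.  Waiting times are exponential in the total rate and
the event is chosen proportionally to rate (the standard SSA), so a run
is a statistically exact realisation of the multitype branching process.

The first cell whose lineage ends at the target defines the hitting time
T and the seeding path.  In ``stop_at_first_target`` mode the run ends
there; in ``track_all_paths`` mode the run continues to the horizon,
recording the first arrival time of every target-reaching lineage.
Target cells themselves are recorded as arrivals but not propagated: all
quantities of interest concern the pre-target population and first
arrivals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .graph import TransitionGraph, VertexId

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate",
    "run_many",
    "estimate_hitting_survival",
    "estimate_path_distribution",
    "estimate_scaled_sizes",
    "HittingCurve",
]

_MODES = ("stop_at_first_target", "track_all_paths")


@dataclass(frozen=True)
class SimConfig:
    """One simulation campaign: graph, horizon, guards, seed, mode."""

    graph: TransitionGraph
    t_max: float
    seed: int
    pop_cap: int = 1_000_000
    mode: str = "stop_at_first_target"
    n_runs: int = 1
    record_times: tuple[float, ...] = ()
    record_events: bool = False
    max_classes: int = 100_000

    def __post_init__(self) -> None:
        if not self.t_max > 0:
            raise ValueError("t_max must be positive")
        if self.pop_cap <= self.graph.z:
            raise ValueError("pop_cap must exceed the initial cell count")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        object.__setattr__(self, "record_times", tuple(sorted(self.record_times)))


@dataclass
class SimResult:
    """Outcome of a single realisation."""

    hitting_time: float  # inf when the target was never seeded
    seeding_lineage: tuple[VertexId, ...] | None
    status: str  # "target_hit" | "extinct" | "censored"
    t_end: float
    path_hits: dict[tuple[VertexId, ...], float] = field(default_factory=dict)
    snapshots: dict[float, dict[VertexId, int]] = field(default_factory=dict)
    final_counts: dict[VertexId, int] = field(default_factory=dict)
    events: list[tuple] = field(default_factory=list)  # (time, lineage, vertex, kind, delta)

    @property
    def target_hit(self) -> bool:
        return math.isfinite(self.hitting_time)

    def scaled_size(self, t_f: float, x: VertexId, lam: float) -> float:
        """e^{-lam t_f} Z_x(t_f) from the recorded snapshot at t_f."""
        if t_f not in self.snapshots:
            raise ValueError(f"no snapshot recorded at t={t_f}")
        return math.exp(-lam * t_f) * self.snapshots[t_f].get(x, 0)


def _rng_for_run(master_seed: int, run_index: int) -> np.random.Generator:
    # documented counter scheme: entropy = (master_seed, run_index)
    return np.random.default_rng(np.random.SeedSequence((master_seed, run_index)))


def simulate(cfg: SimConfig, run_index: int = 0) -> SimResult:
    """One statistically exact realisation (seed derived from cfg.seed and
    ``run_index``; identical inputs give a bit-identical event sequence)."""
    g = cfg.graph
    rng = _rng_for_run(cfg.seed, run_index)
    rand = rng.random  # scalar uniforms drive the whole run

    target = g.target
    # per-vertex event tables
    valpha: dict[VertexId, float] = {}
    vbeta: dict[VertexId, float] = {}
    vout: dict[VertexId, list[tuple[VertexId, float]]] = {}
    vrate: dict[VertexId, float] = {}
    for v in g.vertices:
        valpha[v] = g.alpha(v)
        vbeta[v] = g.beta(v)
        vout[v] = g.out_edges(v)
        vrate[v] = valpha[v] + vbeta[v] + sum(nu for _, nu in vout[v])

    lineages: list[tuple[VertexId, ...]] = [(g.root,)]
    vertex_of: list[VertexId] = [g.root]
    counts: list[int] = [g.z]
    index_of: dict[tuple[VertexId, ...], int] = {(g.root,): 0}
    pop = g.z

    t = 0.0
    hit_t = math.inf
    seed_lineage: tuple[VertexId, ...] | None = None
    path_hits: dict[tuple[VertexId, ...], float] = {}
    snapshots: dict[float, dict[VertexId, int]] = {}
    events: list[tuple] = []
    status = "censored"
    rec = list(cfg.record_times)
    rec_i = 0

    def take_snapshots(up_to: float) -> None:
        nonlocal rec_i
        while rec_i < len(rec) and rec[rec_i] <= up_to:
            snap: dict[VertexId, int] = {}
            for li, c in enumerate(counts):
                if c:
                    x = vertex_of[li]
                    snap[x] = snap.get(x, 0) + c
            snapshots[rec[rec_i]] = snap
            rec_i += 1

    stop_on_hit = cfg.mode == "stop_at_first_target"
    while True:
        total_rate = 0.0
        for li in range(len(counts)):
            total_rate += counts[li] * vrate[vertex_of[li]]
        if total_rate <= 0.0:
            if pop == 0:
                take_snapshots(cfg.t_max)
                status = "extinct" if not math.isfinite(hit_t) else "target_hit"
                t_end = t
                break
            # inert survivors (all rates zero): nothing more can happen
            take_snapshots(cfg.t_max)
            status = "censored" if not math.isfinite(hit_t) else "target_hit"
            t_end = cfg.t_max
            break
        dt = -math.log(rand()) / total_rate
        t_new = t + dt
        if t_new > cfg.t_max:
            take_snapshots(cfg.t_max)
            status = "censored" if not math.isfinite(hit_t) else "target_hit"
            t_end = cfg.t_max
            break
        take_snapshots(t_new)

        # pick the class
        r = rand() * total_rate
        acc = 0.0
        ci = 0
        for li in range(len(counts)):
            acc += counts[li] * vrate[vertex_of[li]]
            if r < acc:
                ci = li
                break
        else:  # numerical edge: fall back to last non-empty class
            ci = max(i for i, c in enumerate(counts) if c > 0)
        x = vertex_of[ci]
        # pick the event within the class
        u = rand() * vrate[x]
        t = t_new
        if u < valpha[x]:
            counts[ci] += 1
            pop += 1
            if cfg.record_events:
                events.append((t, lineages[ci], x, "division", +1))
            if pop > cfg.pop_cap:
                take_snapshots(t)
                status = "censored" if not math.isfinite(hit_t) else "target_hit"
                t_end = t
                break
        elif u < valpha[x] + vbeta[x]:
            counts[ci] -= 1
            pop -= 1
            if cfg.record_events:
                events.append((t, lineages[ci], x, "death", -1))
            if pop == 0:
                take_snapshots(cfg.t_max)
                status = "extinct" if not math.isfinite(hit_t) else "target_hit"
                t_end = t
                break
        else:
            u -= valpha[x] + vbeta[x]
            y = vout[x][-1][0]
            for yy, nu in vout[x]:
                if u < nu:
                    y = yy
                    break
                u -= nu
            new_lin = lineages[ci] + (y,)
            if cfg.record_events:
                events.append((t, new_lin, y, "transition", +1))
            if y == target:
                if new_lin not in path_hits:
                    path_hits[new_lin] = t
                if not math.isfinite(hit_t):
                    hit_t = t
                    seed_lineage = new_lin
                    if stop_on_hit:
                        take_snapshots(t)
                        status = "target_hit"
                        t_end = t
                        break
                # target cells are not propagated (arrival recorded only)
            else:
                j = index_of.get(new_lin)
                if j is None:
                    if len(lineages) >= cfg.max_classes:
                        take_snapshots(t)
                        status = "censored" if not math.isfinite(hit_t) else "target_hit"
                        t_end = t
                        break
                    index_of[new_lin] = len(lineages)
                    lineages.append(new_lin)
                    vertex_of.append(y)
                    counts.append(1)
                else:
                    counts[j] += 1
                pop += 1
                if pop > cfg.pop_cap:
                    take_snapshots(t)
                    status = "censored" if not math.isfinite(hit_t) else "target_hit"
                    t_end = t
                    break

    final: dict[VertexId, int] = {}
    for li, c in enumerate(counts):
        if c:
            x = vertex_of[li]
            final[x] = final.get(x, 0) + c
    return SimResult(
        hitting_time=hit_t,
        seeding_lineage=seed_lineage,
        status=status,
        t_end=t_end,
        path_hits=path_hits,
        snapshots=snapshots,
        final_counts=final,
        events=events,
    )


def run_many(cfg: SimConfig) -> list[SimResult]:
    """cfg.n_runs independent realisations; run i uses the seed stream
    derived from (cfg.seed, i), so the campaign is reproducible and
    embarrassingly parallel."""
    return [simulate(cfg, i) for i in range(cfg.n_runs)]


# ---------------------------------------------------------------------------
# empirical estimators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HittingCurve:
    """Right-continuous step estimate of P(T > t) with pointwise CIs."""

    times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int
    t_valid: float  # curve trustworthy for t < t_valid (censoring limit)

    def at(self, t: float) -> float:
        k = int(np.searchsorted(self.times, t, side="right"))
        return 1.0 if k == 0 else float(self.survival[k - 1])


def _clopper_pearson(k: np.ndarray, n: int, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    a = (1 - level) / 2
    k = np.asarray(k, dtype=float)
    lo = np.where(k == 0, 0.0, beta_dist.ppf(a, k, n - k + 1))
    hi = np.where(k == n, 1.0, beta_dist.ppf(1 - a, k + 1, n - k))
    return lo, hi


def estimate_hitting_survival(
    results: Sequence[SimResult],
    conditioned: bool = False,
    level: float = 0.95,
) -> HittingCurve:
    """Empirical survival of the hitting time from a run collection.

    Runs that never hit the target count as T > t for every t (extinct
    runs genuinely never hit; censored runs bound the valid domain, which
    is reported as ``t_valid``).  With ``conditioned=True``, runs whose
    whole population went extinct before a target hit are discarded — the
    proxy for conditioning on root-population survival.
    """
    if conditioned:
        results = [r for r in results if r.status != "extinct"]
    if not results:
        raise ValueError("no usable runs")
    if all(r.status == "censored" for r in results):
        raise ValueError("all runs censored: no information about the hitting time")
    n = len(results)
    hits = np.sort([r.hitting_time for r in results if r.target_hit])
    censor_limits = [r.t_end for r in results if r.status == "censored"]
    t_valid = float(min(censor_limits)) if censor_limits else math.inf
    times = np.unique(hits)
    n_hit_by = np.searchsorted(hits, times, side="right")
    surv = 1.0 - n_hit_by / n
    lo_hit, hi_hit = _clopper_pearson(n_hit_by, n, level)
    return HittingCurve(
        times=times,
        survival=surv,
        ci_low=1.0 - hi_hit,
        ci_high=1.0 - lo_hit,
        n=n,
        t_valid=t_valid,
    )


def estimate_path_distribution(
    results: Sequence[SimResult],
    paths: Iterable | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Empirical seeding-path frequencies among target-hitting runs.

    One row per observed seeding lineage (plus any requested ``paths``
    never observed, at frequency 0), with Clopper-Pearson CIs.
    """
    hit = [r for r in results if r.target_hit and r.seeding_lineage is not None]
    if not hit:
        raise ValueError("no run hit the target")
    n = len(hit)
    counts: dict[tuple, int] = {}
    for r in hit:
        counts[r.seeding_lineage] = counts.get(r.seeding_lineage, 0) + 1
    if paths is not None:
        for p in paths:
            key = tuple(p.seq) if hasattr(p, "seq") else tuple(p)
            counts.setdefault(key, 0)
    keys = sorted(counts, key=lambda s: tuple(str(v) for v in s))
    k = np.array([counts[key] for key in keys])
    lo, hi = _clopper_pearson(k, n, level)
    return pd.DataFrame(
        {
            "path": keys,
            "count": k,
            "frequency": k / n,
            "ci_low": lo,
            "ci_high": hi,
            "n": n,
        }
    )


def estimate_scaled_sizes(
    results: Sequence[SimResult],
    t_f: float,
    lam: float,
) -> pd.DataFrame:
    """Per-run scaled sizes e^{-lam t_f} Z_x(t_f) and the W estimate.

    The run's W estimate is its scaled root size (root inferred from the
    graph is not needed here; callers pass results simulated with
    ``record_times`` containing ``t_f``).  Dividing mean scaled size by
    mean W estimates Phi_x.
    """
    rows = []
    for i, r in enumerate(results):
        if t_f not in r.snapshots:
            raise ValueError(f"run {i} has no snapshot at t={t_f}; add it to record_times")
        scale = math.exp(-lam * t_f)
        for x, c in r.snapshots[t_f].items():
            rows.append({"run": i, "vertex": x, "scaled_size": scale * c})
    if not rows:
        raise ValueError("no population recorded at t_f in any run")
    return pd.DataFrame(rows)


def events_to_dataframe(results: Sequence[SimResult]) -> pd.DataFrame:
    """Tidy event table (run, time, lineage, vertex, kind, delta)."""
    rows = []
    for i, r in enumerate(results):
        for t, lin, x, kind, delta in r.events:
            rows.append(
                {"run": i, "time": t, "lineage": "->".join(map(str, lin)), "vertex": x, "kind": kind, "delta": delta}
            )
    return pd.DataFrame(rows, columns=["run", "time", "lineage", "vertex", "kind", "delta"])
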