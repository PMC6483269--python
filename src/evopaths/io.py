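"""Graph-specification files and run manifests.

One canonical JSON dialect (versioned) describes a transition graph:

    {
      "schema_version": 1,
      "vertices": [{"id": 1, "alpha": 1.0, "beta": 0.4}, ...],
      "edges":    [{"from": 1, "to": 2, "nu": 0.05}, ...],
      "root": 1, "target": 4, "z": 1
    }

Loading validates the document field by field and reports every problem
with its JSON path; unknown keys are rejected in strict mode (the
default) so typos never silently change a model.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

from .graph import GraphStructureError, TransitionGraph, VertexParams, validate_graph

SCHEMA_VERSION = 1

__all__ = [
    "GraphSpecError",
    "read_graph_spec",
    "write_graph_spec",
    "graph_to_dict",
    "graph_from_dict",
    "RunManifest",
]


class GraphSpecError(ValueError):
    """A graph-spec document violates the schema; message lists every issue."""

    def __init__(self, issues: list[str]):
        self.issues = issues
        super().__init__("invalid graph spec:\n  " + "\n  ".join(issues))


_VERTEX_KEYS = {"id", "alpha", "beta"}
_EDGE_KEYS = {"from", "to", "nu"}
_TOP_KEYS = {"schema_version", "vertices", "edges", "root", "target", "z"}


def _check_number(value, path: str, issues: list[str], nonneg: bool = False) -> float | None:
    if isinstance(value, bool) or not isinstance(value, (int, float)) or not math.isfinite(value):
        issues.append(f"{path}: expected a finite number, got {value!r}")
        return None
    if nonneg and value < 0:
        issues.append(f"{path}: must be >= 0, got {value}")
        return None
    return float(value)


def graph_from_dict(doc: dict, strict: bool = True) -> TransitionGraph:
    issues: list[str] = []
    if not isinstance(doc, dict):
        raise GraphSpecError(["document root must be a JSON object"])
    if strict:
        for key in doc:
            if key not in _TOP_KEYS:
                issues.append(f"$.{key}: unknown key")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        issues.append(f"$.schema_version: expected {SCHEMA_VERSION}, got {version!r}")

    vertices: list[VertexParams] = []
    seen_ids: set = set()
    raw_vertices = doc.get("vertices")
    if not isinstance(raw_vertices, list) or not raw_vertices:
        issues.append("$.vertices: expected a non-empty list")
        raw_vertices = []
    for i, rv in enumerate(raw_vertices):
        path = f"$.vertices[{i}]"
        if not isinstance(rv, dict):
            issues.append(f"{path}: expected an object")
            continue
        if strict:
            for key in rv:
                if key not in _VERTEX_KEYS:
                    issues.append(f"{path}.{key}: unknown key")
        vid = rv.get("id")
        if not isinstance(vid, (str, int)) or isinstance(vid, bool):
            issues.append(f"{path}.id: expected string or integer, got {vid!r}")
            continue
        if vid in seen_ids:
            issues.append(f"{path}.id: duplicate vertex id {vid!r}")
            continue
        seen_ids.add(vid)
        a = _check_number(rv.get("alpha"), f"{path}.alpha", issues, nonneg=True)
        b = _check_number(rv.get("beta"), f"{path}.beta", issues, nonneg=True)
        if a is not None and b is not None:
            vertices.append(VertexParams(vid, a, b))

    edges: list[tuple] = []
    seen_edges: set = set()
    raw_edges = doc.get("edges")
    if not isinstance(raw_edges, list):
        issues.append("$.edges: expected a list")
        raw_edges = []
    for i, re_ in enumerate(raw_edges):
        path = f"$.edges[{i}]"
        if not isinstance(re_, dict):
            issues.append(f"{path}: expected an object")
            continue
        if strict:
            for key in re_:
                if key not in _EDGE_KEYS:
                    issues.append(f"{path}.{key}: unknown key")
        x, y = re_.get("from"), re_.get("to")
        if x not in seen_ids:
            issues.append(f"{path}.from: {x!r} is not a declared vertex id")
        if y not in seen_ids:
            issues.append(f"{path}.to: {y!r} is not a declared vertex id")
        nu = _check_number(re_.get("nu"), f"{path}.nu", issues)
        if nu is not None and nu <= 0:
            issues.append(f"{path}.nu: must be > 0 (omit zero-rate edges), got {nu}")
            nu = None
        if (x, y) in seen_edges:
            issues.append(f"{path}: duplicate edge ({x!r}, {y!r})")
            continue
        seen_edges.add((x, y))
        if x in seen_ids and y in seen_ids and nu is not None:
            edges.append((x, y, nu))

    root, target = doc.get("root"), doc.get("target")
    if root not in seen_ids:
        issues.append(f"$.root: {root!r} is not a declared vertex id")
    if target not in seen_ids:
        issues.append(f"$.target: {target!r} is not a declared vertex id")
    z = doc.get("z", 1)
    if isinstance(z, bool) or not isinstance(z, int) or z < 1:
        issues.append(f"$.z: expected a positive integer, got {z!r}")
        z = 1
    if issues:
        raise GraphSpecError(issues)

    try:
        g = TransitionGraph.build(vertices, edges, root=root, target=target, z=z)
    except GraphStructureError as exc:
        raise GraphSpecError([str(exc)]) from exc
    structural = [v.message for v in validate_graph(g) if v.severity == "error"]
    if structural:
        raise GraphSpecError(structural)
    return g


def read_graph_spec(path: str | Path, strict: bool = True) -> TransitionGraph:
    """Load and validate a graph-spec JSON file."""
    p = Path(path)
    try:
        doc = json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise GraphSpecError([f"{p}: not valid JSON ({exc})"]) from exc
    return graph_from_dict(doc, strict=strict)


def graph_to_dict(g: TransitionGraph) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "vertices": [
            {"id": v.id, "alpha": v.alpha, "beta": v.beta} for v in g.vertices.values()
        ],
        "edges": [
            {"from": x, "to": y, "nu": nu} for (x, y), nu in g.edges.items()
        ],
        "root": g.root,
        "target": g.target,
        "z": g.z,
    }


def write_graph_spec(g: TransitionGraph, path: str | Path, overwrite: bool = False) -> Path:
    p = Path(path)
    if p.exists() and not overwrite:
        raise FileExistsError(f"{p} exists; pass overwrite=True (or --force) to replace it")
    p.write_text(json.dumps(graph_to_dict(g), indent=2, default=str) + "\n")
    return p


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output set."""

    command: str
    config_hash: str
    seed: int | None
    tool_version: str
    created_utc: str
    outputs: list[str]

    @classmethod
    def create(cls, command: str, config: dict, seed: int | None, outputs: list[str]) -> "RunManifest":
        from . import __version__

        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return cls(
            command=command,
            config_hash=hashlib.sha256(blob).hexdigest(),
            seed=seed,
            tool_version=__version__,
            created_utc=datetime.now(timezone.utc).isoformat(timespec="seconds"),
            outputs=[str(o) for o in outputs],
        )

    def write(self, path: str | Path, overwrite: bool = False) -> Path:
        p = Path(path)
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; refusing to overwrite a manifest")
        p.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return p
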