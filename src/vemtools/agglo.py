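"""Agglomeration-graph proofreading backend.

Neurons are unions of supervoxels; the current reconstruction of each cell
is a connected component of an undirected graph over supervoxel ids.
Proofreaders fix split errors by adding edges and merge errors by removing
them.  The service holds the graph in memory, appends every edit to an
append-only log *before* acknowledging it, and can rebuild any state by
replaying the log on top of the automatically generated proposal graph.
Replay is strict: an out-of-order or inapplicable record halts with its
sequence number, so divergence is loud rather than silent.

Writes are serialized through a single lock (acknowledge after append);
reads may run concurrently.  A load-replay harness re-executes a log with
parallel clients and reports per-operation latency percentiles.
"""

from __future__ import annotations

import json
import threading
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AggloGraph",
    "EditRecord",
    "AggloError",
    "UnknownSupervoxelError",
    "SelfEdgeError",
    "DuplicateEdgeError",
    "MissingEdgeError",
    "ReplayError",
    "replay",
    "read_edit_log",
    "write_edit_log",
    "constrained_agglomerate",
    "effort_report",
    "replay_load_test",
]


class AggloError(Exception):
    pass


class UnknownSupervoxelError(AggloError):
    pass


class SelfEdgeError(AggloError):
    pass


class DuplicateEdgeError(AggloError):
    pass


class MissingEdgeError(AggloError):
    pass


class ReplayError(AggloError):
    def __init__(self, seq: int, message: str):
        super().__init__(f"replay halted at seq {seq}: {message}")
        self.seq = seq


@dataclass(frozen=True)
class EditRecord:
    seq: int
    op: str  # "add_edge" | "remove_edge"
    a: int
    b: int
    user: str = ""
    timestamp: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), separators=(",", ":"))

    @classmethod
    def from_json(cls, line: str) -> "EditRecord":
        d = json.loads(line)
        return cls(
            seq=int(d["seq"]),
            op=str(d["op"]),
            a=int(d["a"]),
            b=int(d["b"]),
            user=str(d.get("user", "")),
            timestamp=float(d.get("timestamp", 0.0)),
        )


def _key(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


class AggloGraph:
    """In-memory supervoxel graph with write-ahead edit logging."""

    def __init__(
        self,
        supervoxels,
        base_edges=(),
        nucleus_of: dict[int, int] | None = None,
        log_path: str | Path | None = None,
    ):
        self.ids: set[int] = {int(s) for s in supervoxels}
        self.nucleus_of: dict[int, int] = dict(nucleus_of or {})
        self.base_edges: set[tuple[int, int]] = set()
        self.adj: dict[int, set[int]] = {i: set() for i in self.ids}
        for a, b in base_edges:
            a, b = int(a), int(b)
            if a == b:
                raise SelfEdgeError(f"base self-edge {a}")
            if a not in self.ids or b not in self.ids:
                raise UnknownSupervoxelError(f"base edge ({a},{b}) references unknown id")
            self.base_edges.add(_key(a, b))
            self.adj[a].add(b)
            self.adj[b].add(a)
        self.live_edges: set[tuple[int, int]] = set(self.base_edges)
        self.log: list[EditRecord] = []
        self._next_seq = 1
        self._log_path = Path(log_path) if log_path else None
        self._write_lock = threading.Lock()
        if self._log_path and not self._log_path.exists():
            self._log_path.touch()

    # -- queries -----------------------------------------------------------
    def component_of(self, sv_id: int) -> set[int]:
        """Connected component of a supervoxel under the live edges (DFS)."""
        sv_id = int(sv_id)
        if sv_id not in self.ids:
            raise UnknownSupervoxelError(f"unknown supervoxel {sv_id}")
        comp = {sv_id}
        stack = [sv_id]
        while stack:
            u = stack.pop()
            for v in self.adj[u]:
                if v not in comp:
                    comp.add(v)
                    stack.append(v)
        return comp

    def partition(self) -> dict[int, int]:
        """Map each supervoxel to the smallest id of its component."""
        out: dict[int, int] = {}
        for start in self.ids:
            if start in out:
                continue
            comp = self.component_of(start)
            root = min(comp)
            for v in comp:
                out[v] = root
        return out

    def edge_fingerprint(self) -> int:
        """Order-independent XOR fingerprint of the live edge set."""
        h = 0
        for a, b in self.live_edges:
            h ^= hash((a, b)) & 0xFFFFFFFFFFFFFFFF
        return h

    # -- edits -------------------------------------------------------------
    def _validate(self, a: int, b: int, op: str) -> tuple[int, int]:
        a, b = int(a), int(b)
        if a == b:
            raise SelfEdgeError(f"self-edge ({a},{b})")
        if a not in self.ids or b not in self.ids:
            raise UnknownSupervoxelError(f"edge ({a},{b}) references unknown id")
        k = _key(a, b)
        if op == "add_edge" and k in self.live_edges:
            raise DuplicateEdgeError(f"edge {k} already live")
        if op == "remove_edge" and k not in self.live_edges:
            raise MissingEdgeError(f"edge {k} not live")
        return k

    def _apply(self, k: tuple[int, int], op: str) -> None:
        a, b = k
        if op == "add_edge":
            self.live_edges.add(k)
            self.adj[a].add(b)
            self.adj[b].add(a)
        else:
            self.live_edges.discard(k)
            self.adj[a].discard(b)
            self.adj[b].discard(a)

    def _edit(self, a: int, b: int, op: str, user: str) -> EditRecord:
        with self._write_lock:
            k = self._validate(a, b, op)
            rec = EditRecord(self._next_seq, op, k[0], k[1], user, time.time())
            # write-ahead: append to the on-disk log before acknowledging
            if self._log_path is not None:
                with open(self._log_path, "a") as f:
                    f.write(rec.to_json() + "\n")
                    f.flush()
            self._apply(k, op)
            self.log.append(rec)
            self._next_seq += 1
            return rec

    def add_edge(self, a: int, b: int, user: str = "") -> EditRecord:
        return self._edit(a, b, "add_edge", user)

    def remove_edge(self, a: int, b: int, user: str = "") -> EditRecord:
        return self._edit(a, b, "remove_edge", user)


def replay(base: AggloGraph, log: list[EditRecord]) -> AggloGraph:
    """Rebuild the live state by replaying an edit log on the proposal graph.

    Strict: records must have strictly increasing seq and each must be
    applicable in sequence, otherwise :class:`ReplayError` carries the
    offending seq.
    """
    g = AggloGraph(base.ids, base.base_edges, base.nucleus_of)
    last_seq = 0
    for rec in log:
        if rec.seq <= last_seq:
            raise ReplayError(rec.seq, f"non-increasing seq (previous {last_seq})")
        if rec.op not in ("add_edge", "remove_edge"):
            raise ReplayError(rec.seq, f"unknown op {rec.op!r}")
        try:
            k = g._validate(rec.a, rec.b, rec.op)
        except AggloError as e:
            raise ReplayError(rec.seq, str(e)) from e
        g._apply(k, rec.op)
        g.log.append(rec)
        last_seq = rec.seq
        g._next_seq = rec.seq + 1
    return g


def write_edit_log(log: list[EditRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as f:
        for rec in log:
            f.write(rec.to_json() + "\n")
    return path


def read_edit_log(path: str | Path) -> list[EditRecord]:
    out = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if line:
                out.append(EditRecord.from_json(line))
    return out


def constrained_agglomerate(
    supervoxels,
    candidates: list[tuple[float, int, int]],
    nucleus_of: dict[int, int] | None = None,
    score_threshold: float = 0.0,
) -> list[tuple[float, int, int]]:
    """Accept scored merge candidates while keeping nuclei separated.

    Candidates are visited in descending score order (ties by ascending
    (min id, max id)); one is accepted unless it would place two distinct
    nucleus ids into one component.  Returns the accepted candidates.
    """
    nucleus_of = nucleus_of or {}
    ids = {int(s) for s in supervoxels}
    parent = {i: i for i in ids}
    comp_nucleus: dict[int, set[int]] = {}
    for sv, nuc in nucleus_of.items():
        comp_nucleus.setdefault(int(sv), set()).add(int(nuc))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    accepted = []
    order = sorted(candidates, key=lambda c: (-c[0], min(c[1], c[2]), max(c[1], c[2])))
    for score, a, b in order:
        if score < score_threshold:
            continue
        a, b = int(a), int(b)
        if a not in ids or b not in ids or a == b:
            continue
        ra, rb = find(a), find(b)
        if ra == rb:
            accepted.append((score, a, b))
            continue
        na = comp_nucleus.get(ra, set())
        nb = comp_nucleus.get(rb, set())
        if len(na | nb) > 1:
            continue  # would fuse two somata
        parent[rb] = ra
        if na | nb:
            comp_nucleus[ra] = na | nb
            comp_nucleus.pop(rb, None)
        accepted.append((score, a, b))
    return accepted


def effort_report(
    log: list[EditRecord], cells: dict[int | str, set[int]]
) -> pd.DataFrame:
    """Per-cell proofreading effort: merge fixes (edge removals touching the
    cell) and split fixes (edge additions touching the cell)."""
    rows = []
    for cell_id, svs in cells.items():
        merge_fix = sum(1 for r in log if r.op == "remove_edge" and (r.a in svs or r.b in svs))
        split_fix = sum(1 for r in log if r.op == "add_edge" and (r.a in svs or r.b in svs))
        rows.append(
            {"cell": cell_id, "merge_fixes": merge_fix, "split_fixes": split_fix}
        )
    return pd.DataFrame(rows, columns=["cell", "merge_fixes", "split_fixes"])


def replay_load_test(
    base: AggloGraph, log: list[EditRecord], n_clients: int = 1
) -> tuple[pd.DataFrame, AggloGraph]:
    """Re-execute a log against a live service with parallel clients.

    Records are dealt round-robin to ``n_clients`` submitters; writes are
    funneled through a sequencer that preserves log order (so the final
    partition is independent of the client count), and each client issues a
    component query after each of its writes.  Returns a table of
    1st/50th/99th percentile latencies (ms) per op type — reporting only —
    and the final graph.
    """
    service = AggloGraph(base.ids, base.base_edges, base.nucleus_of)
    if not log:
        return (
            pd.DataFrame(columns=["op", "n", "p01_ms", "p50_ms", "p99_ms"]),
            service,
        )
    latencies: dict[str, list[float]] = {"add_edge": [], "remove_edge": [], "component": []}
    lat_lock = threading.Lock()
    cond = threading.Condition()
    next_write = [0]

    def run_client(ci: int) -> None:
        for gi in range(ci, len(log), n_clients):
            rec = log[gi]
            with cond:
                cond.wait_for(lambda: next_write[0] == gi)
            t0 = time.perf_counter()
            if rec.op == "add_edge":
                service.add_edge(rec.a, rec.b, rec.user)
            else:
                service.remove_edge(rec.a, rec.b, rec.user)
            dt = (time.perf_counter() - t0) * 1000
            with cond:
                next_write[0] = gi + 1
                cond.notify_all()
            t0 = time.perf_counter()
            service.component_of(rec.a)
            dq = (time.perf_counter() - t0) * 1000
            with lat_lock:
                latencies[rec.op].append(dt)
                latencies["component"].append(dq)

    threads = [threading.Thread(target=run_client, args=(ci,)) for ci in range(n_clients)]
    for t in threads:
        t.start()
    for t in threads:
        t.join()

    rows = []
    for op, vals in latencies.items():
        if not vals:
            continue
        rows.append(
            {
                "op": op,
                "n": len(vals),
                "p01_ms": float(np.percentile(vals, 1)),
                "p50_ms": float(np.percentile(vals, 50)),
                "p99_ms": float(np.percentile(vals, 99)),
            }
        )
    return pd.DataFrame(rows, columns=["op", "n", "p01_ms", "p50_ms", "p99_ms"]), service
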