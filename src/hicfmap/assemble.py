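"""FPC-style contig assembly from scored HICF fingerprints.

The schedule follows standard fingerprint-contig practice: build initial
contigs as single-linkage components of the clone graph thresholded at a
stringent Sulston cutoff (1e-40); order each contig's clones and build a
consensus-band (CB) map; flag Q-clones (clones whose bands agree poorly
with their placed neighborhood); dissolve contigs whose Q-clone fraction
exceeds 15% and re-cluster their clones at stepped-up stringency (the
"DQer"); then grow the map back conservatively — several rounds of
end-to-end contig merging at progressively relaxed cutoffs down to 1e-15,
followed by single-to-end attachment of leftover singletons at 1e-15.

Clone ordering (seriation) works in two stages. A global order comes
from spectral seriation: shared-band counts are converted to estimated
inter-clone midpoint distances d = (nA + nB)/2 - m (which corrects for
insert-length variation), turned into a Gaussian affinity, and the
Fiedler vector of the graph Laplacian gives the 1-D embedding. The
order is then refined against the consensus-band map itself: band values
are clustered per channel by single linkage at the size tolerance, each
cluster is split into positional runs (the same band size recurring in
two distant regions is two different restriction fragments), clones are
re-sorted by robust order statistics of their runs' positions, and the
procedure iterates to a fixed point. A clone's CB interval is the rank
span of its runs. Every tie-break is total (lexicographic on
clone/contig ids), so identical inputs give byte-identical assemblies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .overlap import (
    Edge,
    ScoreParams,
    score_all_pairs,
    shared_band_count,
    shared_sorted_count,
)
from .sizes_io import Fingerprint, N_CHANNELS

__all__ = [
    "AssemblyParams",
    "Contig",
    "Assembly",
    "ScoreTable",
    "cluster_at_cutoff",
    "seriate_contig",
    "flag_q_clones",
    "dq_split",
    "merge_end_to_end",
    "attach_singletons",
    "assemble",
    "write_assembly",
]


@dataclass(frozen=True)
class AssemblyParams:
    """Cutoff schedule and Q-clone policy of the assembler."""

    initial_cutoff: float = 1e-40
    final_cutoff: float = 1e-15
    merge_schedule: tuple[float, ...] = (1e-35, 1e-30, 1e-25, 1e-20, 1e-15)
    dq_fraction: float = 0.15
    q_match_fraction: float = 0.5
    end_depth: int = 2
    dq_stringency_step: float = 1e-5
    max_dq_rounds: int = 3
    # seriation internals: positional gap (in clone ranks) above which one
    # band-size class is split into distinct consensus bands, and the order
    # statistic of run positions used as a clone's ordering key (robust to
    # size-collision artifacts).
    cb_split_gap: float = 3.0
    key_order_stat: int = 4
    max_seriation_iter: int = 15
    score: ScoreParams = field(default_factory=ScoreParams)

    def __post_init__(self) -> None:
        if not 0 < self.dq_fraction < 1:
            raise ValueError("dq_fraction must be in (0, 1)")
        for c in self.merge_schedule:
            if not self.initial_cutoff <= c <= self.final_cutoff:
                raise ValueError(
                    "merge schedule cutoffs must lie between initial and final cutoffs"
                )
        if self.initial_cutoff > self.final_cutoff:
            raise ValueError("initial_cutoff must be at most final_cutoff")


@dataclass
class Contig:
    """An ordered run of clones with its consensus-band map.

    ``order_keys`` holds each clone's (left, right) ordering key in CB
    position space; clones with equal left keys share their leftmost
    consensus band and are mutually unordered by the data.
    """

    contig_id: int
    clones: list[str]
    cb_count: int = 0
    cb_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    q_flags: dict[str, bool] = field(default_factory=dict)
    order_keys: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def n_q(self) -> int:
        return sum(1 for v in self.q_flags.values() if v)

    @property
    def q_fraction(self) -> float:
        return self.n_q / self.n_clones if self.clones else 0.0


@dataclass
class Assembly:
    """Contigs + singletons + a provenance log of every split and merge."""

    contigs: list[Contig] = field(default_factory=list)
    singletons: list[str] = field(default_factory=list)
    log: list[dict] = field(default_factory=list)
    next_contig_id: int = 1

    def new_contig_id(self) -> int:
        cid = self.next_contig_id
        self.next_contig_id += 1
        return cid

    def clone_ids(self) -> set[str]:
        ids = set(self.singletons)
        for c in self.contigs:
            ids.update(c.clones)
        return ids

    def check(self, expected: Iterable[str]) -> None:
        """Partition invariant: every clone in exactly one contig or singleton."""
        expected = set(expected)
        seen: list[str] = list(self.singletons)
        for c in self.contigs:
            seen.extend(c.clones)
        if len(seen) != len(set(seen)):
            raise AssertionError("a clone appears in more than one place")
        if set(seen) != expected:
            raise AssertionError("assembly does not partition the input clones")


class ScoreTable:
    """Sparse pair scores (score <= cutoff) with on-demand shared-band counts."""

    def __init__(self, edges: Sequence[Edge], fingerprints: Mapping[str, Fingerprint]):
        self._edges: dict[tuple[str, str], Edge] = {}
        for e in edges:
            key = (e.a, e.b) if e.a < e.b else (e.b, e.a)
            self._edges[key] = e
        self._fps = fingerprints
        self._m_cache: dict[tuple[str, str], int] = {}
        self.tolerance = 0.4

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)

    def edge(self, a: str, b: str) -> Edge | None:
        return self._edges.get(self._key(a, b))

    def score(self, a: str, b: str) -> float:
        e = self.edge(a, b)
        return e.score if e is not None else 1.0

    def shared(self, a: str, b: str) -> int:
        e = self.edge(a, b)
        if e is not None:
            return e.shared
        key = self._key(a, b)
        m = self._m_cache.get(key)
        if m is None:
            m = shared_band_count(self._fps[a], self._fps[b], self.tolerance)
            self._m_cache[key] = m
        return m

    def edges_at(self, cutoff: float) -> list[Edge]:
        return [e for e in self._edges.values() if e.score <= cutoff]


def cluster_at_cutoff(
    clone_ids: Iterable[str], edges: Sequence[Edge], cutoff: float
) -> tuple[list[list[str]], list[str]]:
    """Single-linkage connected components of the thresholded clone graph.

    Returns (components of size >= 2, singletons), each deterministically
    sorted.
    """
    ids = sorted(set(clone_ids))
    parent = {c: c for c in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        if e.score <= cutoff and e.a in parent and e.b in parent:
            ra, rb = find(e.a), find(e.b)
            if ra != rb:
                if ra < rb:
                    parent[rb] = ra
                else:
                    parent[ra] = rb
    groups: dict[str, list[str]] = {}
    for c in ids:
        groups.setdefault(find(c), []).append(c)
    components = sorted(
        (sorted(g) for g in groups.values() if len(g) >= 2), key=lambda g: g[0]
    )
    singles = sorted(c for g in groups.values() if len(g) == 1 for c in g)
    return components, singles


def _spectral_order(
    members: list[str],
    fingerprints: Mapping[str, Fingerprint],
    table: ScoreTable,
) -> list[str]:
    """Global 1-D seriation from length-corrected band distances.

    The shared-band count of overlapping clones estimates their midpoint
    distance: d = (nA + nB)/2 - m (in band units). A Gaussian affinity on
    d restores the Robinson (banded) structure that raw counts lose when
    insert lengths vary; the Fiedler vector of the affinity Laplacian
    orders the clones. Deterministic: ties break on clone id.
    """
    ids = sorted(members)
    n = len(ids)
    if n <= 2:
        return ids
    n_bands = np.array([fingerprints[c].n_bands for c in ids], dtype=float)
    # distances only for genuinely scored pairs: chance-level pairs would
    # add weak long-range links that swamp the tiny Fiedler eigenvalue of
    # a long clone chain
    D = np.full((n, n), np.inf)
    strong: list[float] = []
    for i in range(n):
        for j in range(i + 1, n):
            if table.edge(ids[i], ids[j]) is None:
                continue
            m = table.shared(ids[i], ids[j])
            d = max(0.0, (n_bands[i] + n_bands[j]) / 2.0 - m)
            D[i, j] = D[j, i] = d
            if table.score(ids[i], ids[j]) <= 1e-40:
                strong.append(d)
    finite = D[np.isfinite(D)]
    if finite.size == 0:
        return ids
    scale = float(np.median(strong)) if strong else float(np.median(finite))
    scale = max(scale, 1.0)
    with np.errstate(over="ignore"):
        W = np.where(np.isfinite(D), np.exp(-((D / scale) ** 2)), 0.0)
    np.fill_diagonal(W, 0.0)
    L = np.diag(W.sum(axis=1)) - W
    _, vecs = np.linalg.eigh(L)
    fiedler = vecs[:, 1]
    return [ids[i] for i in sorted(range(n), key=lambda i: (fiedler[i], ids[i]))]


def _cb_runs(
    order: Sequence[str],
    fingerprints: Mapping[str, Fingerprint],
    tolerance: float,
    split_gap: float,
) -> list[tuple[float, int, float, float, tuple[str, ...]]]:
    """Consensus-band runs: size classes split by clone-position gaps.

    Band values are clustered per channel by single linkage at the size
    tolerance; each cluster's occurrences are then split wherever the
    positions (ranks in ``order``) of consecutive carrying clones jump by
    more than ``split_gap`` — the same fragment size recurring in two
    separated regions is two distinct consensus bands. Each run is
    positioned at the median rank of its carrying clones. Returns runs as
    (position, channel, size_lo, size_hi, clones).
    """
    pos = {c: float(i) for i, c in enumerate(order)}
    runs: list[tuple[float, int, float, float, tuple[str, ...]]] = []
    for ch in range(N_CHANNELS):
        values = sorted(
            (b.size, c) for c in order for b in fingerprints[c].bands if b.channel == ch
        )
        if not values:
            continue
        start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i][0] - values[i - 1][0] > tolerance:
                cluster = values[start:i]
                occ = sorted({c for _, c in cluster}, key=lambda c: (pos[c], c))
                lo, hi = cluster[0][0], cluster[-1][0]
                run = [occ[0]]
                for c in occ[1:]:
                    if pos[c] - pos[run[-1]] > split_gap:
                        runs.append(
                            (float(np.median([pos[x] for x in run])), ch, lo, hi, tuple(run))
                        )
                        run = [c]
                    else:
                        run.append(c)
                runs.append(
                    (float(np.median([pos[x] for x in run])), ch, lo, hi, tuple(run))
                )
                start = i
    return runs


def _order_keys(
    order: Sequence[str],
    runs: Sequence[tuple[float, int, float, float, tuple[str, ...]]],
    order_stat: int,
) -> dict[str, tuple[float, float]]:
    """Per-clone (left, right) keys: k-th order statistics of run positions.

    Runs carried by a single clone hold no ordering information and are
    skipped; the k-th smallest/largest (rather than the extreme) position
    makes the keys robust to residual size-collision runs.
    """
    pos = {c: float(i) for i, c in enumerate(order)}
    by_clone: dict[str, list[float]] = {c: [] for c in order}
    for p, _ch, _lo, _hi, clones in runs:
        if len(clones) < 2:
            continue
        for c in clones:
            by_clone[c].append(p)
    keys: dict[str, tuple[float, float]] = {}
    for c in order:
        ms = sorted(by_clone[c])
        if not ms:
            keys[c] = (pos[c], pos[c])
        else:
            k = min(order_stat, len(ms)) - 1
            keys[c] = (ms[k], ms[-1 - k])
    return keys


def flag_q_clones(
    contig: Contig,
    fingerprints: Mapping[str, Fingerprint],
    params: AssemblyParams,
) -> dict[str, bool]:
    """A clone is Q when too few of its bands match its placed neighbors.

    The clone's bands are matched (channel-aware, at the size tolerance)
    against the pooled bands of its immediate neighbors in the contig
    order; a matched fraction below ``q_match_fraction`` flags the clone.
    In a 2-clone contig the single neighbor is the other clone.
    """
    tol = params.score.tolerance
    flags: dict[str, bool] = {}
    order = contig.clones
    for i, cid in enumerate(order):
        fp = fingerprints[cid]
        if fp.n_bands == 0:
            flags[cid] = True
            continue
        neighbor_sizes: list[list[float]] = [[] for _ in range(N_CHANNELS)]
        for j in (i - 1, i + 1):
            if 0 <= j < len(order):
                for b in fingerprints[order[j]].bands:
                    neighbor_sizes[b.channel].append(b.size)
        for sizes in neighbor_sizes:
            sizes.sort()
        own = fp.channel_sizes()
        matched = sum(
            shared_sorted_count(own[ch], neighbor_sizes[ch], tol)
            for ch in range(N_CHANNELS)
        )
        flags[cid] = (matched / fp.n_bands) < params.q_match_fraction
    return flags


def seriate_contig(
    members: Iterable[str],
    fingerprints: Mapping[str, Fingerprint],
    params: AssemblyParams,
    table: ScoreTable,
    contig_id: int,
) -> Contig:
    """Order a component's clones and build its CB map and Q flags.

    Spectral seriation provides the global order; the order is then
    iterated against the consensus-band map (re-sorting clones by their
    run-position keys) to a fixed point. CB ranks and the final keys are
    taken from the converged order.
    """
    members = sorted(members)
    if len(members) < 2:
        raise ValueError("a contig needs at least 2 clones")
    tol = params.score.tolerance
    order = _spectral_order(members, fingerprints, table)
    keys = None
    for _ in range(params.max_seriation_iter):
        runs = _cb_runs(order, fingerprints, tol, params.cb_split_gap)
        keys = _order_keys(order, runs, params.key_order_stat)
        new_order = sorted(order, key=lambda c: (keys[c][0], keys[c][1], c))
        if new_order == order:
            break
        order = new_order
    runs = _cb_runs(order, fingerprints, tol, params.cb_split_gap)
    keys = _order_keys(order, runs, params.key_order_stat)

    # CB ranks: runs sorted along the map; a clone spans its runs' ranks
    ranked = sorted(range(len(runs)), key=lambda i: (runs[i][0], runs[i][1], runs[i][2]))
    rank_of = {idx: r for r, idx in enumerate(ranked)}
    intervals: dict[str, tuple[int, int]] = {}
    for idx, (_p, _ch, _lo, _hi, clones) in enumerate(runs):
        r = rank_of[idx]
        for c in clones:
            lo, hi = intervals.get(c, (len(runs), -1))
            intervals[c] = (min(lo, r), max(hi, r))
    for c in order:
        if c not in intervals:
            intervals[c] = (0, 0)
    contig = Contig(
        contig_id,
        order,
        cb_count=len(runs),
        cb_intervals=intervals,
        order_keys=keys,
    )
    contig.q_flags = flag_q_clones(contig, fingerprints, params)
    return contig


def dq_split(
    assembly: Assembly,
    fingerprints: Mapping[str, Fingerprint],
    params: AssemblyParams,
    table: ScoreTable,
) -> Assembly:
    """Dissolve contigs over the Q-clone fraction; re-cluster more stringently.

    Each round multiplies the clustering cutoff by ``dq_stringency_step``
    (smaller = more stringent); clones that no longer join any component
    become singletons. Contigs still over the threshold after
    ``max_dq_rounds`` are left as flagged Q-contigs.
    """
    for round_no in range(1, params.max_dq_rounds + 1):
        cutoff = params.initial_cutoff * params.dq_stringency_step ** round_no
        bad = [c for c in assembly.contigs if c.q_fraction > params.dq_fraction]
        if not bad:
            break
        for contig in bad:
            assembly.contigs.remove(contig)
            assembly.log.append(
                {
                    "event": "dq_dissolve",
                    "round": round_no,
                    "contig": contig.contig_id,
                    "n_clones": contig.n_clones,
                    "q_fraction": round(contig.q_fraction, 4),
                    "recluster_cutoff": cutoff,
                }
            )
            comps, singles = cluster_at_cutoff(
                contig.clones, table.edges_at(cutoff), cutoff
            )
            for comp in comps:
                new = seriate_contig(
                    comp, fingerprints, params, table, assembly.new_contig_id()
                )
                assembly.contigs.append(new)
                assembly.log.append(
                    {
                        "event": "dq_recluster",
                        "round": round_no,
                        "parent": contig.contig_id,
                        "contig": new.contig_id,
                        "n_clones": new.n_clones,
                    }
                )
            assembly.singletons.extend(singles)
    assembly.singletons.sort()
    return assembly


def _end_clones(contig: Contig, side: str, depth: int) -> list[str]:
    return contig.clones[:depth] if side == "L" else contig.clones[-depth:]


def _best_end_score(
    ends_a: list[str], ends_b: list[str], table: ScoreTable
) -> tuple[float, tuple[str, str]]:
    best = (2.0, ("", ""))
    for x in ends_a:
        for y in ends_b:
            s = table.score(x, y)
            if (s, (x, y)) < best:
                best = (s, (x, y))
    return best


def merge_end_to_end(
    assembly: Assembly,
    fingerprints: Mapping[str, Fingerprint],
    params: AssemblyParams,
    table: ScoreTable,
) -> Assembly:
    """Rounds of end-to-end contig merging at relaxing cutoffs.

    At each schedule cutoff, repeatedly merge the best-scoring pair of
    contig ends (best score among the ``end_depth`` terminal clones of
    each end) while any candidate is at or below the cutoff. A merge
    whose re-seriated result would exceed the Q-clone fraction threshold
    is rejected and not retried at this cutoff.
    """
    for cutoff in params.merge_schedule:
        rejected: set[tuple[int, int, str, str]] = set()
        while True:
            contigs = sorted(assembly.contigs, key=lambda c: c.contig_id)
            best = None  # (score, id_a, id_b, side_a, side_b, junction)
            for i, ca in enumerate(contigs):
                for cb in contigs[i + 1:]:
                    for sa in ("L", "R"):
                        for sb in ("L", "R"):
                            if (ca.contig_id, cb.contig_id, sa, sb) in rejected:
                                continue
                            s, junction = _best_end_score(
                                _end_clones(ca, sa, params.end_depth),
                                _end_clones(cb, sb, params.end_depth),
                                table,
                            )
                            if s > cutoff:
                                continue
                            cand = (s, ca.contig_id, cb.contig_id, sa, sb, junction)
                            if best is None or cand < best:
                                best = cand
            if best is None:
                break
            score, id_a, id_b, sa, sb, junction = best
            ca = next(c for c in assembly.contigs if c.contig_id == id_a)
            cb = next(c for c in assembly.contigs if c.contig_id == id_b)
            merged = seriate_contig(
                ca.clones + cb.clones,
                fingerprints,
                params,
                table,
                assembly.next_contig_id,  # peek; commit only on acceptance
            )
            if merged.q_fraction > params.dq_fraction:
                rejected.add((id_a, id_b, sa, sb))
                assembly.log.append(
                    {
                        "event": "merge_rejected",
                        "cutoff": cutoff,
                        "left": id_a,
                        "right": id_b,
                        "q_fraction": round(merged.q_fraction, 4),
                    }
                )
                continue
            merged.contig_id = assembly.new_contig_id()
            assembly.contigs.remove(ca)
            assembly.contigs.remove(cb)
            assembly.contigs.append(merged)
            assembly.log.append(
                {
                    "event": "merge",
                    "cutoff": cutoff,
                    "left": id_a,
                    "right": id_b,
                    "contig": merged.contig_id,
                    "junction": list(junction),
                    "score": score,
                }
            )
    return assembly


def attach_singletons(
    assembly: Assembly,
    fingerprints: Mapping[str, Fingerprint],
    params: AssemblyParams,
    table: ScoreTable,
) -> Assembly:
    """Single-to-end merging: each singleton joins its best-scoring contig end.

    A singleton attaches when its best score against a contig end's
    terminal clones is at or below the final cutoff; ties break by lower
    score, then lower contig id. The receiving contig is re-seriated.
    """
    remaining: list[str] = []
    for s in sorted(assembly.singletons):
        best = None  # (score, contig_id, side, junction_clone)
        for contig in sorted(assembly.contigs, key=lambda c: c.contig_id):
            for side in ("L", "R"):
                for y in _end_clones(contig, side, params.end_depth):
                    sc = table.score(s, y)
                    cand = (sc, contig.contig_id, side, y)
                    if best is None or cand < best:
                        best = cand
        if best is None or best[0] > params.final_cutoff:
            remaining.append(s)
            continue
        score, cid, side, junction_clone = best
        target = next(c for c in assembly.contigs if c.contig_id == cid)
        new = seriate_contig(
            target.clones + [s], fingerprints, params, table, assembly.new_contig_id()
        )
        assembly.contigs.remove(target)
        assembly.contigs.append(new)
        assembly.log.append(
            {
                "event": "attach_singleton",
                "cutoff": params.final_cutoff,
                "clone": s,
                "contig": cid,
                "new_contig": new.contig_id,
                "junction": [s, junction_clone],
                "score": score,
            }
        )
    assembly.singletons = sorted(remaining)
    return assembly


def assemble(
    fingerprints: Sequence[Fingerprint], params: AssemblyParams | None = None
) -> Assembly:
    """Full pipeline: initial build -> DQer -> end-to-end -> single-to-end."""
    params = params or AssemblyParams()
    fps = {fp.clone_id: fp for fp in fingerprints}
    if len(fps) != len(fingerprints):
        raise ValueError("duplicate clone ids in input")
    score_params = replace(params.score, cutoff=params.final_cutoff)
    edges = score_all_pairs(list(fingerprints), score_params)
    table = ScoreTable(edges, fps)
    table.tolerance = params.score.tolerance

    assembly = Assembly()
    comps, singles = cluster_at_cutoff(fps.keys(), edges, params.initial_cutoff)
    for comp in comps:
        contig = seriate_contig(comp, fps, params, table, assembly.new_contig_id())
        assembly.contigs.append(contig)
    assembly.singletons = singles
    assembly.log.append(
        {
            "event": "initial_build",
            "cutoff": params.initial_cutoff,
            "n_contigs": len(assembly.contigs),
            "n_singletons": len(assembly.singletons),
        }
    )
    dq_split(assembly, fps, params, table)
    merge_end_to_end(assembly, fps, params, table)
    attach_singletons(assembly, fps, params, table)
    assembly.contigs.sort(key=lambda c: c.contig_id)
    assembly.check(fps.keys())
    return assembly


def contigs_table(assembly: Assembly) -> pd.DataFrame:
    """Flat per-clone table: contig, rank, CB interval, Q flag."""
    rows = []
    for contig in sorted(assembly.contigs, key=lambda c: c.contig_id):
        for rank, cid in enumerate(contig.clones):
            lo, hi = contig.cb_intervals.get(cid, (0, 0))
            rows.append(
                {
                    "contig_id": contig.contig_id,
                    "clone_id": cid,
                    "rank": rank,
                    "cb_start": lo,
                    "cb_end": hi,
                    "q_flag": int(contig.q_flags.get(cid, False)),
                }
            )
    return pd.DataFrame(
        rows, columns=["contig_id", "clone_id", "rank", "cb_start", "cb_end", "q_flag"]
    )


def write_assembly(assembly: Assembly, out_dir: str | Path) -> dict[str, Path]:
    """Write contigs TSV, singleton list and the provenance log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "contigs": out_dir / "contigs.tsv",
        "singletons": out_dir / "singletons.txt",
        "log": out_dir / "provenance.json",
    }
    contigs_table(assembly).to_csv(paths["contigs"], sep="\t", index=False)
    paths["singletons"].write_text(
        "".join(f"{s}\n" for s in sorted(assembly.singletons))
    )
    paths["log"].write_text(json.dumps(assembly.log, indent=1) + "\n")
    return paths
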