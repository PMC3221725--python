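"""Scoring an assembly against simulated ground truth.

These metrics are in-silico analogs of the wet-lab checks used to
validate fingerprint physical maps: interval intersection of the two
clones at an end-to-end merge junction stands in for a positive PCR
across the junction; a contig whose clones tile one gap-free genomic
block stands in for whole-contig PCR confirmation; and uniformly dropped
marker points co-locating on one replicon stand in for microsatellite
anchors mapping to a single linkage group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .assemble import Assembly, Contig
from .sizes_io import CloneInterval
from .simulate import TruthSet

__all__ = [
    "EvalReport",
    "label_chimeras",
    "validate_junctions",
    "order_accuracy",
    "marker_consistency",
    "clone_assignment_recall",
    "evaluate_assembly",
]


def _truth_map(truth: TruthSet | Sequence[CloneInterval]) -> dict[str, CloneInterval]:
    if isinstance(truth, TruthSet):
        return truth.interval_of()
    return {iv.clone_id: iv for iv in truth}


@dataclass
class EvalReport:
    """Fractions are in [0, 1]; None marks metrics with no evaluable cases."""

    chimera_rate: float
    junction_true_fraction: float | None
    n_junctions: int
    order_accuracy: float
    mean_rank_correlation: float
    clone_assignment_recall: float
    genome_fraction_covered: float
    marker_consistency: float | None
    n_marker_contigs: int


def label_chimeras(
    assembly: Assembly,
    truth: TruthSet | Sequence[CloneInterval],
    gap_kb: float = 0.0,
) -> dict[int, bool]:
    """True per contig iff its clones tile a single true genomic block.

    A contig is non-chimeric when all member clones lie on one replicon
    and the union of their true intervals is connected, allowing
    inter-clone gaps up to ``gap_kb``.
    """
    tm = _truth_map(truth)
    gap = gap_kb * 1000.0
    labels: dict[int, bool] = {}
    for contig in assembly.contigs:
        ivs = [tm[c] for c in contig.clones]
        if len({iv.replicon for iv in ivs}) > 1:
            labels[contig.contig_id] = False
            continue
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        ok = True
        reach = ivs[0].end
        for iv in ivs[1:]:
            if iv.start > reach + gap:
                ok = False
                break
            reach = max(reach, iv.end)
        labels[contig.contig_id] = ok
    return labels


def chimera_rate(
    assembly: Assembly, truth: TruthSet | Sequence[CloneInterval], gap_kb: float = 0.0
) -> float:
    labels = label_chimeras(assembly, truth, gap_kb)
    if not labels:
        return 0.0
    return sum(1 for ok in labels.values() if not ok) / len(labels)


def validate_junctions(
    assembly: Assembly, truth: TruthSet | Sequence[CloneInterval]
) -> tuple[float | None, pd.DataFrame]:
    """Fraction of end-to-end merge junctions whose clones truly overlap.

    Scans the provenance log for merge events; a junction is true iff the
    two joined end clones' true intervals intersect (what a positive PCR
    across the junction certifies). With no merges the fraction is None.
    """
    tm = _truth_map(truth)
    rows = []
    for event in assembly.log:
        if event.get("event") != "merge":
            continue
        a, b = event["junction"]
        ia, ib = tm[a], tm[b]
        true_overlap = ia.replicon == ib.replicon and ia.start < ib.end and ib.start < ia.end
        rows.append(
            {
                "clone_a": a,
                "clone_b": b,
                "cutoff": event["cutoff"],
                "score": event["score"],
                "true_overlap": "+" if true_overlap else "-",
            }
        )
    table = pd.DataFrame(
        rows, columns=["clone_a", "clone_b", "cutoff", "score", "true_overlap"]
    )
    if not rows:
        return None, table
    frac = float((table["true_overlap"] == "+").mean())
    return frac, table


def _perfectly_ordered(
    contig: Contig, tm: Mapping[str, CloneInterval]
) -> bool:
    """No discordant clone pair, up to reflection, at CB-map resolution.

    Clones sharing their leftmost consensus band (equal left ordering
    key) cannot be ordered from band content and are excused. For the
    remaining pairs the forward reading requires true starts ascending;
    the reflected reading requires true ends descending — a reflected
    map's coordinate is an affine image of the genome end coordinate, so
    that is what its clone order sorts by.
    """
    order = contig.clones
    keys = contig.order_keys
    n = len(order)

    def resolvable(a: str, b: str) -> bool:
        if not keys:
            return True
        return keys[a][0] != keys[b][0]

    fwd = rev = True
    for i in range(n):
        for j in range(i + 1, n):
            a, b = order[i], order[j]
            if not resolvable(a, b):
                continue
            if fwd and tm[a].start >= tm[b].start:
                fwd = False
            if rev and tm[a].end <= tm[b].end:
                rev = False
            if not fwd and not rev:
                return False
    return fwd or rev


def order_accuracy(
    assembly: Assembly,
    truth: TruthSet | Sequence[CloneInterval],
    gap_kb: float = 0.0,
) -> tuple[float, float]:
    """Fraction of non-chimeric contigs perfectly ordered up to reflection.

    A contig counts as perfectly ordered when its clone order has no
    discordant pair against the true coordinates in either reading (see
    :func:`_perfectly_ordered`). Also returns the mean absolute Spearman
    correlation between clone order and true start coordinate.
    """
    tm = _truth_map(truth)
    labels = label_chimeras(assembly, truth, gap_kb)
    n_eval = perfect = 0
    rhos: list[float] = []
    for contig in assembly.contigs:
        if not labels[contig.contig_id]:
            continue
        n_eval += 1
        if _perfectly_ordered(contig, tm):
            perfect += 1
        starts = [tm[c].start for c in contig.clones]
        if len(starts) >= 3 and len(set(starts)) > 1:
            rho = spearmanr(range(len(starts)), starts).statistic
            rhos.append(abs(float(rho)))
        else:
            rhos.append(1.0)
    if n_eval == 0:
        return 0.0, 0.0
    return perfect / n_eval, float(np.mean(rhos))


def clone_assignment_recall(
    assembly: Assembly,
    truth: TruthSet | Sequence[CloneInterval],
    min_overlap_frac: float = 0.4,
) -> float:
    """Of clones with a substantially overlapping partner, the fraction
    co-assembled with at least one such partner.

    Two clones are partners when their true overlap is at least
    ``min_overlap_frac`` of the smaller insert — deep enough that the
    fingerprints must share a large band set.
    """
    tm = _truth_map(truth)
    present = sorted(assembly.clone_ids())
    ivs = [tm[c] for c in present]
    by_rep: dict[str, list[CloneInterval]] = {}
    for iv in ivs:
        by_rep.setdefault(iv.replicon, []).append(iv)
    partners: dict[str, set[str]] = {c: set() for c in present}
    for rep_ivs in by_rep.values():
        rep_ivs.sort(key=lambda iv: iv.start)
        for i, a in enumerate(rep_ivs):
            for b in rep_ivs[i + 1:]:
                if b.start >= a.end:
                    break
                ov = min(a.end, b.end) - b.start
                smaller = min(a.end - a.start, b.end - b.start)
                if ov >= min_overlap_frac * smaller:
                    partners[a.clone_id].add(b.clone_id)
                    partners[b.clone_id].add(a.clone_id)
    contig_of: dict[str, int] = {}
    for contig in assembly.contigs:
        for c in contig.clones:
            contig_of[c] = contig.contig_id
    n_with = n_ok = 0
    for c in present:
        if not partners[c]:
            continue
        n_with += 1
        cid = contig_of.get(c)
        if cid is not None and any(contig_of.get(p) == cid for p in partners[c]):
            n_ok += 1
    return n_ok / n_with if n_with else 1.0


def genome_fraction_covered(
    assembly: Assembly, truth: TruthSet, gap_kb: float = 0.0
) -> float:
    """Genome fraction under the union of non-chimeric contigs' clones."""
    tm = truth.interval_of()
    labels = label_chimeras(assembly, truth, gap_kb)
    by_rep: dict[str, list[tuple[int, int]]] = {}
    for contig in assembly.contigs:
        if not labels[contig.contig_id]:
            continue
        for c in contig.clones:
            iv = tm[c]
            by_rep.setdefault(iv.replicon, []).append((iv.start, iv.end))
    covered = 0
    for spans in by_rep.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    return covered / sum(truth.replicon_lengths.values())


def marker_consistency(
    assembly: Assembly,
    truth: TruthSet,
    n_markers: int = 200,
    seed: int = 0,
    span_factor: float = 1.5,
) -> tuple[float | None, pd.DataFrame]:
    """Drop uniform marker points; check contigs with >= 2 markers co-locate.

    A marker lies in a contig when inside any member clone's true
    interval. A contig is consistent iff all its markers share one
    replicon and span at most ``span_factor`` times the contig's true
    extent there — the analog of microsatellites from one contig mapping
    to a single linkage group at sensible distances. Returns None when no
    contig holds two markers.
    """
    rng = np.random.default_rng(seed)
    reps = sorted(truth.replicon_lengths)
    lengths = np.array([truth.replicon_lengths[r] for r in reps], dtype=float)
    rep_idx = rng.choice(len(reps), size=n_markers, p=lengths / lengths.sum())
    pos = rng.uniform(0.0, lengths[rep_idx])
    markers = [(reps[i], float(p)) for i, p in zip(rep_idx, pos)]

    tm = truth.interval_of()
    rows = []
    for contig in assembly.contigs:
        ivs = [tm[c] for c in contig.clones]
        hits = [
            (rep, p)
            for rep, p in markers
            if any(iv.replicon == rep and iv.start <= p < iv.end for iv in ivs)
        ]
        if len(hits) < 2:
            continue
        marker_reps = {rep for rep, _ in hits}
        if len(marker_reps) > 1:
            consistent = False
        else:
            rep = next(iter(marker_reps))
            span = max(p for _, p in hits) - min(p for _, p in hits)
            member = [iv for iv in ivs if iv.replicon == rep]
            true_span = max(iv.end for iv in member) - min(iv.start for iv in member)
            consistent = span <= span_factor * true_span
        rows.append(
            {
                "contig_id": contig.contig_id,
                "n_markers": len(hits),
                "n_replicons": len(marker_reps),
                "consistent": consistent,
            }
        )
    table = pd.DataFrame(
        rows, columns=["contig_id", "n_markers", "n_replicons", "consistent"]
    )
    if not rows:
        return None, table
    return float(table["consistent"].mean()), table


def evaluate_assembly(
    assembly: Assembly,
    truth: TruthSet,
    gap_kb: float = 0.0,
    n_markers: int = 200,
    seed: int = 0,
) -> EvalReport:
    """All truth-based metrics in one report."""
    labels = label_chimeras(assembly, truth, gap_kb)
    n_contigs = len(labels)
    chim = (
        sum(1 for ok in labels.values() if not ok) / n_contigs if n_contigs else 0.0
    )
    junc, junc_table = validate_junctions(assembly, truth)
    acc, rho = order_accuracy(assembly, truth, gap_kb)
    marker, marker_table = marker_consistency(assembly, truth, n_markers, seed)
    return EvalReport(
        chimera_rate=chim,
        junction_true_fraction=junc,
        n_junctions=len(junc_table),
        order_accuracy=acc,
        mean_rank_correlation=rho,
        clone_assignment_recall=clone_assignment_recall(assembly, truth),
        genome_fraction_covered=genome_fraction_covered(assembly, truth, gap_kb),
        marker_consistency=marker,
        n_marker_contigs=len(marker_table),
    )
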