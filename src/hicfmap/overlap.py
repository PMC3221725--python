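"""Shared-band counting and the Sulston overlap probability.

Two clones that overlap in the genome share restriction fragments, hence
bands of near-identical size in the same fluorescent channel. The Sulston
score is the probability of observing at least the seen number of shared
bands if the two fingerprints were unrelated, with band positions uniform
over ``G`` effective positions ("gellen"). Writing ``p = 1 - (1 - 2t/G)^nH``
for the chance that one band of the smaller fingerprint (nL bands) lands
within tolerance ``t`` of any band of the larger (nH bands), the score for
``m`` shared bands is the binomial tail

    S = sum_{k=m}^{nL} C(nL, k) p^k (1 - p)^(nL - k).

Tiny scores (1e-40 and far below) are routine, so the tail is accumulated
in log space. ``G`` defaults to 1800: four labeled channels times the
450-bp sizing window, each position resolvable at the file's 0.1-bp grid
only up to the matching tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .sizes_io import Fingerprint, N_CHANNELS

__all__ = [
    "ScoreParams",
    "Edge",
    "shared_band_count",
    "shared_sorted_count",
    "sulston_score",
    "score_all_pairs",
]

#: Scores whose log-space tail falls below this are reported as exactly 0.
_SCORE_FLOOR = 1e-300


@dataclass(frozen=True)
class ScoreParams:
    """Parameters of the chance-overlap model.

    tolerance
        Band size matching tolerance in bp (0.4 by default).
    gellen
        Effective number of distinguishable band positions; default
        4 channels x 450 bp window = 1800.
    cutoff
        Score threshold below which a pair is reported as an edge.
    """

    tolerance: float = 0.4
    gellen: float = 1800.0
    cutoff: float = 1e-15

    def __post_init__(self) -> None:
        if not 0.0 < 2.0 * self.tolerance / self.gellen < 1.0:
            raise ValueError("require 0 < 2*tolerance/gellen < 1")
        if not 0.0 < self.cutoff <= 1.0:
            raise ValueError("cutoff must be in (0, 1]")


class Edge(NamedTuple):
    """A scored clone pair: ids, band counts (nL <= nH), shared count, score."""

    a: str
    b: str
    n_low: int
    n_high: int
    shared: int
    score: float


def shared_sorted_count(a: Sequence[float], b: Sequence[float], tolerance: float) -> int:
    """Greedy sweep match count between two ascending size lists.

    Advance whichever head is smaller; match (and consume both) when the
    heads agree within tolerance. Each band is used at most once. For
    threshold matching on a line this greedy attains the maximum bipartite
    matching (exchange argument on the two least heads).
    """
    i = j = m = 0
    na, nb = len(a), len(b)
    while i < na and j < nb:
        d = a[i] - b[j]
        if d < -tolerance:
            i += 1
        elif d > tolerance:
            j += 1
        else:
            m += 1
            i += 1
            j += 1
    return m


def shared_band_count(fp_a: Fingerprint, fp_b: Fingerprint, tolerance: float = 0.4) -> int:
    """Channel-aware shared-band count between two fingerprints."""
    ca, cb = fp_a.channel_sizes(), fp_b.channel_sizes()
    return sum(shared_sorted_count(ca[ch], cb[ch], tolerance) for ch in range(N_CHANNELS))


def sulston_score(n_low: int, n_high: int, shared: int, params: ScoreParams) -> float:
    """Probability of >= ``shared`` chance matches between unrelated clones.

    Exact binomial tail computed with log-space accumulation; values below
    1e-300 are reported as 0.0. ``shared == 0`` gives exactly 1.0.
    """
    if not 0 <= shared <= n_low <= n_high:
        raise ValueError(
            f"require 0 <= m <= nL <= nH, got m={shared}, nL={n_low}, nH={n_high}"
        )
    if shared == 0:
        return 1.0
    # chance that one band of the smaller clone matches any band of the larger
    log1m_q = n_high * np.log1p(-2.0 * params.tolerance / params.gellen)
    p = -np.expm1(log1m_q)
    log_p = np.log(p)
    log_1mp = log1m_q  # log(1 - p)
    k = np.arange(shared, n_low + 1)
    log_binom = gammaln(n_low + 1) - gammaln(k + 1) - gammaln(n_low - k + 1)
    log_terms = log_binom + k * log_p + (n_low - k) * log_1mp
    log_score = float(logsumexp(log_terms))
    if log_score >= 0.0:
        return 1.0
    score = float(np.exp(log_score))
    return score if score >= _SCORE_FLOOR else 0.0


def _score_pair_cached(
    n_low: int, n_high: int, shared: int, params: ScoreParams, cache: dict
) -> float:
    key = (n_low, n_high, shared)
    s = cache.get(key)
    if s is None:
        s = sulston_score(n_low, n_high, shared, params)
        cache[key] = s
    return s


def score_all_pairs(
    fingerprints: Sequence[Fingerprint], params: ScoreParams
) -> list[Edge]:
    """Score every clone pair sharing at least one band; keep score <= cutoff.

    Candidate pairs are generated by bucketing band values at the tolerance
    granularity per channel: two bands within tolerance always fall in the
    same or adjacent buckets, so the pruning is lossless with respect to a
    brute-force all-pairs scan. Exact with respect to
    :func:`sulston_score`. Edges come back sorted by (a, b) clone id.
    """
    if len(fingerprints) < 2:
        return []
    order = sorted(range(len(fingerprints)), key=lambda i: fingerprints[i].clone_id)
    fps = [fingerprints[i] for i in order]
    channel_lists = [fp.channel_sizes() for fp in fps]
    n_bands = [fp.n_bands for fp in fps]

    tol = params.tolerance
    buckets: dict[tuple[int, int], list[int]] = {}
    for idx, chans in enumerate(channel_lists):
        keys = set()
        for ch in range(N_CHANNELS):
            for size in chans[ch]:
                keys.add((ch, int(size // tol)))
        for key in keys:
            buckets.setdefault(key, []).append(idx)

    candidates: set[tuple[int, int]] = set()
    for (ch, slot), members in buckets.items():
        for ii, a in enumerate(members):
            for b in members[ii + 1:]:
                candidates.add((a, b))
        nxt = buckets.get((ch, slot + 1))
        if nxt:
            for a in members:
                for b in nxt:
                    if a != b:
                        candidates.add((min(a, b), max(a, b)))

    cache: dict[tuple[int, int, int], float] = {}
    edges: list[Edge] = []
    for a, b in sorted(candidates):
        la, lb = channel_lists[a], channel_lists[b]
        m = sum(shared_sorted_count(la[ch], lb[ch], tol) for ch in range(N_CHANNELS))
        if m == 0:
            continue
        n_low, n_high = min(n_bands[a], n_bands[b]), max(n_bands[a], n_bands[b])
        score = _score_pair_cached(n_low, n_high, m, params, cache)
        if score <= params.cutoff:
            edges.append(
                Edge(fps[a].clone_id, fps[b].clone_id, n_low, n_high, m, score)
            )
    edges.sort(key=lambda e: (e.a, e.b))
    return edges
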