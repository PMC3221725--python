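"""Fingerprint quality control for HICF capillary data.

The cascade mirrors what fingerprint-processing software applies before
contig assembly, in a fixed, logged order:

1. frequent-band removal — vector fragments and high-frequency repeat
   fragments are found by clustering band values per channel (single
   linkage at the size tolerance) and removing every class present in
   more than a configurable fraction of clones;
2. per-clone screening — empty wells dropped; off-scale bands (peak
   height above 6,000 RFU) removed; clones with fewer than 50 or more
   than 250 remaining bands dropped; clones with more than 60 bands in
   any one fluorescent channel dropped (a contamination signature);
3. cross-contamination — same-plate clone pairs sharing at least 80% of
   the smaller fingerprint's bands are both removed.

Frequent-band removal runs first so that vector bands can neither rescue
nor doom clones sitting near the band-count thresholds. All thresholds
are strict inequalities. Every input clone is accounted for exactly once
in the report, and the cascade is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

from .overlap import shared_band_count
from .sizes_io import Fingerprint, N_CHANNELS

__all__ = [
    "QcParams",
    "QcReport",
    "ScreenResult",
    "BandClass",
    "screen_fingerprint",
    "detect_contamination",
    "prune_frequent_bands",
    "run_qc",
]

MIN_CLONES_FOR_FREQUENCY = 20


@dataclass(frozen=True)
class QcParams:
    """Thresholds of the QC cascade (defaults follow standard HICF practice)."""

    min_bands: int = 50
    max_bands: int = 250
    max_per_channel: int = 60
    max_height_rfu: float = 6000.0
    contamination_similarity: float = 0.8
    # a contaminated well carries the union of two fingerprints, so its
    # band count is ~2x its source's; requiring this ratio separates true
    # cross-contamination from genuine deep overlaps between same-plate
    # clones (which have ordinary band counts)
    contamination_count_ratio: float = 1.5
    # a band-size window is "frequent" above this clone fraction. The
    # ceiling of chance window frequencies is ~mean + 4 sd of the
    # per-window clone count, where locus granularity (each genomic
    # fragment is carried by ~coverage clones at once) inflates the sd;
    # at deep coverage that ceiling is ~25%, while vector and repeat
    # families sit at >=50%.
    frequent_band_fraction: float = 0.30
    tolerance: float = 0.4

    def __post_init__(self) -> None:
        if not 0 < self.min_bands < self.max_bands:
            raise ValueError("need 0 < min_bands < max_bands")
        if self.max_per_channel <= 0 or self.max_height_rfu <= 0 or self.tolerance <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.contamination_similarity <= 1:
            raise ValueError("contamination_similarity must be in (0, 1]")


class BandClass(NamedTuple):
    """A frequent-band class removed by frequency analysis."""

    channel: int
    lo: float
    hi: float
    clone_fraction: float


class ScreenResult(NamedTuple):
    """Outcome of per-clone screening: verdict plus band-level edits."""

    keep: bool
    reason: str | None
    fingerprint: Fingerprint
    n_offscale_removed: int


@dataclass
class QcReport:
    """Per-rule accounting of the cascade; totals reconcile by construction."""

    n_input: int = 0
    n_pass: int = 0
    dropped: dict[str, int] = field(
        default_factory=lambda: {
            "empty": 0,
            "band_count": 0,
            "per_channel": 0,
            "contamination": 0,
        }
    )
    offscale_bands_removed: int = 0
    frequent_band_classes: list[BandClass] = field(default_factory=list)
    frequent_bands_removed: int = 0
    dropped_ids: dict[str, list[str]] = field(default_factory=dict)

    @property
    def pass_rate(self) -> float:
        return self.n_pass / self.n_input if self.n_input else 0.0

    def check(self) -> None:
        """Conservation: input = survivors + sum of clone-level removals."""
        total = self.n_pass + sum(self.dropped.values())
        if total != self.n_input:
            raise AssertionError(
                f"QC accounting broken: {self.n_input} in, {total} accounted"
            )


def screen_fingerprint(fp: Fingerprint, params: QcParams) -> ScreenResult:
    """Apply the per-clone rules in order; verdict carries the first failure.

    Order: empty well -> off-scale band removal -> band-count window ->
    per-channel cap. Total function: never raises on any fingerprint.
    """
    if fp.n_bands == 0:
        return ScreenResult(False, "empty", fp, 0)
    kept = [
        b for b in fp.bands if b.height is None or b.height <= params.max_height_rfu
    ]
    n_off = fp.n_bands - len(kept)
    out = Fingerprint(fp.clone_id, kept, fp.plate, fp.well)
    if len(kept) < params.min_bands or len(kept) > params.max_bands:
        return ScreenResult(False, "band_count", out, n_off)
    per_channel = [0] * N_CHANNELS
    for b in kept:
        per_channel[b.channel] += 1
    if max(per_channel) > params.max_per_channel:
        return ScreenResult(False, "per_channel", out, n_off)
    return ScreenResult(True, None, out, n_off)


def detect_contamination(
    fingerprints: Sequence[Fingerprint], params: QcParams
) -> set[str]:
    """Flag same-plate pairs that look like well-to-well contamination.

    A pair is flagged when shared bands cover at least
    ``contamination_similarity`` of the smaller fingerprint (channel-
    aware, at the size tolerance) and either (a) the larger fingerprint
    carries ``contamination_count_ratio`` times the smaller's bands —
    the union signature of a well that received a second clone's DNA on
    top of its own — or (b) the shared bands also cover that fraction of
    the larger fingerprint — a full replacement / duplicate well. The
    two-sided condition keeps genuine deep overlaps between neighboring
    clones (common in a deeply covered library) from being flagged.
    Both members of a flagged pair are removed (the source well cannot
    be distinguished with certainty). Cross-contamination is a
    within-plate phenomenon (liquid handling), so different-plate
    lookalikes are never flagged.
    """
    by_plate: dict[str, list[Fingerprint]] = {}
    for fp in fingerprints:
        by_plate.setdefault(fp.plate, []).append(fp)
    flagged: set[str] = set()
    for plate in sorted(by_plate):
        members = sorted(by_plate[plate], key=lambda f: f.clone_id)
        for i, fa in enumerate(members):
            for fb in members[i + 1:]:
                smaller = min(fa.n_bands, fb.n_bands)
                larger = max(fa.n_bands, fb.n_bands)
                if smaller == 0:
                    continue
                shared = shared_band_count(fa, fb, params.tolerance)
                if shared / smaller < params.contamination_similarity:
                    continue
                union_like = larger >= params.contamination_count_ratio * smaller
                duplicate_like = shared / larger >= params.contamination_similarity
                if union_like or duplicate_like:
                    flagged.add(fa.clone_id)
                    flagged.add(fb.clone_id)
    return flagged


def prune_frequent_bands(
    fingerprints: Sequence[Fingerprint], params: QcParams
) -> tuple[list[Fingerprint], list[BandClass]]:
    """Remove band-size windows present in too many clones (vector/repeats).

    Fragment frequency analysis, per channel: slide a window of width
    2 x tolerance over the sorted band values and count the fraction of
    distinct clones carrying a band inside it; while the most frequent
    window exceeds ``frequent_band_fraction``, remove every band in it
    and rescan. Iterative window removal (rather than single-linkage
    clustering of the pooled values) is required at realistic coverage:
    with ~25 bands per channel per clone the pooled values of a few
    hundred clones chain into one cluster at any usable tolerance.
    Requires at least 20 fingerprints — frequency is meaningless below.
    """
    n = len(fingerprints)
    if n < MIN_CLONES_FOR_FREQUENCY:
        raise ValueError(
            f"frequency analysis needs >= {MIN_CLONES_FOR_FREQUENCY} fingerprints, got {n}"
        )
    width = 2.0 * params.tolerance
    removed: list[BandClass] = []
    # working copy of band lists per clone
    bands_of: list[list] = [list(fp.bands) for fp in fingerprints]
    for ch in range(N_CHANNELS):
        while True:
            values = sorted(
                (b.size, idx)
                for idx, bl in enumerate(bands_of)
                for b in bl
                if b.channel == ch
            )
            if not values:
                break
            best = None  # (-count, lo_index)
            counts: dict[int, int] = {}
            j = 0
            for i, (lo, _idx) in enumerate(values):
                while j < len(values) and values[j][0] <= lo + width:
                    counts[values[j][1]] = counts.get(values[j][1], 0) + 1
                    j += 1
                if i > 0:
                    prev = values[i - 1][1]
                    counts[prev] -= 1
                    if counts[prev] == 0:
                        del counts[prev]
                cand = (-len(counts), i)
                if best is None or cand < best:
                    best = cand
            count = -best[0]
            if count / n <= params.frequent_band_fraction:
                break
            lo = values[best[1]][0]
            hi = lo + width
            removed.append(BandClass(ch, lo, hi, count / n))
            for idx, bl in enumerate(bands_of):
                bands_of[idx] = [
                    b for b in bl if not (b.channel == ch and lo <= b.size <= hi)
                ]
    out = [
        Fingerprint(fp.clone_id, bl, fp.plate, fp.well)
        for fp, bl in zip(fingerprints, bands_of)
    ]
    removed.sort(key=lambda c: (c.channel, c.lo))
    return out, removed


def run_qc(
    fingerprints: Sequence[Fingerprint], params: QcParams | None = None
) -> tuple[list[Fingerprint], QcReport]:
    """Full cascade: frequent-band pruning -> screening -> contamination."""
    params = params or QcParams()
    report = QcReport(n_input=len(fingerprints))
    pruned, classes = prune_frequent_bands(fingerprints, params)
    report.frequent_band_classes = classes
    report.frequent_bands_removed = sum(
        a.n_bands - b.n_bands for a, b in zip(fingerprints, pruned)
    )

    screened: list[Fingerprint] = []
    for fp in pruned:
        res = screen_fingerprint(fp, params)
        report.offscale_bands_removed += res.n_offscale_removed
        if res.keep:
            screened.append(res.fingerprint)
        else:
            report.dropped[res.reason] += 1
            report.dropped_ids.setdefault(res.reason, []).append(fp.clone_id)

    contaminated = detect_contamination(screened, params)
    survivors = [fp for fp in screened if fp.clone_id not in contaminated]
    report.dropped["contamination"] = len(contaminated)
    report.dropped_ids["contamination"] = sorted(contaminated)
    report.n_pass = len(survivors)
    report.check()
    return survivors, report
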