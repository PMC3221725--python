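"""Summary statistics of a fingerprint physical-map assembly.

Computes the standard table of map statistics — clone and contig counts,
mean clones and consensus bands (CB) per contig, the kb each band
represents (mean insert size over mean band count), contig physical
lengths (CB count x kb per band), N50, total assembled length — plus the
distribution of Q-clones over contigs and the band-count and
contig-size histograms.

Rounding conventions are fixed per field so that the same aggregates
always print the same table: kb-per-band is truncated (not rounded) at 3
decimals; per-contig means are rounded half-up to 2 decimals; CB means to
the nearest integer; percentages of contigs to 1 decimal (half-up); the
fingerprinting pass rate to the nearest integer percent; total assembled
length to 3 significant figures in Gb.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assemble import Assembly
from .sizes_io import Fingerprint

__all__ = [
    "MapStats",
    "kb_per_band",
    "n50",
    "contig_stats",
    "stats_from_totals",
    "q_distribution",
    "summarize_distributions",
]


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _trunc(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_DOWN))


def kb_per_band(mean_insert_kb: float, mean_bands_per_clone: float) -> float:
    """Kilobases represented by one band: insert size over band count.

    Reported truncated (floored) to 3 decimals; e.g. 141 kb inserts at
    98.7 bands per clone give 1.428 kb per band.
    """
    if mean_insert_kb <= 0 or mean_bands_per_clone <= 0:
        raise ValueError("inputs must be positive")
    return _trunc(mean_insert_kb / mean_bands_per_clone, 3)


def n50(contig_lengths_kb: Sequence[float]) -> tuple[float, int]:
    """N50 length and the number of contigs strictly longer than it.

    N50 is the length of the contig at which the cumulative sum of
    descending-sorted lengths first reaches half the total.
    """
    lengths = sorted(contig_lengths_kb, reverse=True)
    if not lengths:
        raise ValueError("n50 of an empty length list")
    half = sum(lengths) / 2.0
    acc = 0.0
    value = lengths[-1]
    for length in lengths:
        acc += length
        if acc >= half:
            value = length
            break
    longer = sum(1 for length in lengths if length > value)
    return value, longer


@dataclass
class MapStats:
    """The summary-table record of one assembly."""

    n_fingerprinted: int | None
    n_valid: int
    pass_rate_pct: int | None
    n_contigs: int
    n_clones_in_contigs: int
    n_singletons: int
    mean_clones_per_contig: float
    mean_cb_per_contig: int
    mean_bands_per_clone: float
    kb_per_band: float
    mean_contig_kb: float
    n50_kb: float
    n_contigs_longer_than_n50: int
    total_cb: int
    total_length_gb: float
    cb_per_assembled_clone: float
    kb_per_assembled_clone: int
    coverage_x: float | None
    q_contigs: int
    q_clones: int
    q_free_contigs: int

    def check(self) -> None:
        assert self.n_valid == self.n_clones_in_contigs + self.n_singletons
        assert self.q_free_contigs + self.q_contigs == self.n_contigs


def _derived(
    n_fingerprinted: int | None,
    n_valid: int,
    n_contigs: int,
    n_clones_in_contigs: int,
    mean_insert_kb: float,
    mean_bands_per_clone: float,
    total_cb: int,
) -> dict:
    kpb = kb_per_band(mean_insert_kb, mean_bands_per_clone)
    out = {
        "pass_rate_pct": (
            int(_round_half_up(100.0 * n_valid / n_fingerprinted, 0))
            if n_fingerprinted
            else None
        ),
        "n_singletons": n_valid - n_clones_in_contigs,
        "mean_clones_per_contig": _round_half_up(n_clones_in_contigs / n_contigs, 2),
        "mean_cb_per_contig": int(_round_half_up(total_cb / n_contigs, 0)),
        "kb_per_band": kpb,
        "total_length_gb": float(f"{total_cb * kpb / 1e6:.3g}"),
        "cb_per_assembled_clone": _trunc(total_cb / n_clones_in_contigs, 1),
        "kb_per_assembled_clone": int(
            _round_half_up(total_cb / n_clones_in_contigs * kpb, 0)
        ),
    }
    return out


def stats_from_totals(
    *,
    n_fingerprinted: int,
    n_valid: int,
    n_contigs: int,
    n_clones_in_contigs: int,
    mean_insert_kb: float,
    mean_bands_per_clone: float,
    total_cb: int,
    q_free_contigs: int | None = None,
) -> dict:
    """All statistics derivable from printed whole-map aggregates.

    This is the arithmetic backbone of the summary table: feeding it the
    aggregates of a published map reproduces that table's derived rows.
    """
    out = _derived(
        n_fingerprinted,
        n_valid,
        n_contigs,
        n_clones_in_contigs,
        mean_insert_kb,
        mean_bands_per_clone,
        total_cb,
    )
    if q_free_contigs is not None:
        out["q_free_pct"] = _round_half_up(100.0 * q_free_contigs / n_contigs, 1)
    return out


def contig_stats(
    assembly: Assembly,
    fingerprints: Sequence[Fingerprint] | Mapping[str, Fingerprint],
    *,
    mean_insert_kb: float = 141.0,
    n_fingerprinted: int | None = None,
    genome_size_gb: float | None = None,
) -> MapStats:
    """Compute the full statistics table from an assembly and its fingerprints.

    ``n_fingerprinted`` (pre-QC well count) enables the pass rate;
    ``genome_size_gb`` enables coverage (reported, never asserted — genome
    size estimates are external constants).
    """
    if isinstance(fingerprints, Mapping):
        fps = dict(fingerprints)
    else:
        fps = {fp.clone_id: fp for fp in fingerprints}
    n_valid = len(fps)
    contigs = assembly.contigs
    n_contigs = len(contigs)
    if n_contigs == 0:
        raise ValueError("assembly has no contigs")
    n_in = sum(c.n_clones for c in contigs)
    mean_bands = float(np.mean([fp.n_bands for fp in fps.values()]))
    total_cb = sum(c.cb_count for c in contigs)
    d = _derived(
        n_fingerprinted,
        n_valid,
        n_contigs,
        n_in,
        mean_insert_kb,
        float(_round_half_up(mean_bands, 1)),
        total_cb,
    )
    lengths_kb = [c.cb_count * d["kb_per_band"] for c in contigs]
    n50_kb, n_longer = n50(lengths_kb)
    q_contigs = sum(1 for c in contigs if c.n_q > 0)
    coverage = None
    if genome_size_gb:
        coverage = round(n_valid * mean_insert_kb / (genome_size_gb * 1e6), 1)
    stats = MapStats(
        n_fingerprinted=n_fingerprinted,
        n_valid=n_valid,
        pass_rate_pct=d["pass_rate_pct"],
        n_contigs=n_contigs,
        n_clones_in_contigs=n_in,
        n_singletons=len(assembly.singletons),
        mean_clones_per_contig=d["mean_clones_per_contig"],
        mean_cb_per_contig=d["mean_cb_per_contig"],
        mean_bands_per_clone=float(_round_half_up(mean_bands, 1)),
        kb_per_band=d["kb_per_band"],
        mean_contig_kb=_round_half_up(float(np.mean(lengths_kb)), 0),
        n50_kb=_round_half_up(n50_kb, 0),
        n_contigs_longer_than_n50=n_longer,
        total_cb=total_cb,
        total_length_gb=d["total_length_gb"],
        cb_per_assembled_clone=d["cb_per_assembled_clone"],
        kb_per_assembled_clone=d["kb_per_assembled_clone"],
        coverage_x=coverage,
        q_contigs=q_contigs,
        q_clones=sum(c.n_q for c in contigs),
        q_free_contigs=n_contigs - q_contigs,
    )
    stats.check()
    return stats


#: Q-clones-per-contig buckets of the distribution table.
_Q_BUCKETS = (0, 1, 2, 3, 4, 5)


def q_distribution(assembly: Assembly) -> pd.DataFrame:
    """Contigs bucketed by Q-clone count (0,1,...,5,>5) with percentages.

    Percentages are count / all contigs x 100, half-up to 1 decimal.
    """
    n_contigs = len(assembly.contigs)
    if n_contigs == 0:
        raise ValueError("assembly has no contigs")
    counts = {b: 0 for b in _Q_BUCKETS}
    over = 0
    for c in assembly.contigs:
        if c.n_q in counts:
            counts[c.n_q] += 1
        else:
            over += 1
    rows = [
        {
            "q_clones_per_contig": str(b),
            "n_contigs": counts[b],
            "pct_of_contigs": _round_half_up(100.0 * counts[b] / n_contigs, 1),
        }
        for b in _Q_BUCKETS
    ] + [
        {
            "q_clones_per_contig": ">5",
            "n_contigs": over,
            "pct_of_contigs": _round_half_up(100.0 * over / n_contigs, 1),
        }
    ]
    return pd.DataFrame(rows)


def summarize_distributions(
    fingerprints: Sequence[Fingerprint],
    assembly: Assembly,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Band-count histogram (bin width 10) and clones-per-contig histogram."""
    band_counts = np.array([fp.n_bands for fp in fingerprints])
    hi = int(band_counts.max() // 10 + 1) * 10 if len(band_counts) else 10
    edges = np.arange(0, hi + 10, 10)
    hist, _ = np.histogram(band_counts, bins=edges)
    bands_df = pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "n_clones": hist}
    )
    sizes = sorted(c.n_clones for c in assembly.contigs)
    size_df = (
        pd.Series(sizes, name="clones_per_contig")
        .value_counts()
        .sort_index()
        .rename("n_contigs")
        .reset_index()
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        bands_df.to_csv(out_dir / "band_count_hist.tsv", sep="\t", index=False)
        size_df.to_csv(out_dir / "contig_size_hist.tsv", sep="\t", index=False)
    return bands_df, size_df
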