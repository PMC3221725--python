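"""Synthetic BAC library and HICF fingerprint generator with ground truth.

The simulator works at the coordinate level: restriction sites of the four
labeled 6-bp cutters (EcoRI, XbaI, BamHI, XhoI) and of the unlabeled 4-bp
cutter (HaeIII) are drawn as independent Poisson processes along each
replicon. A clone's fingerprint is the set of fragments between
consecutive cut sites inside its insert; every fragment end that is a
labeled-enzyme site emits one band in that enzyme's channel (a fragment
cut by 6-bp cutters at both ends emits two single-channel bands, matching
channel-wise peak calling), and only fragments inside the capillary sizing
window are retained. Fragments touching the insert boundaries stand in
for vector-junction fragments and are excluded.

On top of the clean fingerprints the generator plants exactly the artifact
classes the downstream QC cascade must remove: sizing noise, band dropout,
spurious peaks, empty wells, well-to-well cross-contamination (the donor
clone is drawn from the same plate), off-scale peaks, vector bands common
to every clone, and a high-frequency repeat-band family. All randomness
flows from one seeded generator, so a fixed seed reproduces the dataset
byte for byte.

The default six-cutter site density (1.265e-4 per bp per enzyme, about one
site per 7.9 kb) is lower than the naive 4^-6 expectation for a random
sequence: 6-bp palindromes containing CG dinucleotides (XhoI, BamHI) are
strongly under-represented in AT-rich fish genomes. The default is
calibrated so a 141-kb insert carries ~98.5 bands in expectation, with
most clones in the 60-120 band range typical of four-color HICF.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .sizes_io import (
    Band,
    CloneInterval,
    Fingerprint,
    N_CHANNELS,
    write_clone_meta,
    write_sizes,
    write_truth,
)

__all__ = [
    "SimParams",
    "SiteMap",
    "TruthSet",
    "SimOutput",
    "simulate_site_map",
    "sample_clones",
    "fingerprint_clone",
    "corrupt_fingerprints",
    "expected_bands_per_clone",
    "emit_dataset",
]

#: Artifact labels recorded in the truth set, mutually exclusive.
ARTIFACT_LABELS = ("clean", "empty", "contaminated", "offscale", "vector_only")

#: Planted vector band family (channel, size bp): present in every clone.
DEFAULT_VECTOR_BANDS = ((0, 73.4), (1, 210.6), (2, 388.1), (3, 131.9))
#: Planted repeat band family: present in a large fraction of clones.
DEFAULT_REPEAT_BANDS = ((0, 156.4), (2, 301.9))

_WELL_ROWS = "ABCDEFGH"


@dataclass(frozen=True)
class SimParams:
    """All knobs of the simulated fingerprinting experiment.

    Lengths are bp, rates are per bp, fractions are probabilities. The
    seed is mandatory: every dataset is reproducible by construction.
    """

    seed: int
    genome_length: int = 10_000_000
    n_replicons: int = 2
    n_clones: int = 710
    insert_mean: float = 141_000.0
    insert_cv: float = 0.15
    six_cutter_rate: float = 1.265e-4
    four_cutter_rate: float = 4.0 ** -4
    window_lo: float = 50.0
    window_hi: float = 500.0
    size_noise_sd: float = 0.15
    dropout_prob: float = 0.05
    spurious_per_clone: float = 2.0
    frac_empty: float = 0.005
    frac_contaminated: float = 0.005
    frac_offscale: float = 0.005
    frac_vector_only: float = 0.005
    repeat_fraction: float = 0.50
    vector_bands: tuple[tuple[int, float], ...] = DEFAULT_VECTOR_BANDS
    repeat_bands: tuple[tuple[int, float], ...] = DEFAULT_REPEAT_BANDS
    plate_size: int = 96
    height_log_mean: float = math.log(1200.0)
    height_log_sd: float = 0.6
    offscale_height: float = 6500.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "dropout_prob",
            "frac_empty",
            "frac_contaminated",
            "frac_offscale",
            "frac_vector_only",
            "repeat_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.artifact_fraction_total > 1.0:
            raise ValueError("artifact fractions sum above 1")
        if self.six_cutter_rate < 0 or self.four_cutter_rate < 0:
            raise ValueError("site rates must be >= 0")
        if self.genome_length < self.insert_mean:
            raise ValueError("genome_length smaller than mean insert size")
        if not 0 < self.window_lo < self.window_hi:
            raise ValueError("need 0 < window_lo < window_hi")

    @property
    def artifact_fraction_total(self) -> float:
        return (
            self.frac_empty
            + self.frac_contaminated
            + self.frac_offscale
            + self.frac_vector_only
        )

    def noiseless(self, **overrides) -> "SimParams":
        """A copy with all noise and artifact planting switched off."""
        clean = dict(
            size_noise_sd=0.0,
            dropout_prob=0.0,
            spurious_per_clone=0.0,
            frac_empty=0.0,
            frac_contaminated=0.0,
            frac_offscale=0.0,
            frac_vector_only=0.0,
            repeat_fraction=0.0,
            vector_bands=(),
            repeat_bands=(),
        )
        clean.update(overrides)
        return replace(self, **clean)


@dataclass
class SiteMap:
    """Per-replicon sorted restriction-site coordinates.

    ``sites[replicon]`` holds five ascending float arrays: indices 0..3
    are the labeled 6-bp cutters (channel order), index 4 the unlabeled
    4-bp cutter.
    """

    replicon_lengths: dict[str, int]
    sites: dict[str, list[np.ndarray]]

    def site_counts(self) -> dict[str, list[int]]:
        return {rep: [len(s) for s in arrs] for rep, arrs in self.sites.items()}


@dataclass
class TruthSet:
    """Ground truth: replicon lengths, clone placements, artifact labels."""

    replicon_lengths: dict[str, int]
    intervals: list[CloneInterval]
    labels: dict[str, str] = field(default_factory=dict)
    site_counts: dict[str, list[int]] = field(default_factory=dict)

    def interval_of(self) -> dict[str, CloneInterval]:
        return {iv.clone_id: iv for iv in self.intervals}

    def clones_with_label(self, label: str) -> list[str]:
        return sorted(c for c, lab in self.labels.items() if lab == label)


def _replicon_names(n: int) -> list[str]:
    return [f"rep{i + 1}" for i in range(n)]


def simulate_site_map(params: SimParams, rng: np.random.Generator) -> SiteMap:
    """Draw every enzyme's sites as an independent Poisson process."""
    lengths: dict[str, int] = {}
    base = params.genome_length // params.n_replicons
    for i, name in enumerate(_replicon_names(params.n_replicons)):
        extra = params.genome_length % params.n_replicons if i == 0 else 0
        lengths[name] = base + extra
    sites: dict[str, list[np.ndarray]] = {}
    rates = [params.six_cutter_rate] * N_CHANNELS + [params.four_cutter_rate]
    for name in sorted(lengths):
        length = lengths[name]
        per_enzyme = []
        for rate in rates:
            n = rng.poisson(rate * length) if rate > 0 else 0
            per_enzyme.append(np.sort(rng.uniform(0.0, length, size=n)))
        sites[name] = per_enzyme
    return SiteMap(replicon_lengths=lengths, sites=sites)


def sample_clones(
    params: SimParams, site_map: SiteMap, rng: np.random.Generator
) -> TruthSet:
    """Place ``n_clones`` inserts uniformly; lengths ~ truncated Normal.

    Insert lengths are Normal(mean, cv * mean) truncated to
    [0.5, 1.5] x mean; starts uniform within the chosen replicon
    (replicons weighted by length). Expected coverage is
    n * mean / genome_length.
    """
    if params.n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    reps = sorted(site_map.replicon_lengths)
    lengths = np.array([site_map.replicon_lengths[r] for r in reps], dtype=float)
    probs = lengths / lengths.sum()
    lo, hi = 0.5 * params.insert_mean, 1.5 * params.insert_mean
    intervals: list[CloneInterval] = []
    labels: dict[str, str] = {}
    for i in range(params.n_clones):
        clone_id = f"c{i:05d}"
        while True:
            size = rng.normal(params.insert_mean, params.insert_cv * params.insert_mean)
            if lo <= size <= hi:
                break
        size = int(round(size))
        rep_idx = int(rng.choice(len(reps), p=probs))
        rep = reps[rep_idx]
        max_start = site_map.replicon_lengths[rep] - size
        if max_start < 0:
            raise ValueError(f"replicon {rep} shorter than a clone insert")
        start = int(rng.uniform(0, max_start + 1))
        intervals.append(CloneInterval(rep, start, start + size, clone_id))
        labels[clone_id] = "clean"
    return TruthSet(
        replicon_lengths=dict(site_map.replicon_lengths),
        intervals=intervals,
        labels=labels,
        site_counts=site_map.site_counts(),
    )


def _plate_well(index: int, plate_size: int) -> tuple[str, str]:
    plate = f"P{index // plate_size + 1:03d}"
    w = index % plate_size
    n_cols = max(1, plate_size // len(_WELL_ROWS))
    row = _WELL_ROWS[(w // n_cols) % len(_WELL_ROWS)]
    col = w % n_cols + 1
    return plate, f"{row}{col:02d}"


def fingerprint_clone(
    interval: CloneInterval,
    site_map: SiteMap,
    params: SimParams,
    rng: np.random.Generator,
) -> Fingerprint:
    """Digest one insert in silico and emit its labeled, sized bands.

    Cut positions are the union of all five enzymes' sites inside the
    insert plus the two insert boundaries. Each fragment between
    consecutive cuts contributes one band per end that is a labeled-enzyme
    site; fragments touching the boundaries are excluded; only bands whose
    size falls inside the sizing window survive. Sizes are quantized to
    0.1 bp (the instrument's reporting resolution); heights are lognormal.
    """
    rep_sites = site_map.sites[interval.replicon]
    positions = [np.array([float(interval.start), float(interval.end)])]
    enzymes = [np.array([-1, -1])]
    for enz in range(5):
        s = rep_sites[enz]
        inside = s[(s > interval.start) & (s < interval.end)]
        positions.append(inside)
        enzymes.append(np.full(len(inside), enz))
    pos = np.concatenate(positions)
    enz = np.concatenate(enzymes)
    order = np.argsort(pos, kind="stable")
    pos, enz = pos[order], enz[order]

    bands: list[Band] = []
    # fragments [pos[i], pos[i+1]]; skip the two boundary fragments
    for i in range(1, len(pos) - 2):
        size = round(float(pos[i + 1] - pos[i]), 1)
        if not params.window_lo <= size <= params.window_hi:
            continue
        for cut_enzyme in (int(enz[i]), int(enz[i + 1])):
            if 0 <= cut_enzyme < N_CHANNELS:
                height = round(
                    float(rng.lognormal(params.height_log_mean, params.height_log_sd)), 1
                )
                bands.append(Band(cut_enzyme, size, height))
    fp = Fingerprint(clone_id=interval.clone_id, bands=sorted(bands, key=lambda b: b[:2]))
    return fp


def expected_bands_per_clone(params: SimParams, insert: float | None = None) -> float:
    """Closed-form expectation of the clean band count for one insert.

    Labeled fragment-end incidences are 2 x (4 x six-cutter rate) x length;
    each survives with the probability that an Exponential(total cut rate)
    fragment length falls in the sizing window.
    """
    length = params.insert_mean if insert is None else insert
    lam = N_CHANNELS * params.six_cutter_rate + params.four_cutter_rate
    p_window = math.exp(-lam * params.window_lo) - math.exp(-lam * params.window_hi)
    return 2.0 * N_CHANNELS * params.six_cutter_rate * length * p_window


def corrupt_fingerprints(
    fingerprints: Sequence[Fingerprint],
    truth: TruthSet,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[list[Fingerprint], TruthSet]:
    """Apply sizing noise, dropout, spurious bands and planted artifacts.

    Order: per-band Gaussian size noise (bands pushed outside the window
    are lost off-ladder), per-band dropout, spurious bands, then clone
    artifacts (empty wells, same-plate contamination, off-scale heights,
    vector-only wells), then the vector band family on every clone and the
    repeat family on a random subset. Labels land in ``truth.labels``.
    """

    def _noisy_size(size: float) -> float:
        return round(size + float(rng.normal(0.0, params.size_noise_sd)), 1)

    def _height() -> float:
        return round(float(rng.lognormal(params.height_log_mean, params.height_log_sd)), 1)

    plates = {fp.clone_id: fp.plate for fp in fingerprints}
    out: list[Fingerprint] = []
    for fp in fingerprints:
        bands: list[Band] = []
        for b in fp.bands:
            size = _noisy_size(b.size)
            if not params.window_lo <= size <= params.window_hi:
                continue
            if rng.random() < params.dropout_prob:
                continue
            bands.append(Band(b.channel, size, b.height))
        for _ in range(rng.poisson(params.spurious_per_clone)):
            ch = int(rng.integers(0, N_CHANNELS))
            size = round(float(rng.uniform(params.window_lo, params.window_hi)), 1)
            bands.append(Band(ch, size, _height()))
        out.append(Fingerprint(fp.clone_id, bands, fp.plate, fp.well))

    # assign artifact labels by one uniform draw per clone
    cum_cont = params.frac_empty + params.frac_contaminated
    cum_off = cum_cont + params.frac_offscale
    cum_vec = cum_off + params.frac_vector_only
    labels: dict[str, str] = {}
    for fp in out:
        u = rng.random()
        if u < params.frac_empty:
            labels[fp.clone_id] = "empty"
        elif u < cum_cont:
            labels[fp.clone_id] = "contaminated"
        elif u < cum_off:
            labels[fp.clone_id] = "offscale"
        elif u < cum_vec:
            labels[fp.clone_id] = "vector_only"
        else:
            labels[fp.clone_id] = "clean"

    snapshot = {fp.clone_id: list(fp.bands) for fp in out}
    clean_by_plate: dict[str, list[str]] = {}
    for cid, lab in labels.items():
        if lab == "clean":
            clean_by_plate.setdefault(plates[cid], []).append(cid)
    for ids in clean_by_plate.values():
        ids.sort()
    all_clean = sorted(cid for cid, lab in labels.items() if lab == "clean")

    for fp in out:
        lab = labels[fp.clone_id]
        if lab in ("empty", "vector_only"):
            fp.bands = []
        elif lab == "contaminated":
            donors = [c for c in clean_by_plate.get(fp.plate, []) if c != fp.clone_id]
            if not donors:
                donors = [c for c in all_clean if c != fp.clone_id]
            donor = donors[int(rng.integers(0, len(donors)))] if donors else None
            if donor is not None:
                fp.bands = fp.bands + snapshot[donor]
        elif lab == "offscale":
            fp.bands = [Band(b.channel, b.size, params.offscale_height) for b in fp.bands]

    for fp in out:
        for ch, size in params.vector_bands:
            fp.bands.append(Band(ch, _noisy_size(size), _height()))
    if params.repeat_bands:
        for fp in out:
            if rng.random() < params.repeat_fraction:
                for ch, size in params.repeat_bands:
                    fp.bands.append(Band(ch, _noisy_size(size), _height()))

    for fp in out:
        fp.bands.sort(key=lambda b: (b.channel, b.size, b.height or 0.0))
    truth.labels.update(labels)
    return out, truth


@dataclass
class SimOutput:
    """Everything one simulated experiment produced, in memory and on disk."""

    fingerprints: list[Fingerprint]
    truth: TruthSet
    sizes_path: Path | None = None
    meta_path: Path | None = None
    truth_path: Path | None = None
    manifest_path: Path | None = None


def generate(params: SimParams) -> SimOutput:
    """Run the full generator in memory (site map -> clones -> fingerprints)."""
    rng = np.random.default_rng(params.seed)
    site_map = simulate_site_map(params, rng)
    truth = sample_clones(params, site_map, rng)
    fps = []
    for i, interval in enumerate(truth.intervals):
        fp = fingerprint_clone(interval, site_map, params, rng)
        fp.plate, fp.well = _plate_well(i, params.plate_size)
        fps.append(fp)
    fps, truth = corrupt_fingerprints(fps, truth, params, rng)
    return SimOutput(fingerprints=fps, truth=truth)


def emit_dataset(params: SimParams, out_dir: str | Path) -> SimOutput:
    """Generate a dataset and write .sizes, clone-meta TSV, truth BED, manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = generate(params)
    sim.sizes_path = out_dir / "fingerprints.sizes"
    sim.meta_path = out_dir / "clone_meta.tsv"
    sim.truth_path = out_dir / "truth.bed"
    sim.manifest_path = out_dir / "manifest.json"
    write_sizes(sim.fingerprints, sim.sizes_path)
    write_clone_meta(sim.fingerprints, sim.meta_path)
    write_truth(sim.truth.intervals, sim.truth_path)
    label_counts: dict[str, int] = {}
    for lab in sim.truth.labels.values():
        label_counts[lab] = label_counts.get(lab, 0) + 1
    manifest = {
        "params": asdict(params),
        "n_clones": len(sim.fingerprints),
        "replicon_lengths": sim.truth.replicon_lengths,
        "site_counts": sim.truth.site_counts,
        "label_counts": dict(sorted(label_counts.items())),
        "mean_bands_per_clone": round(
            float(np.mean([fp.n_bands for fp in sim.fingerprints])), 2
        ),
    }
    sim.manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return sim
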