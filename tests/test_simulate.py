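"""Generator distributions, digestion rules and determinism."""

import numpy as np
import pytest

from hicfmap.sizes_io import Band, CloneInterval, Fingerprint
from hicfmap.simulate import (
    SimParams,
    SiteMap,
    corrupt_fingerprints,
    emit_dataset,
    expected_bands_per_clone,
    fingerprint_clone,
    generate,
    sample_clones,
    simulate_site_map,
    TruthSet,
)


def make_params(**kw):
    base = dict(seed=1, genome_length=10_000_000, n_replicons=1, n_clones=10)
    base.update(kw)
    return SimParams(**base)


class TestSiteMap:
    def test_poisson_site_counts(self):
        """Naive 4^-6 rate on 10 Mb gives ~2441 sites per enzyme (+-4 sd)."""
        p = make_params(six_cutter_rate=4.0**-6)
        sm = simulate_site_map(p, np.random.default_rng(0))
        mean = 4.0**-6 * 10_000_000
        sd = np.sqrt(mean)
        for enz in range(4):
            n = len(sm.sites["rep1"][enz])
            assert abs(n - mean) < 4 * sd

    def test_zero_rate_no_sites(self):
        p = make_params(six_cutter_rate=0.0, four_cutter_rate=0.0)
        sm = simulate_site_map(p, np.random.default_rng(0))
        assert all(len(s) == 0 for s in sm.sites["rep1"])

    def test_sites_sorted(self):
        sm = simulate_site_map(make_params(), np.random.default_rng(3))
        for arrs in sm.sites.values():
            for s in arrs:
                assert np.all(np.diff(s) > 0)

    def test_genome_shorter_than_insert_rejected(self):
        with pytest.raises(ValueError):
            make_params(genome_length=100_000)


class TestClones:
    def test_expected_coverage(self):
        p = make_params(n_clones=710, insert_mean=141_000.0)
        sm = simulate_site_map(p, np.random.default_rng(0))
        truth = sample_clones(p, sm, np.random.default_rng(1))
        total = sum(iv.end - iv.start for iv in truth.intervals)
        assert abs(total / p.genome_length - 10.0) < 0.5

    def test_single_clone(self):
        p = make_params(n_clones=1)
        sm = simulate_site_map(p, np.random.default_rng(0))
        truth = sample_clones(p, sm, np.random.default_rng(1))
        assert len(truth.intervals) == 1

    def test_mean_insert_clt(self):
        """Empirical mean insert is within 3 se of 141 kb at n=2000."""
        p = make_params(n_clones=2000)
        sm = simulate_site_map(p, np.random.default_rng(0))
        truth = sample_clones(p, sm, np.random.default_rng(2))
        lengths = np.array([iv.end - iv.start for iv in truth.intervals], float)
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert abs(lengths.mean() - 141_000.0) < 3 * se

    def test_intervals_inside_replicons(self):
        p = make_params(n_clones=500, n_replicons=2)
        sm = simulate_site_map(p, np.random.default_rng(0))
        truth = sample_clones(p, sm, np.random.default_rng(1))
        for iv in truth.intervals:
            assert 0 <= iv.start < iv.end <= sm.replicon_lengths[iv.replicon]


def manual_site_map(sites_by_enzyme, length=10_000):
    arrs = [np.array(sites_by_enzyme.get(e, []), dtype=float) for e in range(5)]
    return SiteMap({"rep1": length}, {"rep1": arrs})


class TestFingerprintClone:
    def test_no_labeled_sites_no_bands(self):
        sm = manual_site_map({4: [300.0, 500.0]})
        fp = fingerprint_clone(
            CloneInterval("rep1", 0, 1000, "c1"), sm, make_params(), np.random.default_rng(0)
        )
        assert fp.bands == []

    def test_doubly_labeled_fragment_two_bands(self):
        # EcoRI site at 100, BamHI at 220: one 120-bp fragment, two channels
        sm = manual_site_map({0: [100.0], 2: [220.0]})
        fp = fingerprint_clone(
            CloneInterval("rep1", 0, 1000, "c1"), sm, make_params(), np.random.default_rng(0)
        )
        assert sorted((b.channel, b.size) for b in fp.bands) == [(0, 120.0), (2, 120.0)]

    def test_boundary_fragments_excluded(self):
        # single labeled site: both adjacent fragments touch the boundaries
        sm = manual_site_map({0: [400.0]})
        fp = fingerprint_clone(
            CloneInterval("rep1", 0, 1000, "c1"), sm, make_params(), np.random.default_rng(0)
        )
        assert fp.bands == []

    def test_window_filter(self):
        # 40-bp fragment below the sizing window is dropped
        sm = manual_site_map({0: [100.0], 1: [140.0], 2: [700.0]})
        fp = fingerprint_clone(
            CloneInterval("rep1", 0, 1000, "c1"), sm, make_params(), np.random.default_rng(0)
        )
        # only the 140->700 fragment (560 bp) is out of window too; nothing survives
        sizes = sorted(b.size for b in fp.bands)
        assert sizes == []

    def test_band_count_range_for_default_rates(self):
        """Most noiseless 141-kb clones carry 60-120 bands.

        Local restriction-site density varies along the genome, so the
        band-count distribution is wider than Poisson; ~94% of clones
        fall in the range (the observed range of "most" BACs).
        """
        p = make_params()
        sm = simulate_site_map(p, np.random.default_rng(5))
        rng = np.random.default_rng(6)
        counts = []
        for i in range(600):
            start = int(rng.uniform(0, p.genome_length - 141_000))
            fp = fingerprint_clone(
                CloneInterval("rep1", start, start + 141_000, f"c{i}"), sm, p, rng
            )
            counts.append(fp.n_bands)
        counts = np.array(counts)
        assert np.mean((counts >= 60) & (counts <= 120)) >= 0.90
        assert 90 <= counts.mean() <= 110

    def test_expected_band_count_formula(self):
        p = make_params()
        sm = simulate_site_map(p, np.random.default_rng(5))
        rng = np.random.default_rng(6)
        counts = [
            fingerprint_clone(
                CloneInterval("rep1", s, s + 141_000, f"c{s}"), sm, p, rng
            ).n_bands
            for s in range(0, 9_000_000, 30_000)
        ]
        assert abs(np.mean(counts) - expected_bands_per_clone(p)) / expected_bands_per_clone(p) < 0.05


class TestCorrupt:
    def _clean_setup(self, n=30):
        rng = np.random.default_rng(0)
        fps = []
        intervals = []
        for i in range(n):
            bands = [Band(int(rng.integers(0, 4)), round(float(rng.uniform(50, 500)), 1), 1000.0)
                     for _ in range(60)]
            bands.sort(key=lambda b: (b.channel, b.size, b.height or 0))
            fps.append(Fingerprint(f"c{i:05d}", bands, plate="P001", well=f"A{i:02d}"))
            intervals.append(CloneInterval("rep1", i * 1000, i * 1000 + 141000, f"c{i:05d}"))
        truth = TruthSet({"rep1": 10_000_000}, intervals, {fp.clone_id: "clean" for fp in fps})
        return fps, truth

    def test_identity_when_all_noise_off(self):
        fps, truth = self._clean_setup()
        p = make_params().noiseless()
        out, _ = corrupt_fingerprints(fps, truth, p, np.random.default_rng(1))
        assert [fp.bands for fp in out] == [fp.bands for fp in fps]

    def test_empty_fraction_binomial(self):
        fps, truth = self._clean_setup(n=1000)
        p = make_params(frac_empty=0.01).noiseless(frac_empty=0.01)
        out, truth = corrupt_fingerprints(fps, truth, p, np.random.default_rng(2))
        empties = truth.clones_with_label("empty")
        assert abs(len(empties) - 10) < 4 * np.sqrt(1000 * 0.01 * 0.99)
        for fp in out:
            if fp.clone_id in empties:
                assert fp.bands == []

    def test_contaminated_clone_gets_donor_union(self):
        fps, truth = self._clean_setup(n=50)
        p = make_params().noiseless(frac_contaminated=0.2)
        out, truth = corrupt_fingerprints(fps, truth, p, np.random.default_rng(3))
        by_id = {fp.clone_id: fp for fp in out}
        originals = {fp.clone_id: fp for fp in fps}
        contaminated = truth.clones_with_label("contaminated")
        assert contaminated
        for cid in contaminated:
            assert by_id[cid].n_bands > originals[cid].n_bands

    def test_same_seed_identical(self):
        fps, truth = self._clean_setup()
        p = make_params()
        out1, _ = corrupt_fingerprints(fps, truth, p, np.random.default_rng(9))
        fps2, truth2 = self._clean_setup()
        out2, _ = corrupt_fingerprints(fps2, truth2, p, np.random.default_rng(9))
        assert [fp.bands for fp in out1] == [fp.bands for fp in out2]


class TestDataset:
    def test_same_seed_identical_files(self, tmp_path):
        p = SimParams(seed=42, genome_length=1_000_000, n_clones=40)
        a = emit_dataset(p, tmp_path / "a")
        b = emit_dataset(p, tmp_path / "b")
        assert a.sizes_path.read_bytes() == b.sizes_path.read_bytes()
        assert a.truth_path.read_bytes() == b.truth_path.read_bytes()
        assert a.manifest_path.read_bytes() == b.manifest_path.read_bytes()

    def test_shared_bands_track_true_overlap(self, small_sim):
        """Noiseless clones share bands in proportion to their true overlap."""
        from scipy.stats import spearmanr
        from hicfmap.overlap import shared_band_count

        tm = small_sim.truth.interval_of()
        fps = {fp.clone_id: fp for fp in small_sim.fingerprints}
        ids = sorted(fps)[:60]
        overlaps, shares = [], []
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                ia, ib = tm[a], tm[b]
                if ia.replicon != ib.replicon:
                    continue
                ov = max(0, min(ia.end, ib.end) - max(ia.start, ib.start))
                if ov == 0:
                    continue
                overlaps.append(ov)
                shares.append(shared_band_count(fps[a], fps[b], 0.4))
        rho = spearmanr(overlaps, shares).statistic
        assert rho > 0.9

    def test_artifact_labels_recorded(self, noisy_sim):
        labels = set(noisy_sim.truth.labels.values())
        assert labels <= {"clean", "empty", "contaminated", "offscale", "vector_only"}
        assert len(noisy_sim.truth.labels) == len(noisy_sim.fingerprints)
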