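"""Clustering, seriation, Q-flagging, DQer and merge behavior."""

import numpy as np
import pytest

from hicfmap.assemble import (
    Assembly,
    AssemblyParams,
    Contig,
    ScoreTable,
    assemble,
    cluster_at_cutoff,
    contigs_table,
    dq_split,
    flag_q_clones,
    merge_end_to_end,
    seriate_contig,
    write_assembly,
)
from hicfmap.evaluate import label_chimeras
from hicfmap.overlap import Edge, ScoreParams, score_all_pairs
from hicfmap.simulate import SimParams, generate
from hicfmap.sizes_io import Band, Fingerprint


def fake_edge(a, b, score, m=50):
    a, b = sorted((a, b))
    return Edge(a, b, 80, 90, m, score)


class TestCluster:
    def test_no_edges_all_singletons(self):
        comps, singles = cluster_at_cutoff(["a", "b", "c"], [], 1e-40)
        assert comps == [] and singles == ["a", "b", "c"]

    def test_single_linkage_transitivity(self):
        edges = [fake_edge("a", "b", 1e-50), fake_edge("b", "c", 1e-45)]
        comps, singles = cluster_at_cutoff(["a", "b", "c"], edges, 1e-40)
        assert comps == [["a", "b", "c"]] and singles == []

    def test_cutoff_respected(self):
        edges = [fake_edge("a", "b", 1e-50), fake_edge("b", "c", 1e-20)]
        comps, singles = cluster_at_cutoff(["a", "b", "c"], edges, 1e-40)
        assert comps == [["a", "b"]] and singles == ["c"]

    def test_two_regions_two_components(self, small_sim, small_table):
        """Clusters never span the two simulated replicons (noiseless)."""
        fps, edges, table, params = small_table
        comps, _ = cluster_at_cutoff(fps.keys(), edges, params.initial_cutoff)
        tm = small_sim.truth.interval_of()
        for comp in comps:
            assert len({tm[c].replicon for c in comp}) == 1


def tiling_fingerprints():
    """Three clones tiling left-to-right over a shared band sequence."""
    sizes = [round(60 + 3.7 * i, 1) for i in range(30)]
    bands = [Band(i % 4, s) for i, s in enumerate(sizes)]
    a = Fingerprint("cA", bands[0:16])
    b = Fingerprint("cB", bands[6:24])
    c = Fingerprint("cC", bands[14:30])
    return [a, b, c]


class TestSeriate:
    def test_two_identical_clones(self):
        bands = [Band(i % 4, round(60 + 4.0 * i, 1)) for i in range(60)]
        fps = {"a": Fingerprint("a", list(bands)), "b": Fingerprint("b", list(bands))}
        params = AssemblyParams()
        edges = score_all_pairs(list(fps.values()), ScoreParams(cutoff=1e-15))
        table = ScoreTable(edges, fps)
        contig = seriate_contig(["a", "b"], fps, params, table, 1)
        assert contig.cb_count == 60
        assert contig.cb_intervals["a"] == contig.cb_intervals["b"]
        assert not any(contig.q_flags.values())

    def test_three_tiling_clones_ordered(self):
        fps = {fp.clone_id: fp for fp in tiling_fingerprints()}
        params = AssemblyParams(score=ScoreParams(cutoff=1.0))
        edges = score_all_pairs(list(fps.values()), ScoreParams(cutoff=1.0))
        table = ScoreTable(edges, fps)
        contig = seriate_contig(list(fps), fps, params, table, 1)
        assert contig.clones in (["cA", "cB", "cC"], ["cC", "cB", "cA"])

    def test_singleton_component_rejected(self, small_table):
        fps, _edges, table, params = small_table
        with pytest.raises(ValueError):
            seriate_contig([next(iter(fps))], fps, params, table, 1)

    def test_cb_count_tracks_true_span(self):
        """CB count approximates contig span / mean band footprint (+-15%)
        at moderate coverage."""
        sim = generate(
            SimParams(seed=31, genome_length=3_000_000, n_clones=106).noiseless()
        )  # ~5x coverage: modest contigs, few band-size collisions
        fps = {fp.clone_id: fp for fp in sim.fingerprints}
        params = AssemblyParams()
        edges = score_all_pairs(sim.fingerprints, ScoreParams(cutoff=1e-15))
        table = ScoreTable(edges, fps)
        comps, _ = cluster_at_cutoff(fps.keys(), edges, params.initial_cutoff)
        tm = sim.truth.interval_of()
        footprint = 141_000 / 98.5  # bp per band at default rates
        checked = 0
        for comp in comps:
            if len(comp) < 5:
                continue
            contig = seriate_contig(comp, fps, params, table, 1)
            span = max(tm[c].end for c in comp) - min(tm[c].start for c in comp)
            expected = span / footprint
            assert abs(contig.cb_count - expected) / expected < 0.15
            checked += 1
        assert checked >= 2


class TestQFlags:
    def _contig_with(self, fps, params, table, members):
        return seriate_contig(members, fps, params, table, 1)

    def test_identical_neighbor_not_q(self):
        bands = [Band(i % 4, round(60 + 4.0 * i, 1)) for i in range(60)]
        fps = {"a": Fingerprint("a", list(bands)), "b": Fingerprint("b", list(bands))}
        params = AssemblyParams()
        table = ScoreTable(score_all_pairs(list(fps.values()), ScoreParams(cutoff=1e-15)), fps)
        contig = self._contig_with(fps, params, table, ["a", "b"])
        assert contig.q_flags == {"a": False, "b": False}

    def test_chimeric_fingerprint_flagged(self, small_sim, small_table):
        """A planted mixed fingerprint from two distant regions is Q.

        The chimera carries 40% of a local clone's bands plus foreign
        bands; once clustered in (at a relaxed cutoff, as chimeric links
        are weaker), fewer than half its bands match its neighborhood.
        """
        fps, _e, _t, params = small_table
        tm = small_sim.truth.interval_of()
        ids = sorted(fps)
        rep1 = [c for c in ids if tm[c].replicon == "rep1"]
        rep2 = [c for c in ids if tm[c].replicon == "rep2"]
        donor_a, donor_b = rep1[0], rep2[0]
        part_a = fps[donor_a].sorted_bands()
        part_b = fps[donor_b].sorted_bands()
        chimera = Fingerprint(
            "chimera",
            part_a[: int(0.4 * len(part_a))] + part_b[: int(0.6 * len(part_b))],
        )
        # the donor's genomic neighborhood, so the chimera joins a real contig
        neighborhood = [
            c
            for c in rep1
            if tm[c].start < tm[donor_a].end + 200_000
            and tm[c].end > tm[donor_a].start - 200_000
        ]
        pool = {c: fps[c] for c in neighborhood}
        pool["chimera"] = chimera
        edges = score_all_pairs(list(pool.values()), ScoreParams(cutoff=1e-10))
        table = ScoreTable(edges, pool)
        comps, _singles = cluster_at_cutoff(pool.keys(), edges, 1e-15)
        target = next((c for c in comps if "chimera" in c), None)
        assert target is not None and len(target) >= 3
        contig = seriate_contig(target, pool, params, table, 1)
        assert contig.q_flags["chimera"]


class TestDqSplit:
    def test_low_q_contig_untouched(self, small_sim, small_table):
        fps, edges, table, params = small_table
        comps, singles = cluster_at_cutoff(fps.keys(), edges, params.initial_cutoff)
        assembly = Assembly()
        for comp in comps:
            assembly.contigs.append(
                seriate_contig(comp, fps, params, table, assembly.new_contig_id())
            )
        assembly.singletons = singles
        before = [(c.contig_id, list(c.clones)) for c in assembly.contigs]
        assert all(c.q_fraction <= params.dq_fraction for c in assembly.contigs)
        dq_split(assembly, fps, params, table)
        after = [(c.contig_id, list(c.clones)) for c in assembly.contigs]
        assert before == after

    def test_high_q_contig_dissolved(self, small_sim, small_table):
        fps, edges, table, params = small_table
        comps, singles = cluster_at_cutoff(fps.keys(), edges, params.initial_cutoff)
        assembly = Assembly()
        for comp in comps:
            assembly.contigs.append(
                seriate_contig(comp, fps, params, table, assembly.new_contig_id())
            )
        assembly.singletons = singles
        victim = max(assembly.contigs, key=lambda c: c.n_clones)
        # force 20% Q-flags (> 15% threshold)
        for cid in victim.clones[: max(2, victim.n_clones // 5)]:
            victim.q_flags[cid] = True
        all_clones = set(assembly.clone_ids())
        dq_split(assembly, fps, params, table)
        assert any(e["event"] == "dq_dissolve" for e in assembly.log)
        assembly.check(all_clones)


class TestMerging:
    def test_empty_schedule_no_change(self, small_table):
        fps, edges, table, params0 = small_table
        from dataclasses import replace

        params = replace(params0, merge_schedule=())
        comps, singles = cluster_at_cutoff(fps.keys(), edges, params.initial_cutoff)
        assembly = Assembly()
        for comp in comps:
            assembly.contigs.append(
                seriate_contig(comp, fps, params, table, assembly.new_contig_id())
            )
        assembly.singletons = singles
        n_before = len(assembly.contigs)
        merge_end_to_end(assembly, fps, params, table)
        assert len(assembly.contigs) == n_before
        assert not any(e["event"] == "merge" for e in assembly.log)

    def test_merges_are_true_and_never_cross_replicons(
        self, noiseless_sim, noiseless_assembly
    ):
        tm = noiseless_sim.truth.interval_of()
        merges = [e for e in noiseless_assembly.log if e["event"] == "merge"]
        assert merges, "end-to-end merging should fire on a 10x dataset"
        for e in merges:
            a, b = e["junction"]
            assert tm[a].replicon == tm[b].replicon
        for contig in noiseless_assembly.contigs:
            assert len({tm[c].replicon for c in contig.clones}) == 1


class TestFullAssembly:
    def test_partition_invariant(self, noiseless_sim, noiseless_assembly):
        noiseless_assembly.check(fp.clone_id for fp in noiseless_sim.fingerprints)

    def test_contigs_have_at_least_two_clones(self, noiseless_assembly):
        assert all(c.n_clones >= 2 for c in noiseless_assembly.contigs)

    def test_co_assembly_recall(self, noiseless_sim, noiseless_assembly):
        """Clones with a deeply overlapping partner are co-assembled >= 99%."""
        from hicfmap.evaluate import clone_assignment_recall

        recall = clone_assignment_recall(noiseless_assembly, noiseless_sim.truth)
        assert recall >= 0.99

    def test_high_rank_correlation(self, noiseless_sim, noiseless_assembly):
        from hicfmap.evaluate import order_accuracy

        _frac, rho = order_accuracy(noiseless_assembly, noiseless_sim.truth)
        assert rho >= 0.99

    def test_determinism_byte_identical(self, tmp_path):
        sim = generate(SimParams(seed=13, genome_length=1_500_000, n_clones=106))
        a1 = assemble(sim.fingerprints)
        a2 = assemble(sim.fingerprints)
        p1 = write_assembly(a1, tmp_path / "a")
        p2 = write_assembly(a2, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_stringency_monotonicity(self):
        """A stricter initial cutoff never increases the chimera count."""
        from dataclasses import replace

        sim = generate(SimParams(seed=17, genome_length=1_500_000, n_clones=106))
        strict = assemble(
            sim.fingerprints, AssemblyParams(initial_cutoff=1e-50)
        )
        default = assemble(sim.fingerprints, AssemblyParams())

        def chimeras(a):
            labels = label_chimeras(a, sim.truth)
            return sum(1 for ok in labels.values() if not ok)

        assert chimeras(strict) <= chimeras(default)

    def test_table_round_trip_shape(self, noiseless_assembly):
        df = contigs_table(noiseless_assembly)
        assert set(df.columns) == {
            "contig_id", "clone_id", "rank", "cb_start", "cb_end", "q_flag"
        }
        assert len(df) == sum(c.n_clones for c in noiseless_assembly.contigs)
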