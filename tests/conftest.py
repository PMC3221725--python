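"""Shared simulation fixtures.

The expensive end-to-end datasets (a 10 Mb noiseless library and a 10 Mb
noisy library with planted artifacts, ~710 clones each at ~10x coverage)
are built once per session and shared across module and acceptance
tests. Smaller throwaway datasets are built per test.
"""

from __future__ import annotations

from dataclasses import replace

import pytest

from hicfmap.assemble import (
    Assembly,
    AssemblyParams,
    ScoreTable,
    assemble,
    attach_singletons,
    cluster_at_cutoff,
    dq_split,
    merge_end_to_end,
    seriate_contig,
)
from hicfmap.evaluate import label_chimeras
from hicfmap.overlap import score_all_pairs
from hicfmap.qc import QcParams, run_qc
from hicfmap.simulate import SimParams, generate


@pytest.fixture(scope="session")
def noiseless_sim():
    """Default-size noiseless library: 10 Mb genome, 710 clones (~10x)."""
    return generate(SimParams(seed=11).noiseless())


@pytest.fixture(scope="session")
def noiseless_assembly(noiseless_sim):
    return assemble(noiseless_sim.fingerprints, AssemblyParams())


@pytest.fixture(scope="session")
def small_sim():
    """Quick noiseless library: 2 Mb genome, 142 clones (~10x)."""
    return generate(
        SimParams(seed=7, genome_length=2_000_000, n_clones=142).noiseless()
    )


@pytest.fixture(scope="session")
def small_table(small_sim):
    params = AssemblyParams()
    edges = score_all_pairs(
        small_sim.fingerprints, replace(params.score, cutoff=params.final_cutoff)
    )
    fps = {fp.clone_id: fp for fp in small_sim.fingerprints}
    table = ScoreTable(edges, fps)
    return fps, edges, table, params


@pytest.fixture(scope="session")
def noisy_sim():
    """Default simulator parameters: sizing noise, dropout, spurious bands
    and ~2% planted artifact clones on 10 Mb / 710 clones."""
    return generate(SimParams(seed=23))


@pytest.fixture(scope="session")
def noisy_qc(noisy_sim):
    return run_qc(noisy_sim.fingerprints, QcParams())


@pytest.fixture(scope="session")
def noisy_staged(noisy_sim, noisy_qc):
    """Staged assembly of the QC'd noisy library with pre/post-DQer
    chimera rates measured against truth."""
    clean, _report = noisy_qc
    params = AssemblyParams()
    fps = {fp.clone_id: fp for fp in clean}
    edges = score_all_pairs(clean, replace(params.score, cutoff=params.final_cutoff))
    table = ScoreTable(edges, fps)
    assembly = Assembly()
    comps, singles = cluster_at_cutoff(fps.keys(), edges, params.initial_cutoff)
    for comp in comps:
        assembly.contigs.append(
            seriate_contig(comp, fps, params, table, assembly.new_contig_id())
        )
    assembly.singletons = singles

    def rate(a):
        labels = label_chimeras(a, noisy_sim.truth)
        return (
            sum(1 for ok in labels.values() if not ok) / len(labels) if labels else 0.0
        )

    pre_rate = rate(assembly)
    dq_split(assembly, fps, params, table)
    post_rate = rate(assembly)
    merge_end_to_end(assembly, fps, params, table)
    attach_singletons(assembly, fps, params, table)
    assembly.contigs.sort(key=lambda c: c.contig_id)
    assembly.check(fps.keys())
    return {
        "assembly": assembly,
        "fingerprints": fps,
        "pre_dq_chimera": pre_rate,
        "post_dq_chimera": post_rate,
    }
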