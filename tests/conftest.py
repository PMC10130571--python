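"""Shared fixtures: small simulated scenarios and truth-level helpers."""

from __future__ import annotations

import pytest

from parasnv import orthomap, sharedsnv
from parasnv.simdata import SimulationConfig, simulate_scenario
from parasnv.snvcall import SnvRecord, collate_snv_table, restrict_to_orfs


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A three-contig, 30 kb-per-population scenario: fast but large enough
    for the shared-SNV statistics to be non-degenerate."""
    defaults = dict(
        seed=seed,
        contig_lengths=(10_000, 10_000, 10_000),
        snv_rate=4e-3,
        n_recomb_tracts=1,
        tract_mean=5_000.0,
        tract_sd=500.0,
        n_mges=2,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def truth_tables(mags, truth):
    """Per-population collated SNV tables built from ground truth (bypassing
    read simulation), for testing the shared-SNV stages in isolation."""
    tables, totals = {}, {}
    for mag_id, mag in mags.items():
        recs = [
            SnvRecord(s.mag_id, s.contig, s.position, s.consensus_base,
                      s.variant_base, s.frequency, depth=0)
            for s in truth.snvs_for(mag_id)
        ]
        orf_snvs, tot = restrict_to_orfs(recs, mag.orfs)
        tables[mag_id] = collate_snv_table(orf_snvs, mag)
        totals[mag_id] = tot
    return tables, totals


def shared_records_from_truth(mags, truth):
    """Cluster proteins and identify shared SNVs from ground-truth tables."""
    tables, _ = truth_tables(mags, truth)
    proteins = {
        (mag_id, orf_id): seq
        for mag_id, mag in mags.items()
        for orf_id, seq in mag.protein_sequences().items()
    }
    clusters = orthomap.cluster_proteins(proteins)
    orf_nt = {
        (mag_id, orf_id): seq
        for mag_id, mag in mags.items()
        for orf_id, seq in mag.orf_nt_sequences().items()
    }
    site_maps = orthomap.build_site_maps(clusters, orf_nt)
    return sharedsnv.find_shared_snvs(tables, clusters, site_maps), clusters


@pytest.fixture(scope="session")
def demo_scenario():
    """One fully featured small scenario reused across tests."""
    config = small_config(seed=7)
    mags, truth, lineage = simulate_scenario(config)
    return config, mags, truth, lineage
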