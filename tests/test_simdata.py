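"""Generator contracts: layout, divergence, polymorphism, recombination,
elements, and read-pair statistics, checked against direct sequence
comparison oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from parasnv import simdata
from parasnv.simdata import (
    ConfigError,
    SimulationConfig,
    TruthSet,
    diverge_populations,
    encode,
    inject_polymorphisms,
    inject_recombination,
    insert_element,
    make_mge_sequence,
    revcomp,
    simulate_ancestor,
    simulate_read_pairs,
    simulate_scenario,
)

from conftest import small_config


class TestAncestor:
    def test_requested_layout_and_orf_fraction(self):
        cfg = SimulationConfig(seed=7, contig_lengths=(20_000,) * 5, orf_fraction=0.85)
        anc = simulate_ancestor(cfg)
        assert len(anc.contigs) == 5
        assert anc.genome_size == 100_000
        orf_bp = sum(len(o) for o in anc.orfs)
        assert abs(orf_bp / anc.genome_size - 0.85) < 0.02
        # non-overlapping, in-bounds, codon-granular ORFs with a valid start
        by_contig = {}
        for o in anc.orfs:
            by_contig.setdefault(o.contig, []).append(o)
        for contig, orfs in by_contig.items():
            orfs.sort(key=lambda o: o.start)
            for prev, nxt in zip(orfs, orfs[1:]):
                assert prev.end <= nxt.start
            for o in orfs:
                seq = anc.contigs[contig][o.start:o.end]
                assert seq.startswith("ATG")
                assert seq[-3:] in ("TAA", "TAG", "TGA")

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=3, contig_lengths=(8_000, 8_000))
        a, b = simulate_ancestor(cfg), simulate_ancestor(cfg)
        assert a.contigs == b.contigs
        assert a.orfs == b.orfs

    def test_zero_orf_fraction_emits_no_orfs(self):
        cfg = SimulationConfig(seed=1, contig_lengths=(5_000,), orf_fraction=0.0)
        assert simulate_ancestor(cfg).orfs == []

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(contig_lengths=(-5,)),
            dict(orf_fraction=1.5),
            dict(snv_freq_range=(0.0, 0.4)),
            dict(snv_rate=-1e-3),
            dict(clade_divergence=2.0),
        ],
    )
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)


class TestDivergence:
    def test_zero_divergence_reproduces_ancestor(self):
        cfg = SimulationConfig(seed=2, contig_lengths=(6_000,),
                               clade_divergence=0.0, within_clade_divergence=0.0)
        anc = simulate_ancestor(cfg)
        mags, _ = diverge_populations(anc, cfg)
        assert all(m.contigs == anc.contigs for m in mags.values())

    def test_between_clade_identity_matches_configured_divergence(self):
        # oracle: per-site equality count over the full 100 kb sequence
        cfg = SimulationConfig(seed=9, contig_lengths=(100_000,),
                               clade_divergence=0.16, within_clade_divergence=0.0)
        mags, _ = diverge_populations(simulate_ancestor(cfg), cfg)
        a = encode(mags["S-30"].contigs["c00"])
        b = encode(mags["D-30"].contigs["c00"])
        identity = float((a == b).mean())
        assert abs(identity - 0.84) < 0.005

    def test_within_clade_hamming_in_poisson_interval(self):
        # population-vs-clade-reference distance ~ Poisson(rate * L)
        cfg = SimulationConfig(seed=4, contig_lengths=(100_000,),
                               clade_divergence=0.0, within_clade_divergence=1e-4)
        anc = simulate_ancestor(cfg)
        mags, lineage = diverge_populations(anc, cfg)
        lo, hi = stats.poisson.ppf([0.005, 0.995], 1e-4 * 100_000)
        for label in ("S-30", "S-65", "S-132"):
            d = int((encode(anc.contigs["c00"]) != encode(mags[label].contigs["c00"])).sum())
            assert lo <= d <= hi
            assert lineage["within"][label] == d


class TestPolymorphisms:
    def test_zero_rate_yields_empty_truth(self):
        cfg = small_config(snv_rate=0.0)
        mags, _ = diverge_populations(simulate_ancestor(cfg), cfg)
        assert inject_polymorphisms(mags["S-30"], cfg) == []

    def test_count_in_poisson_interval_and_frequencies_in_range(self):
        cfg = SimulationConfig(seed=12, contig_lengths=(50_000, 50_000),
                               snv_rate=5e-4, snv_freq_range=(0.05, 0.35))
        mags, _ = diverge_populations(simulate_ancestor(cfg), cfg)
        mag = mags["D-65"]
        snvs = inject_polymorphisms(mag, cfg)
        orf_bp = sum(len(o) for o in mag.orfs)
        lo, hi = stats.poisson.ppf([0.005, 0.995], 5e-4 * orf_bp)
        assert lo <= len(snvs) <= hi
        for s in snvs:
            assert 0.05 <= s.frequency <= 0.35
            assert s.variant_base != s.consensus_base
            assert mag.contigs[s.contig][s.position] == s.consensus_base
            assert mag.orf_at(s.contig, s.position) is not None

    def test_sites_are_unique(self):
        cfg = small_config(snv_rate=1e-2)
        mags, _ = diverge_populations(simulate_ancestor(cfg), cfg)
        snvs = inject_polymorphisms(mags["S-132"], cfg)
        sites = [(s.contig, s.position) for s in snvs]
        assert len(sites) == len(set(sites))


class TestRecombination:
    def _pair(self, **kw):
        cfg = small_config(**kw)
        mags, _ = diverge_populations(simulate_ancestor(cfg), cfg)
        return cfg, mags["D-65"], mags["S-132"]

    def test_zero_tracts_leave_recipient_untouched(self):
        cfg, donor, recipient = self._pair(n_recomb_tracts=0)
        before = dict(recipient.contigs)
        inject_recombination(donor, recipient, TruthSet(), cfg)
        assert recipient.contigs == before

    def test_tract_sequence_equals_donor_and_orfs_never_split(self):
        cfg, donor, recipient = self._pair(n_recomb_tracts=2)
        truth = TruthSet()
        tracts = inject_recombination(donor, recipient, truth, cfg)
        assert len(tracts) == 2
        for t in tracts:
            assert 0 <= t.start < t.end <= len(recipient.contigs[t.contig])
            assert (recipient.contigs[t.contig][t.start:t.end]
                    == donor.contigs[t.contig][t.start:t.end])
            for orf in recipient.orfs:
                if orf.contig == t.contig:
                    assert not (orf.start < t.start < orf.end)
                    assert not (orf.start < t.end < orf.end)

    def test_donor_polymorphisms_inside_tract_become_shared_truth(self):
        cfg, donor, recipient = self._pair(n_recomb_tracts=1)
        truth = TruthSet()
        truth.true_snvs.extend(inject_polymorphisms(donor, cfg))
        truth.true_snvs.extend(inject_polymorphisms(recipient, cfg))
        donor_snvs = {(s.contig, s.position): s for s in truth.snvs_for(donor.mag_id)}
        (tract,) = inject_recombination(donor, recipient, truth, cfg)
        inside = [
            s for (c, p), s in donor_snvs.items()
            if c == tract.contig and tract.start <= p < tract.end
        ]
        copied = [
            s for s in truth.snvs_for(recipient.mag_id)
            if s.contig == tract.contig and tract.start <= s.position < tract.end
        ]
        assert len(copied) == len(inside) > 0
        by_site = {(s.contig, s.position): s for s in copied}
        for s in inside:
            c = by_site[(s.contig, s.position)]
            assert (c.consensus_base, c.variant_base) == (s.consensus_base, s.variant_base)

    def test_overlong_tract_rejected(self):
        cfg, donor, recipient = self._pair(n_recomb_tracts=1)
        bad = SimulationConfig(**{**cfg.__dict__, "tract_mean": 1e6, "tract_sd": 1.0})
        with pytest.raises(ConfigError):
            inject_recombination(donor, recipient, TruthSet(), bad)


class TestMges:
    def test_inverted_repeat_structure(self):
        rng = np.random.default_rng(0)
        seq = make_mge_sequence(rng, 1_000, 20)
        assert len(seq) == 1_000
        assert seq[-20:] == revcomp(seq[:20])

    def test_truncation_fraction(self):
        cfg = small_config(n_mges=0)
        mags, _ = diverge_populations(simulate_ancestor(cfg), cfg)
        mag = mags["S-30"]
        rng = np.random.default_rng(1)
        element = make_mge_sequence(rng, 1_000, 20)
        truth = TruthSet()
        # find an intergenic spot
        pos = next(p for p in range(len(mag.contigs["c00"])) if mag.orf_at("c00", p) is None)
        rec = insert_element(mag, truth, "mgeX", element, "c00", pos, truncate_fraction=0.6)
        assert rec.end - rec.start == 600
        assert rec.truncated
        assert mag.contigs["c00"][rec.start:rec.end] == element[:600]

    def test_insertion_shifts_downstream_annotation_consistently(self):
        cfg = small_config(n_mges=0)
        mags, _ = diverge_populations(simulate_ancestor(cfg), cfg)
        mag = mags["D-30"]
        truth = TruthSet()
        truth.true_snvs.extend(inject_polymorphisms(mag, cfg))
        orf_seqs_before = mag.orf_nt_sequences()
        rng = np.random.default_rng(2)
        pos = next(p for p in range(len(mag.contigs["c01"])) if mag.orf_at("c01", p) is None)
        insert_element(mag, truth, "mgeY", make_mge_sequence(rng, 800, 20), "c01", pos)
        # ORF sequences unchanged under the coordinate shift
        assert mag.orf_nt_sequences() == orf_seqs_before
        # truth SNV consensus bases still agree with the shifted sequence
        for s in truth.snvs_for(mag.mag_id):
            assert mag.contigs[s.contig][s.position] == s.consensus_base

    def test_identical_elements_in_two_genomes(self, demo_scenario):
        _, mags, truth, _ = demo_scenario
        copies = {m.mag_id: m for m in truth.mge_insertions if m.mge_name == "mge02"}
        # the horizontal-transfer scenario makes the donor and recipient identical
        assert copies["D-132"].sequence == copies["S-65"].sequence

    def test_overlapping_insertions_rejected(self):
        cfg = small_config(n_mges=0)
        mags, _ = diverge_populations(simulate_ancestor(cfg), cfg)
        mag = mags["S-65"]
        truth = TruthSet()
        rng = np.random.default_rng(3)
        pos = next(p for p in range(len(mag.contigs["c02"])) if mag.orf_at("c02", p) is None)
        insert_element(mag, truth, "a", make_mge_sequence(rng, 500, 20), "c02", pos)
        with pytest.raises(ConfigError):
            insert_element(mag, truth, "b", make_mge_sequence(rng, 500, 20), "c02", pos + 10)


class TestReadPairs:
    def test_zero_coverage_yields_no_pairs(self):
        cfg = small_config(coverage=0.0)
        mags, truth, _ = simulate_scenario(cfg)
        assert len(simulate_read_pairs(mags["S-30"], truth, cfg)) == 0

    def test_error_free_reads_match_reference_exactly(self):
        cfg = small_config(seed=5, snv_rate=0.0, error_rate=0.0, coverage=10,
                           n_recomb_tracts=0, n_mges=0, mge_transfers=(), recomb_pairs=())
        mags, truth, _ = simulate_scenario(cfg)
        mag = mags["D-132"]
        pairs = simulate_read_pairs(mag, truth, cfg)
        assert (pairs["pair_identity"] == 1.0).all()
        row = pairs.iloc[17]
        ref = mag.contigs[row.contig]
        assert ref[row.mate1_start:row.mate1_start + cfg.read_length] == row.bases1
        assert ref[row.mate2_start:row.mate2_start + cfg.read_length] == row.bases2

    def test_mean_depth_near_configured_coverage(self):
        cfg = SimulationConfig(seed=6, contig_lengths=(100_000,), coverage=50,
                               n_mges=0, n_recomb_tracts=0, recomb_pairs=(), mge_transfers=())
        mags, truth, _ = simulate_scenario(cfg)
        pairs = simulate_read_pairs(mags["S-65"], truth, cfg)
        depth = np.zeros(100_000)
        for col in ("mate1_start", "mate2_start"):
            np.add.at(depth, pairs[col].to_numpy(), 1)
        # cumulated starts -> coverage profile
        depth = np.convolve(depth, np.ones(cfg.read_length))[: 100_000]
        assert abs(depth.mean() - 50) < 3

    def test_variant_read_fraction_tracks_truth_frequency(self):
        cfg = small_config(seed=8, error_rate=0.0, coverage=60, n_recomb_tracts=0,
                           n_mges=0, recomb_pairs=(), mge_transfers=())
        mags, truth, _ = simulate_scenario(cfg)
        mag = mags["S-132"]
        pairs = simulate_read_pairs(mag, truth, cfg)
        rl = cfg.read_length
        inside_999 = 0
        snvs = truth.snvs_for(mag.mag_id)[:50]
        for s in snvs:
            sub = pairs[pairs["contig"] == s.contig]
            n = v = 0
            for _, row in sub.iterrows():
                for st, bases in ((row.mate1_start, row.bases1), (row.mate2_start, row.bases2)):
                    if st <= s.position < st + rl:
                        n += 1
                        v += bases[s.position - st] == s.variant_base
            lo, hi = stats.binom.ppf([0.0005, 0.9995], n, s.frequency)
            inside_999 += lo <= v <= hi
        assert inside_999 >= 0.95 * len(snvs)

    def test_read_longer_than_contig_rejected(self):
        cfg = small_config()
        mags, truth, _ = simulate_scenario(cfg)
        bad = SimulationConfig(**{**cfg.__dict__, "read_length": 100_000})
        with pytest.raises(ConfigError):
            simulate_read_pairs(mags["S-30"], truth, bad)


class TestScenario:
    def test_scenario_deterministic(self):
        cfg = small_config(seed=13)
        m1, t1, _ = simulate_scenario(cfg)
        m2, t2, _ = simulate_scenario(cfg)
        assert {k: v.contigs for k, v in m1.items()} == {k: v.contigs for k, v in m2.items()}
        assert t1.true_snvs == t2.true_snvs
        assert t1.recomb_tracts == t2.recomb_tracts
        assert t1.mge_insertions == t2.mge_insertions

    def test_truth_consistent_with_sequences(self, demo_scenario):
        _, mags, truth, _ = demo_scenario
        for s in truth.true_snvs:
            assert mags[s.mag_id].contigs[s.contig][s.position] == s.consensus_base
        for m in truth.mge_insertions:
            assert mags[m.mag_id].contigs[m.contig][m.start:m.end] == m.sequence
        for t in truth.recomb_tracts:
            assert (mags[t.recipient].contigs[t.contig][t.start:t.end]
                    == mags[t.donor].contigs[t.contig][t.start:t.end])


class TestIo:
    def test_fasta_gff_pair_tables_round_trip(self, tmp_path, demo_scenario):
        cfg, mags, truth, _ = demo_scenario
        mag = mags["S-30"]
        simdata.write_fasta(mag.contigs, tmp_path / "m.fa")
        assert simdata.read_fasta(tmp_path / "m.fa") == mag.contigs
        simdata.write_gff3(mag, tmp_path / "m.gff3")
        assert simdata.read_gff3(tmp_path / "m.gff3") == mag.orfs
        pairs = simulate_read_pairs(mag, truth, cfg)
        simdata.write_read_pairs(pairs, tmp_path / "p.tsv")
        back = simdata.read_read_pairs(tmp_path / "p.tsv")
        pd.testing.assert_frame_equal(back, pairs)

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = small_config(seed=99)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert SimulationConfig.from_yaml(tmp_path / "c.yaml") == cfg
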