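"""Ground-truthed library simulation: construction, limits and statistics."""

import numpy as np
import pytest

from ptseq.callers import control_threshold, quantify_genome
from ptseq.genome import sample_control_sites, scan_motifs
from ptseq.pileup import build_end_pileup, five_prime_end
from ptseq.qc import TAG_SEQUENCE, QCParams, run_qc
from ptseq.simulate import (PlantedSite, SimConfig, expected_shear_background,
                            load_truth, make_reference, simulate_dataset,
                            simulate_library, write_truth)


def planted_grid(length, fractions, start=1500, step=2000):
    return [PlantedSite(start + step * i, "GAAC" if i % 2 == 0 else "GTTC", f)
            for i, f in enumerate(fractions)]


class TestMakeReference:
    def test_planted_sites_are_found_by_scan(self):
        ref, truth = make_reference(1000, seed=1,
                                    planted=[PlantedSite(500, "GAAC", 0.3)])
        assert any(s.start == 500 and s.forward_motif == "GAAC"
                   for s in scan_motifs(ref))
        assert [(s.position, s.fraction) for s in truth.planted_sites] == \
            [(500, 0.3)]

    def test_deterministic_per_seed(self):
        a, _ = make_reference(2000, seed=42)
        b, _ = make_reference(2000, seed=42)
        c, _ = make_reference(2000, seed=43)
        assert a.seq == b.seq and a.seq != c.seq

    def test_overlapping_planted_positions_error(self):
        with pytest.raises(ValueError, match="overlap"):
            make_reference(1000, planted=[PlantedSite(10, "GAAC", 1),
                                          PlantedSite(12, "GTTC", 1)])

    def test_motif_count_matches_binomial_expectation(self):
        # at GC 0.5 each 4-mer window matches a given motif w.p. (1/4)^4
        L = 50_000
        ref, truth = make_reference(L, gc=0.5, seed=7)
        expected = 2 * (L - 3) * 0.25 ** 4
        sd = np.sqrt(2 * (L - 3) * 0.25 ** 4)
        assert abs(len(truth.sites) - expected) < 3 * sd


class TestSimulateLibrary:
    def test_deterministic_per_seed(self):
        cfg = SimConfig(length=3000, planted=planted_grid(3000, [0.5], 1000),
                        n_molecules=20, seed=9)
        _, _, reads_a, alns_a = simulate_dataset(cfg)
        _, _, reads_b, alns_b = simulate_dataset(cfg)
        assert [(r.id, r.bases) for r in reads_a] == \
            [(r.id, r.bases) for r in reads_b]
        assert alns_a == alns_b

    def test_read_length_above_max_fragment_errors(self):
        with pytest.raises(ValueError, match="read_length"):
            SimConfig(read_length=400)

    def test_fully_modified_site_has_no_spanning_reads(self):
        """f=1, c=1: no intact molecule can span a planted site; reads either
        end at a cleavage point or lie strictly to one side."""
        cfg = SimConfig(length=8000, planted=planted_grid(8000, [1.0, 1.0]),
                        n_molecules=40, substitution_error_rate=0.0,
                        n_call_rate=0.0, seed=3)
        ref, truth, reads, alns = simulate_dataset(cfg)
        pup = build_end_pileup(alns, {ref.name: len(ref)})
        for s in truth.planted_sites:
            site = next(m for m in scan_motifs(ref) if m.start == s.position)
            assert pup.count_spanning(site) == 0
            for a in alns:
                fp, _ = five_prime_end(a)
                inside = a.start <= site.start and a.end >= site.start + 4
                assert (not inside) or fp in (site.plus_cleavage,
                                              site.minus_cleavage)

    def test_unmodified_genome_end_rate_matches_renewal_density(self):
        """f=0: reads begin at a probe position only by shear coincidence,
        at rate ~ 1/mean-fragment-length per molecule-strand."""
        cfg = SimConfig(length=30_000, planted=[], n_molecules=150, seed=5,
                        substitution_error_rate=0.0, n_call_rate=0.0)
        ref, truth, reads, alns = simulate_dataset(cfg)
        pup = build_end_pileup(alns, {ref.name: len(ref)})
        probes = np.arange(2000, 28_000, 500)
        counts = [pup.count_ends_at(int(p), "+") for p in probes]
        u = 1.0 / 250.0  # renewal density: 1 / mean of U{150..350}
        expect = cfg.n_molecules * u
        se = np.sqrt(expect / len(probes))
        assert abs(np.mean(counts) - expect) < 3 * se

    def test_icds_reads_tagged_and_start_with_cleavage_trinucleotide(self):
        cfg = SimConfig(length=6000, planted=planted_grid(6000, [1.0, 1.0]),
                        n_molecules=30, mode="ICDS", seed=4,
                        substitution_error_rate=0.0, n_call_rate=0.0)
        ref, truth, reads, alns = simulate_dataset(cfg)
        assert reads and all(r.tagged for r in reads)
        assert all(r.bases.startswith(TAG_SEQUENCE) for r in reads)
        survivors, _ = run_qc(reads, QCParams(mode="ICDS", adapters=()))
        assert survivors
        assert all(r.bases[:3] in ("AAC", "TTC") for r in survivors)

    def test_total_aligned_bases_bounded_by_molecule_bases(self):
        cfg = SimConfig(length=5000, planted=[], n_molecules=10, seed=6)
        ref, truth, reads, alns = simulate_dataset(cfg)
        total = sum(a.end - a.start for a in alns)
        assert total <= 2 * cfg.n_molecules * cfg.length
        # reads observe whole fragments at the default read length, and
        # fragments tile each strand completely
        assert total == 2 * cfg.n_molecules * cfg.length

    def test_estimator_consistency_frequency_near_f_times_c(self):
        cfg = SimConfig(length=20_000,
                        planted=planted_grid(20_000, [0.3, 0.3, 0.3], 3000,
                                             5000),
                        cleavage_efficiency=0.8, n_molecules=150, seed=8)
        ref, truth, reads, alns = simulate_dataset(cfg)
        pup = build_end_pileup(alns, {ref.name: len(ref)})
        sites = scan_motifs(ref)
        quants = quantify_genome(
            pup, sites,
            controls=sample_control_sites(ref, sites, 10, seed=1))
        fc = 0.3 * 0.8
        for q in quants:
            if q.site.start in {s.position for s in truth.planted_sites}:
                n_eff = (q.n_end + q.n_span) / 2  # coupled strands
                se = np.sqrt(fc * (1 - fc) / n_eff)
                assert abs(q.frequency - fc) < 4 * se


class TestTruthIO:
    def test_round_trip(self, tmp_path):
        cfg = SimConfig(length=2000, planted=planted_grid(2000, [0.25], 800),
                        seed=2)
        ref, truth, _, _ = simulate_dataset(cfg)
        write_truth(truth, tmp_path / "t.bed", tmp_path / "t.json")
        back = load_truth(tmp_path / "t.json")
        assert back.sites == truth.sites
        assert back.cleavage_efficiency == truth.cleavage_efficiency

    def test_bed_matches_scan(self, tmp_path):
        cfg = SimConfig(length=2000, planted=planted_grid(2000, [0.25], 800),
                        seed=2)
        ref, truth, _, _ = simulate_dataset(cfg)
        write_truth(truth, tmp_path / "t.bed", tmp_path / "t.json")
        rows = [l.split("\t") for l in
                (tmp_path / "t.bed").read_text().splitlines()
                if not l.startswith("#")]
        scan_starts = {s.start for s in scan_motifs(ref)}
        for r in rows:
            assert int(r[1]) in scan_starts

    def test_empty_planted_set(self, tmp_path):
        ref, truth = make_reference(500, seed=1)
        write_truth(truth, tmp_path / "t.bed", tmp_path / "t.json")
        back = load_truth(tmp_path / "t.json")
        assert back.planted_sites == []


def test_expected_shear_background_value():
    # u = 1/250: u / (u + (1-u)^3)
    u = 1 / 250
    assert expected_shear_background(250) == \
        pytest.approx(u / (u + (1 - u) ** 3))
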