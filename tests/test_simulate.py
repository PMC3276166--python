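"""Generator correctness: determinism, composition, truth-table identities,
read placement statistics, and the evaluator's edge cases."""
import numpy as np
import pytest

from iesmap._util import revcomp
from iesmap.iescall import IesSite
from iesmap.refbuild import build_conmac
from iesmap.simulate import (
    SHORT_PRECISE,
    LONG_HETEROGENEOUS,
    SimConfig,
    evaluate_calls,
    fragments_for_coverage,
    simulate_genomes,
    simulate_reads,
)

BASE = SimConfig(
    seed=5, contig_lens=(80_000, 60_000), n_ies=10, placement_margin=10_000,
    min_ies_spacing=2500,
)


@pytest.fixture(scope="module")
def genomes():
    return simulate_genomes(BASE)


class TestGenomes:
    def test_no_ies_means_identity(self):
        cfg = SimConfig(seed=1, contig_lens=(50_000,), n_ies=0)
        g = simulate_genomes(cfg)
        assert g.mic_contigs[0].sequence == g.mac_contigs[0].sequence
        assert g.truth == []

    def test_fixed_seed_reproducible(self):
        a = simulate_genomes(BASE)
        b = simulate_genomes(BASE)
        assert [c.sequence for c in a.mac_contigs] == [c.sequence for c in b.mac_contigs]
        assert [c.sequence for c in a.mic_contigs] == [c.sequence for c in b.mic_contigs]
        assert [(t.mac_pos, t.core) for t in a.truth] == [(t.mac_pos, t.core) for t in b.truth]

    def test_at_fraction_within_binomial_bound(self):
        cfg = SimConfig(seed=2, contig_lens=(1_000_000,), n_ies=0, at_fraction=0.75)
        g = simulate_genomes(cfg)
        seq = g.mac_contigs[0].sequence
        at = (seq.count("A") + seq.count("T")) / len(seq)
        sigma = np.sqrt(0.75 * 0.25 / len(seq))
        assert abs(at - 0.75) <= 3 * sigma

    def test_germline_reconstruction_identity(self, genomes):
        """MIC == left + mh + core + mh + right around every planted IES."""
        mac = {c.name: c.sequence for c in genomes.mac_contigs}
        mic = {c.name: c.sequence for c in genomes.mic_contigs}
        for t in genomes.truth:
            k = len(t.microhomology)
            p = t.mac_pos
            assert mac[t.contig][p : p + k] == t.microhomology
            s, e = t.mic_core_start, t.mic_core_end
            assert mic[t.contig][s:e] == t.core
            # both boundary copies of the microhomology present in the germline
            assert mic[t.contig][s - k : s] == t.microhomology
            assert mic[t.contig][e : e + k] == t.microhomology
            # flanks agree with the somatic genome
            assert mic[t.contig][s - k - 30 : s - k] == mac[t.contig][p - 30 : p]
            assert mic[t.contig][e + k : e + k + 30] == mac[t.contig][p + k : p + k + 30]

    def test_class_properties(self, genomes):
        for t in genomes.truth:
            if t.cls == SHORT_PRECISE:
                assert t.ies_len <= 500
                assert 3 <= len(t.microhomology) <= 4
                assert "TA" in t.microhomology
            else:
                assert t.cls == LONG_HETEROGENEOUS
                assert 1000 <= t.ies_len <= 3000
                assert t.microhomology == ""
                assert (0, 0) in t.alt_boundaries

    def test_spacing_respected(self, genomes):
        by_contig: dict[str, list[int]] = {}
        for t in genomes.truth:
            by_contig.setdefault(t.contig, []).append(t.mac_pos)
        for positions in by_contig.values():
            positions.sort()
            assert all(b - a >= BASE.min_ies_spacing for a, b in zip(positions, positions[1:]))


class TestReads:
    def test_error_free_reads_are_germline_substrings(self, genomes):
        cfg = SimConfig(**{**BASE.__dict__, "error_rate": 0.0})
        sim = simulate_reads(genomes, cfg)
        mic = {c.name: c.sequence for c in genomes.mic_contigs}
        assert sim.reads
        for read, pl in zip(sim.reads, sim.placements):
            expect = mic[pl.contig][pl.start : pl.end]
            if pl.strand == "-":
                expect = revcomp(expect)
            assert read.bases == expect

    def test_fixed_seed_reproducible(self, genomes):
        a = simulate_reads(genomes, BASE)
        b = simulate_reads(genomes, BASE)
        assert [r.bases for r in a.reads] == [r.bases for r in b.reads]
        assert [list(r.quals) for r in a.reads] == [list(r.quals) for r in b.reads]

    def test_realised_coverage_matches_lander_waterman(self, genomes):
        cfg = SimConfig(**{**BASE.__dict__, "coverage_fraction": 0.6})
        sim = simulate_reads(genomes, cfg)
        genome_len = sum(len(c.sequence) for c in genomes.mic_contigs)
        depth = sum(len(r.bases) for r in sim.reads) / genome_len
        n_expected = sum(
            2 * fragments_for_coverage(cfg, len(c.sequence)) for c in genomes.mic_contigs
        )
        assert abs(len(sim.reads) - n_expected) <= 2  # rounding only
        assert depth == pytest.approx(
            len(sim.reads) * cfg.read_len_mean / genome_len, rel=0.05
        )

    def test_error_rate_realised(self, genomes):
        cfg = SimConfig(**{**BASE.__dict__, "error_rate": 0.01, "coverage_fraction": 0.9})
        sim = simulate_reads(genomes, cfg)
        mic = {c.name: c.sequence for c in genomes.mic_contigs}
        mismatches = total = 0
        for read, pl in zip(sim.reads, sim.placements):
            expect = mic[pl.contig][pl.start : pl.end]
            if pl.strand == "-":
                expect = revcomp(expect)
            mismatches += sum(a != b for a, b in zip(read.bases, expect))
            total += len(read.bases)
        assert 0.5 * 0.01 < mismatches / total < 2 * 0.01

    def test_mate_tags_follow_pairing_convention(self, genomes):
        sim = simulate_reads(genomes, BASE)
        tags = {r.mate_tag for r in sim.reads}
        assert tags == {"b1", "g1"}
        frags = {}
        for r in sim.reads:
            frags.setdefault(r.id.rsplit(".", 1)[0], set()).add(r.mate_tag)
        assert all(t == {"b1", "g1"} for t in frags.values())


@pytest.fixture(scope="module")
def setup():
    g = simulate_genomes(BASE)
    ref = build_conmac(g.mac_contigs)
    return g, ref


class TestEvaluate:
    def test_perfect_calls(self, setup):
        g, ref = setup
        sites = []
        for t in g.truth:
            start = ref.lift_to_conmac(t.contig, t.mac_pos)
            k = len(t.microhomology)
            if k:  # convergent reads both span the retained microhomology
                site = IesSite(window=(start, start + k), category="win1",
                               l_coord=start + k - 1, r_coord=start)
            else:  # blunt junction: terminal coordinates are adjacent
                site = IesSite(window=(start, start + 1), category="win1",
                               l_coord=start - 1, r_coord=start)
            sites.append(site)
        ev = evaluate_calls(sites, g.truth, ref)
        assert ev.recall["win1"] == 1.0
        assert ev.precision["win1"] == 1.0
        assert ev.microhomology_accuracy == 1.0
        assert all(abs(e) == 0 for e in ev.positional_errors)

    def test_empty_calls(self, setup):
        g, ref = setup
        ev = evaluate_calls([], g.truth, ref)
        assert ev.recall["any"] == 0.0
        assert ev.precision["any"] is None

    def test_tolerance_window(self, setup):
        g, ref = setup
        t = g.truth[0]
        start = ref.lift_to_conmac(t.contig, t.mac_pos)
        near = IesSite(window=(start + 9, start + 10), category="win2")
        far = IesSite(window=(start + 30, start + 31), category="win2")
        ev = evaluate_calls([near, far], g.truth, ref, tol=9)
        assert ev.recall["win2"] == pytest.approx(1 / len(g.truth))
        assert ev.precision["win2"] == 0.5
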