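"""Built-in aligner behaviour, SAM ingest, uniqueness marking."""
import subprocess

import numpy as np
import pytest

from iesmap._util import random_dna, revcomp
from iesmap.align import (
    AlignParams,
    AlignmentRecord,
    ReferenceIndex,
    ingest_sam,
    mark_uniqueness,
    seed_extend_align,
    write_sam,
)
from iesmap.refbuild import Contig, build_conmac
from iesmap.sangerprep import SangerRead


@pytest.fixture(scope="module")
def ref():
    rng = np.random.default_rng(21)
    return build_conmac([Contig("chr1", random_dna(rng, 20_000))], spacer_len=1000)


@pytest.fixture(scope="module")
def index(ref):
    return ReferenceIndex(ref)


def mkread(bases, rid="r"):
    return SangerRead(id=rid, mate_tag="b1", bases=bases, quals=np.full(len(bases), 40))


class TestSeedExtend:
    def test_exact_window_full_length(self, ref, index):
        seq = ref.sequence()[2000:2600]
        recs = seed_extend_align(mkread(seq), index)
        assert len(recs) == 1
        r = recs[0]
        assert (r.ref_start, r.ref_end) == (2000, 2600)
        assert (r.left_clip, r.right_clip) == (0, 0)
        assert r.strand == "+"
        assert r.score == 600

    def test_nonreference_tail_is_clipped(self, ref, index):
        rng = np.random.default_rng(3)
        seq = ref.sequence()[5000:5300] + random_dna(rng, 300)
        recs = [r for r in seed_extend_align(mkread(seq), index) if not r.is_secondary]
        assert len(recs) == 1
        r = recs[0]
        assert r.left_clip == 0
        assert abs(r.right_clip - 300) <= 5  # chance matches may erode a few bp
        assert abs(r.ref_end - 5300) <= 5

    def test_reverse_complement_mirror_clips(self, ref, index):
        rng = np.random.default_rng(4)
        tail = random_dna(rng, 200)
        fwd = mkread(ref.sequence()[8000:8400] + tail, "fwd")
        rev = mkread(revcomp(ref.sequence()[8000:8400] + tail), "rev")
        rf = [r for r in seed_extend_align(fwd, index) if not r.is_secondary][0]
        rr = [r for r in seed_extend_align(rev, index) if not r.is_secondary][0]
        assert rr.strand == "-"
        assert (rr.ref_start, rr.ref_end) == (rf.ref_start, rf.ref_end)
        # clips are reference-oriented, so they coincide, not swap
        assert (rr.left_clip, rr.right_clip) == (rf.left_clip, rf.right_clip)

    def test_substitution_errors_tolerated(self, ref, index):
        seq = list(ref.sequence()[3000:3700])
        for pos in (100, 350, 600):
            seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        recs = [r for r in seed_extend_align(mkread("".join(seq)), index) if not r.is_secondary]
        assert len(recs) == 1
        assert (recs[0].ref_start, recs[0].ref_end) == (3000, 3700)
        assert recs[0].score == 700 - 3 * 4

    def test_no_seed_means_unmapped(self, index):
        rng = np.random.default_rng(9)
        assert seed_extend_align(mkread(random_dna(rng, 100)), index) == []

    def test_split_read_yields_two_segments(self, ref, index):
        # read spans a 2 kb deletion relative to the reference
        seq = ref.sequence()[4000:4300] + ref.sequence()[6300:6600]
        recs = [r for r in seed_extend_align(mkread(seq), index) if not r.is_secondary]
        assert len(recs) == 2
        assert [r.segment_index for r in recs] == [0, 1]
        assert recs[0].ref_start == 4000 and recs[1].ref_end == 6600

    def test_clip_arithmetic_invariant(self, ref, index):
        rng = np.random.default_rng(17)
        for _ in range(20):
            start = int(rng.integers(0, 19_000))
            span = int(rng.integers(60, 900))
            pre = random_dna(rng, int(rng.integers(0, 80)))
            post = random_dna(rng, int(rng.integers(0, 80)))
            read = mkread(pre + ref.sequence()[start : start + span] + post)
            for r in seed_extend_align(read, index):
                assert r.left_clip + (r.read_end - r.read_start) + r.right_clip == len(read)


class TestUniqueness:
    def rec(self, **kw):
        base = dict(
            read_id="r", ref_start=0, ref_end=100, read_start=0, read_end=100,
            strand="+", score=100, read_len=100,
        )
        base.update(kw)
        return AlignmentRecord(**base)

    def test_single_alignment_unique(self):
        recs = mark_uniqueness([self.rec()])
        assert recs[0].is_unique

    def test_equal_score_elsewhere_is_multi(self):
        recs = mark_uniqueness(
            [self.rec(), self.rec(ref_start=5000, ref_end=5100, is_secondary=True)]
        )
        assert not recs[0].is_unique and not recs[1].is_unique

    def test_weak_secondary_keeps_unique(self):
        recs = mark_uniqueness(
            [
                self.rec(),
                self.rec(ref_start=5000, ref_end=5100, score=50, is_secondary=True),
            ],
            score_margin=0.95,
        )
        assert recs[0].is_unique

    def test_repeat_element_detected_as_multi(self, ref):
        # two identical 500 bp windows at different loci
        rng = np.random.default_rng(33)
        element = random_dna(rng, 500)
        seq = ref.sequence()[:20_000]
        doubled = seq[:3000] + element + seq[3500:10_000] + element + seq[10_500:]
        ref2 = build_conmac([Contig("chr1", doubled)], spacer_len=1000)
        idx2 = ReferenceIndex(ref2)
        recs = seed_extend_align(mkread(element[20:480]), idx2)
        mark_uniqueness(recs)
        assert len(recs) >= 2
        assert not any(r.is_unique for r in recs)


class TestSamRoundTrip:
    def test_write_then_ingest(self, ref, index, tmp_path):
        rng = np.random.default_rng(8)
        reads = []
        for i, (start, pre, post) in enumerate([(1000, 0, 0), (2500, 0, 120), (7000, 150, 0)]):
            bases = (
                random_dna(rng, pre)
                + ref.sequence()[start : start + 400]
                + random_dna(rng, post)
            )
            reads.append(mkread(bases, f"r{i}"))
        aligned = [(r, seed_extend_align(r, index)) for r in reads]
        sam = tmp_path / "x.sam"
        write_sam(sam, ref, aligned)
        back, unmapped = ingest_sam(sam, ref)
        assert unmapped == []
        for read, recs in aligned:
            orig = [r for r in recs if not r.is_secondary]
            got = [r for r in back[read.id] if not r.is_secondary]
            assert [(r.ref_start, r.ref_end, r.left_clip, r.right_clip) for r in got] == [
                (r.ref_start, r.ref_end, r.left_clip, r.right_clip) for r in orig
            ]

    def test_cigar_clip_semantics(self, ref, tmp_path):
        sam = tmp_path / "c.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:conMAC\tLN:21000\n"
            "q1\t0\tconMAC\t101\t60\t100S500M\t*\t0\t0\t*\t*\n"
            "q2\t16\tconMAC\t201\t60\t500M100S\t*\t0\t0\t*\t*\n"
            "q3\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t!!!!\n"
        )
        back, unmapped = ingest_sam(sam, ref)
        assert unmapped == ["q3"]
        r1 = back["q1"][0]
        assert (r1.left_clip, r1.right_clip, r1.ref_start) == (100, 0, 100)
        r2 = back["q2"][0]
        # clips in SAM are already reference-oriented for reverse strand
        assert (r2.left_clip, r2.right_clip, r2.strand) == (0, 100, "-")

    def test_reference_name_mismatch_is_hard_error(self, ref, tmp_path):
        sam = tmp_path / "bad.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:other\tLN:500\n"
            "q1\t0\tother\t1\t60\t50M\t*\t0\t0\t*\t*\n"
        )
        with pytest.raises(ValueError, match="reference names"):
            ingest_sam(sam, ref)


class TestExternalAlignerAgreement:
    """The ingest path fed by a real external aligner must reproduce the
    built-in aligner's read classification on clean simulated data."""

    def test_bwa_mem_classification_agreement(self, tmp_path):
        from iesmap import SimConfig
        from iesmap import refbuild as rb
        from iesmap import sangerprep as sp
        from iesmap.pipeline import run_reads
        from iesmap.simulate import simulate_genomes, simulate_reads

        cfg = SimConfig(
            seed=7, contig_lens=(120_000,), n_ies=15, coverage_fraction=1.0,
            error_rate=0.002,
        )
        genomes = simulate_genomes(cfg)
        sim = simulate_reads(genomes, cfg)
        ref2 = build_conmac(genomes.mac_contigs)
        fa = tmp_path / "conMAC.fa"
        fq = tmp_path / "reads.fq"
        rb.write_conmac_fasta(ref2, fa)
        sp.write_fastq(sim.reads, fq)
        subprocess.run(["bwa", "index", str(fa)], check=True, capture_output=True)
        sam = tmp_path / "aln.sam"
        with open(sam, "wb") as fh:
            subprocess.run(
                ["bwa", "mem", "-x", "intractg", str(fa), str(fq)],
                check=True, stdout=fh, stderr=subprocess.DEVNULL,
            )
        records, _ = ingest_sam(sam, ref2)
        res_ext = run_reads(sim.reads, ref2, records_by_read=records)
        res_int = run_reads(sim.reads, ref2)
        ci = {c.read_id: c.category for c in res_int.classifications}
        ce = {c.read_id: c.category for c in res_ext.classifications}
        agree = sum(ci[r] == ce[r] for r in ci)
        assert agree / len(ci) >= 0.9
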