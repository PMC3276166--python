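"""End-to-end orchestration: trim -> align -> classify -> call -> annotate.

This module wires the stage modules together behind one configuration
object so that the command line, the test suite, and the acceptance script
all execute the identical path.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import align as _align
from . import classify as _classify
from . import context as _context
from . import iescall as _iescall
from . import junction as _junction
from . import sangerprep as _prep
from .refbuild import ConMacReference
from .sangerprep import SangerRead
from .simulate import SimConfig, SimulatedGenomes, SimulatedReads, simulate_genomes, simulate_reads
from . import refbuild as _refbuild

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters in one serialisable place."""

    spacer_len: int = 10_000
    min_mean_q: float = 20.0
    min_len: int = 50
    seed_len: int = 20
    seed_step: int = 5
    match: int = 1
    mismatch: int = -3
    min_score: int = 40
    x_drop: int = 20
    score_margin: float = 0.95
    min_ext: int = 10
    edge_margin: int = 100
    max_sep: int = 9
    veto_margin: int = 10
    flank_width: int = 4
    min_olap: int = 20
    min_exon_len: int = 30
    max_intron_len: int = 1000
    bin_bp: int = 10_000

    def align_params(self) -> _align.AlignParams:
        return _align.AlignParams(
            seed_len=self.seed_len,
            seed_step=self.seed_step,
            match=self.match,
            mismatch=self.mismatch,
            min_score=self.min_score,
            x_drop=self.x_drop,
            score_margin=self.score_margin,
        )

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    ref: ConMacReference
    reads_by_id: dict[str, SangerRead]
    records_by_read: dict[str, list[_align.AlignmentRecord]]
    classifications: list[_classify.Classification]
    tally: _classify.Tally
    sites: list[_iescall.IesSite]
    vetoed: list[_iescall.IesSite]
    coverage: int
    contexts: dict[int, list[_context.SiteContext]] = field(default_factory=dict)
    n_discarded: int = 0

    @property
    def full_alignments(self) -> list[_align.AlignmentRecord]:
        return [
            cl.primary
            for cl in self.classifications
            if cl.category is _classify.ReadClass.FULL and cl.unique and cl.primary
        ]


def run_reads(
    reads: Iterable[SangerRead],
    ref: ConMacReference,
    cfg: PipelineConfig = PipelineConfig(),
    gene_models: Sequence[_context.GeneModel] | None = None,
    records_by_read: Mapping[str, list[_align.AlignmentRecord]] | None = None,
) -> PipelineResult:
    """Run the full calling pipeline on trimmed-or-raw reads.

    If ``records_by_read`` is given (e.g. from :func:`iesmap.align.ingest_sam`)
    the built-in aligner is skipped and those records are used instead.
    """
    trimmed, discarded = _prep.trim_reads(
        reads, min_mean_q=cfg.min_mean_q, min_len=cfg.min_len
    )
    reads_by_id = {r.id: r for r in trimmed}

    if records_by_read is None:
        index = _align.ReferenceIndex(ref, seed_len=cfg.seed_len)
        params = cfg.align_params()
        records_by_read = {}
        for read in trimmed:
            recs = _align.seed_extend_align(read, index, params)
            _align.mark_uniqueness(recs, cfg.score_margin)
            records_by_read[read.id] = recs
    else:
        records_by_read = {
            rid: _align.mark_uniqueness(list(recs), cfg.score_margin)
            for rid, recs in records_by_read.items()
        }

    classifications = [
        _classify.classify_read(
            records_by_read.get(r.id, []),
            len(r),
            ref,
            min_ext=cfg.min_ext,
            edge_margin=cfg.edge_margin,
        )
        for r in trimmed
    ]
    # classify_read leaves read_id empty for unmapped reads; fill it in
    for cl, r in zip(classifications, trimmed):
        if not cl.read_id:
            cl.read_id = r.id
    tally = _classify.tally(classifications)

    full = [
        cl.primary
        for cl in classifications
        if cl.category is _classify.ReadClass.FULL and cl.unique and cl.primary
    ]
    evidence = _iescall.collect_breakpoints(classifications, reads_by_id)
    sites, vetoed = _iescall.call_sites(
        evidence, full, max_sep=cfg.max_sep, veto_margin=cfg.veto_margin
    )

    ref_seq = ref.sequence()
    for site in sites:
        jm = _junction.site_junction_model(ref_seq, site, flank=cfg.flank_width)
        if site.category == "win1" and site.l_clips and site.r_clips:
            l_trim = [
                _junction.trim_clip_to_ies(c, ref_seq, site.l_coord, site.r_coord, "L")
                for c in site.l_clips
            ]
            r_trim = [
                _junction.trim_clip_to_ies(c, ref_seq, site.l_coord, site.r_coord, "R")
                for c in site.r_clips
            ]
            asm = _junction.assemble_ies(l_trim, r_trim, min_olap=cfg.min_olap)
            jm.ies_seq = asm.sequence
            jm.ies_len = (
                asm.length + len(jm.microhomology) if asm.length else None
            )
            jm.length_is_exact = asm.is_exact
        site.junction = jm

    contexts: dict[int, list[_context.SiteContext]] = {}
    if gene_models is not None:
        for i, site in enumerate(sites):
            contexts[i] = _context.annotate_site(site, gene_models, ref)

    all_records = [r for recs in records_by_read.values() for r in recs]
    coverage = _context.coverage_bp(all_records, ref)

    return PipelineResult(
        ref=ref,
        reads_by_id=reads_by_id,
        records_by_read=dict(records_by_read),
        classifications=classifications,
        tally=tally,
        sites=sites,
        vetoed=vetoed,
        coverage=coverage,
        contexts=contexts,
        n_discarded=len(discarded),
    )


def run_simulation(
    sim_cfg: SimConfig, cfg: PipelineConfig = PipelineConfig()
) -> tuple[SimulatedGenomes, SimulatedReads, PipelineResult]:
    """Simulate genomes and reads, then run the pipeline on them."""
    genomes = simulate_genomes(sim_cfg)
    sim = simulate_reads(genomes, sim_cfg)
    ref = _refbuild.build_conmac(genomes.mac_contigs, spacer_len=cfg.spacer_len)
    result = run_reads(sim.reads, ref, cfg)
    return genomes, sim, result
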