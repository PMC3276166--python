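"""Gene-model context annotation and genome-level summaries.

Called sites are placed relative to predicted gene models (exon / intron /
intergenic), with the position of an exonic hit within its gene recorded
the way genome-browser annotations express it: ``5'`` (first exon), ``3'``
(last exon), ``Mid`` (internal), ``Single`` (single-exon model), and
``Jxn 3'`` etc. for a site straddling an exon/intron boundary.

Automated gene prediction in AT-rich genomes over-calls tiny exons and
implausibly long introns; rather than manual curation, two configurable
filters (minimum exon length, maximum intron length) set the
``is_plausible`` flag consulted during annotation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np

from .align import AlignmentRecord
from .iescall import IesSite
from .refbuild import ConMacReference, SPACER

log = logging.getLogger(__name__)

DEFAULT_MIN_EXON_LEN = 30
DEFAULT_MAX_INTRON_LEN = 1000


@dataclass
class GeneModel:
    """A predicted gene: ordered exon intervals on one contig.

    Exons are stored 0-based half-open in genomic order (GFF3's 1-based
    inclusive convention is converted at input).
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    is_plausible: bool = True

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (a1, b1), (a2, _b2) in zip(self.exons, self.exons[1:]):
            if a2 < b1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(b1, a2) for (_a1, b1), (a2, _b2) in zip(self.exons, self.exons[1:])]


@dataclass
class SiteContext:
    label: str  # 'exon' | 'intron' | 'intergenic'
    gene_id: str | None = None
    exon_position: str | None = None  # "5'" | "3'" | 'Mid' | 'Single' | "Jxn 3'" ...


def read_gff3(source: str | Path, from_string: bool = False) -> list[GeneModel]:
    """Load gene models (gene -> [mRNA ->] exon) from GFF3."""
    db = gffutils.create_db(
        str(source),
        dbfn=":memory:",
        from_string=from_string,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons = [
            (ex.start - 1, ex.end)
            for ex in db.children(gene, featuretype="exon", order_by="start")
        ]
        if not exons:
            log.warning("gene %s has no exons; skipped", gene.id)
            continue
        models.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=exons,
            )
        )
    return models


def apply_plausibility(
    models: Iterable[GeneModel],
    min_exon_len: int = DEFAULT_MIN_EXON_LEN,
    max_intron_len: int = DEFAULT_MAX_INTRON_LEN,
) -> list[GeneModel]:
    """Flag improbable models: any tiny exon or any atypically long intron."""
    models = list(models)
    for m in models:
        tiny_exon = any(b - a < min_exon_len for a, b in m.exons)
        long_intron = any(b - a > max_intron_len for a, b in m.introns)
        m.is_plausible = not (tiny_exon or long_intron)
    return models


def _exon_ordinal_label(model: GeneModel, exon_idx: int) -> str:
    n = len(model.exons)
    if n == 1:
        return "Single"
    first_is_5prime = model.strand != "-"
    if exon_idx == 0:
        return "5'" if first_is_5prime else "3'"
    if exon_idx == n - 1:
        return "3'" if first_is_5prime else "5'"
    return "Mid"


def annotate_site(
    site: IesSite, models: Sequence[GeneModel], ref: ConMacReference
) -> list[SiteContext]:
    """Context labels for one site against all overlapping plausible models.

    The site window is lifted from conMAC to contig coordinates; a window in
    a spacer (should not occur for real sites) is labelled intergenic. A
    window touching both an exon and an adjacent intron is an exon hit at
    the junction ("Jxn" prefix).
    """
    ws, we = site.window
    contig, local_s = ref.lift_to_contig(ws)
    if contig == SPACER:
        return [SiteContext("intergenic")]
    local_e = local_s + (we - ws)
    out: list[SiteContext] = []
    for m in models:
        if m.contig != contig or not m.is_plausible:
            continue
        g0, g1 = m.span
        if local_e <= g0 or local_s >= g1:
            continue
        hit_exons = [
            i
            for i, (a, b) in enumerate(m.exons)
            if local_s < b and local_e > a
        ]
        if hit_exons:
            i = hit_exons[0]
            pos = _exon_ordinal_label(m, i)
            a, b = m.exons[i]
            in_intron = any(
                local_s < ib and local_e > ia for ia, ib in m.introns
            )
            if in_intron:
                pos = f"Jxn {pos}" if pos != "Single" else "Jxn"
            out.append(SiteContext("exon", m.gene_id, pos))
        else:
            out.append(SiteContext("intron", m.gene_id))
    if not out:
        out.append(SiteContext("intergenic"))
    return out


def coverage_bp(alignments: Iterable[AlignmentRecord], ref: ConMacReference) -> int:
    """Total bp of the somatic genome covered by unique alignments.

    The union of aligned reference intervals, intersected with contig
    intervals (spacer positions never count). Invariant to input order and
    duplication.
    """
    intervals = sorted(
        (r.ref_start, r.ref_end) for r in alignments if r.is_unique and not r.is_secondary
    )
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    contig_iv = ref.contig_intervals()
    total = 0
    for s, e in merged:
        for cs, ce in contig_iv:
            if ce <= s:
                continue
            if cs >= e:
                break
            total += min(e, ce) - max(s, cs)
    return total


def site_distribution(
    sites: Sequence[IesSite], ref: ConMacReference, bin_bp: int
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of site midpoints over fixed-size conMAC bins.

    Returns (counts per bin, boolean flags marking bins wholly inside
    spacers). Useful for chromosome-scale distribution plots.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    n_bins = max(1, -(-ref.total_length // bin_bp))
    mids = [(s.window[0] + s.window[1]) // 2 for s in sites]
    counts, _ = np.histogram(mids, bins=n_bins, range=(0, n_bins * bin_bp))
    contig_iv = ref.contig_intervals()
    spacer_only = np.ones(n_bins, dtype=bool)
    for cs, ce in contig_iv:
        lo = cs // bin_bp
        hi = min(n_bins - 1, (ce - 1) // bin_bp)
        spacer_only[lo : hi + 1] = False
    return counts, spacer_only
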