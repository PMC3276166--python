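"""Calling candidate IES sites from one-end-mapper breakpoints.

A site is called where unique one-end reads depart from MAC-mapping
sequence. Three criteria apply:

1. at least one L and/or R breakpoint;
2. convergent L and R breakpoints may overlap by at most ``max_sep`` bp
   (default 9) in their terminal MAC-matching coordinates — the allowance
   for IES-flanking microhomology retained on both reads — and may likewise
   be separated by a gap of at most ``max_sep`` bp (alignment-end erosion);
3. no fully mapped unique read spans the putative site (the spanning-read
   veto): such a read is direct evidence against an interruption.

Convergent L+R evidence yields a ``win1`` site; L-only evidence ``win2``;
R-only evidence ``win3``. Same-side breakpoints within ``max_sep`` bp of
each other are clustered (median coordinate) before pairing, so a site can
carry multi-read support on either side.

The genome-wide extrapolation follows the two-sided detection argument: if
a fraction ``f`` of the somatic genome is covered by germline reads, a given
excision site is L-covered with probability ~``f`` and independently
R-covered with probability ~``f``, so win1 detects ~``f**2`` of all sites.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from ._util import revcomp
from .align import AlignmentRecord
from .classify import Classification, ReadClass
from .sangerprep import SangerRead

DEFAULT_MAX_SEP = 9
DEFAULT_VETO_MARGIN = 10


@dataclass
class BreakpointEvidence:
    """One read's departure point from MAC-mapping sequence.

    ``coord`` is the conMAC coordinate of the terminal MAC-matching base
    (L: last aligned base, 0-based inclusive; R: first aligned base).
    ``clip_seq`` is the non-mapping extension in reference orientation.
    """

    side: str  # 'L' or 'R'
    coord: int
    read_id: str
    clip_seq: str


@dataclass
class IesSite:
    """A candidate excision site on the conMAC."""

    window: tuple[int, int]  # [start, end) conMAC interval containing the junction
    category: str  # 'win1' | 'win2' | 'win3'
    l_support: list[str] = field(default_factory=list)
    r_support: list[str] = field(default_factory=list)
    l_clips: list[str] = field(default_factory=list)
    r_clips: list[str] = field(default_factory=list)
    #: cluster coordinates: last L-aligned base / first R-aligned base
    l_coord: int | None = None
    r_coord: int | None = None
    vetoed: bool = False
    junction: object | None = None  # JunctionModel, attached downstream

    @property
    def support(self) -> int:
        return len(self.l_support) + len(self.r_support)


def collect_breakpoints(
    classified: Iterable[Classification],
    reads_by_id: Mapping[str, SangerRead],
) -> list[BreakpointEvidence]:
    """Extract breakpoint evidence from unique one-end reads.

    Edge-excluded and multi-mapping reads contribute nothing. The clip
    sequence is taken from the strand-normalised read so that an L clip
    reads 5'->3' into the IES and an R clip reads 5'->3' out of it, both in
    reference orientation.
    """
    evidence: list[BreakpointEvidence] = []
    for cl in classified:
        if cl.category not in (ReadClass.ONE_END_L, ReadClass.ONE_END_R):
            continue
        if not cl.unique or cl.primary is None or cl.breakpoint is None:
            continue
        rec = cl.primary
        read = reads_by_id[cl.read_id]
        oriented = read.bases.upper()
        if rec.strand == "-":
            oriented = revcomp(oriented)
        if cl.side == "L":
            clip = oriented[rec.read_end :]
        else:
            clip = oriented[: rec.read_start]
        evidence.append(
            BreakpointEvidence(
                side=cl.side, coord=cl.breakpoint, read_id=cl.read_id, clip_seq=clip
            )
        )
    return evidence


@dataclass
class _Cluster:
    coord: int
    read_ids: list[str]
    clips: list[str]


def _cluster_side(evidence: list[BreakpointEvidence], max_sep: int) -> list[_Cluster]:
    """Single-linkage clustering of same-side breakpoints within ``max_sep`` bp."""
    clusters: list[_Cluster] = []
    group: list[BreakpointEvidence] = []
    for ev in sorted(evidence, key=lambda e: (e.coord, e.read_id)):
        if group and ev.coord - group[-1].coord > max_sep:
            clusters.append(_finish(group))
            group = []
        group.append(ev)
    if group:
        clusters.append(_finish(group))
    return clusters


def _finish(group: list[BreakpointEvidence]) -> _Cluster:
    coords = sorted(e.coord for e in group)
    median = coords[(len(coords) - 1) // 2]  # lower median: deterministic
    return _Cluster(
        coord=median,
        read_ids=[e.read_id for e in group],
        clips=[e.clip_seq for e in group],
    )


def _converge(l_coord: int, r_coord: int, max_sep: int) -> bool:
    """Criterion 2: overlap of the MAC-matching portions <= max_sep bp,
    and gap between them <= max_sep bp.

    The overlap of an L read ending at ``l_coord`` (inclusive) and an R read
    starting at ``r_coord`` is ``l_coord - r_coord + 1`` bp.
    """
    overlap = l_coord - r_coord + 1
    gap = r_coord - l_coord - 1
    return overlap <= max_sep and gap <= max_sep


def call_sites(
    evidence: Sequence[BreakpointEvidence],
    full_alignments: Sequence[AlignmentRecord],
    max_sep: int = DEFAULT_MAX_SEP,
    veto_margin: int = DEFAULT_VETO_MARGIN,
) -> tuple[list[IesSite], list[IesSite]]:
    """Cluster breakpoints, pair convergent evidence, apply the spanning veto.

    Returns (called sites in conMAC order, vetoed sites). ``full_alignments``
    should be the primary records of unique FULL reads; a site spanned by one
    of them with at least ``veto_margin`` aligned bp on each side is vetoed.
    """
    l_clusters = _cluster_side([e for e in evidence if e.side == "L"], max_sep)
    r_clusters = _cluster_side([e for e in evidence if e.side == "R"], max_sep)

    used_r: set[int] = set()
    sites: list[IesSite] = []
    for lc in l_clusters:
        best_j: int | None = None
        best_d = None
        for j, rc in enumerate(r_clusters):
            if j in used_r or not _converge(lc.coord, rc.coord, max_sep):
                continue
            d = abs(lc.coord - rc.coord)
            if best_d is None or d < best_d:
                best_j, best_d = j, d
        if best_j is not None:
            used_r.add(best_j)
            rc = r_clusters[best_j]
            ws = min(rc.coord, lc.coord + 1)
            we = max(rc.coord, lc.coord + 1, ws + 1)
            sites.append(
                IesSite(
                    window=(ws, we),
                    category="win1",
                    l_support=lc.read_ids,
                    r_support=rc.read_ids,
                    l_clips=lc.clips,
                    r_clips=rc.clips,
                    l_coord=lc.coord,
                    r_coord=rc.coord,
                )
            )
        else:
            sites.append(
                IesSite(
                    window=(lc.coord, lc.coord + 1),
                    category="win2",
                    l_support=lc.read_ids,
                    l_clips=lc.clips,
                    l_coord=lc.coord,
                )
            )
    for j, rc in enumerate(r_clusters):
        if j in used_r:
            continue
        sites.append(
            IesSite(
                window=(rc.coord, rc.coord + 1),
                category="win3",
                r_support=rc.read_ids,
                r_clips=rc.clips,
                r_coord=rc.coord,
            )
        )

    tree = IntervalTree()
    for rec in full_alignments:
        tree.addi(rec.ref_start, rec.ref_end)
    kept: list[IesSite] = []
    vetoed: list[IesSite] = []
    for site in sites:
        ws, we = site.window
        spanned = any(
            iv.begin <= ws - veto_margin and iv.end >= we + veto_margin
            for iv in tree.overlap(ws, we)
        )
        if spanned:
            site.vetoed = True
            vetoed.append(site)
        else:
            kept.append(site)
    kept.sort(key=lambda s: s.window)
    vetoed.sort(key=lambda s: s.window)
    return kept, vetoed


def extrapolate_total(n_win1: int, f: float) -> int:
    """Genome-wide site estimate from the win1 count under the f**2 law."""
    if not 0 < f <= 1:
        raise ValueError("coverage fraction f must be in (0, 1]")
    if n_win1 < 0:
        raise ValueError("n_win1 must be non-negative")
    return round(n_win1 / (f * f))
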