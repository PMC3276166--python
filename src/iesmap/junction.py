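"""Junction microhomology, motif content, and IES sequence assembly.

At a precise excision site the germline locus reads

    left_flank + m + ies_core + m + right_flank

where ``m`` is a short microhomology duplicated at both IES boundaries; the
somatic (MAC) junction retains a single copy:

    left_flank + m + right_flank

Junctions are rendered with lowercase flanks and the retained microhomology
in uppercase (``ttaTTAAtgg``); a blunt join without microhomology uses a
slash (``atat/cctg``). The TA dinucleotide and the full TTAA tetranucleotide
— the motif cleaved by domesticated piggyBac-like transposases implicated in
ciliate DNA elimination — are flagged within the microhomology.

Microhomology search is exact-match only: at the 3-4 bp scale of these
motifs, fuzzy matching is meaningless. When several equally long placements
exist, the leftmost is reported.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

DEFAULT_MAX_MH = 9


@dataclass
class JunctionModel:
    """Decomposition of a somatic junction into flanks and microhomology."""

    left_flank: str
    microhomology: str
    right_flank: str
    has_TA: bool | None = None
    has_TTAA: bool | None = None
    ies_seq: str | None = None
    ies_len: int | None = None
    length_is_exact: bool = True
    flagged: bool = False  # set when the junction could not be reconstructed

    @property
    def mac_junction(self) -> str:
        return self.left_flank + self.microhomology + self.right_flank


def render_junction(jm: JunctionModel) -> str:
    """Lowercase flanks, uppercase microhomology, '/' for a blunt join."""
    if not jm.microhomology:
        return f"{jm.left_flank.lower()}/{jm.right_flank.lower()}"
    return jm.left_flank.lower() + jm.microhomology.upper() + jm.right_flank.lower()


def parse_junction_string(s: str) -> JunctionModel:
    """Inverse of :func:`render_junction` for published junction strings."""
    if "/" in s:
        left, _, right = s.partition("/")
        if "/" in right or any(c.isupper() for c in left + right):
            raise ValueError(f"malformed junction string: {s!r}")
        return JunctionModel(left.upper(), "", right.upper())
    i = 0
    while i < len(s) and s[i].islower():
        i += 1
    j = i
    while j < len(s) and s[j].isupper():
        j += 1
    if j == i or any(c.isupper() for c in s[j:]):
        raise ValueError(f"malformed junction string: {s!r}")
    return JunctionModel(s[:i].upper(), s[i:j].upper(), s[j:].upper())


def detect_motifs(jm: JunctionModel) -> JunctionModel:
    """Flag the TA dinucleotide and the TTAA piggyBac motif in the microhomology."""
    mh = jm.microhomology.upper()
    jm.has_TTAA = "TTAA" in mh
    jm.has_TA = "TA" in mh
    return jm


def compute_microhomology(
    mic_left_boundary: str,
    mic_right_boundary: str,
    mac_junction: str,
    max_mh: int = DEFAULT_MAX_MH,
) -> JunctionModel:
    """Decompose a somatic junction against germline boundary sequence.

    ``mic_left_boundary`` should span the left IES boundary of the germline
    locus (MAC-destined flank running into the IES) and
    ``mic_right_boundary`` the right boundary. The microhomology is the
    longest string ``m`` (up to ``max_mh`` bp) occurring immediately
    3' of the left MAC-matching segment and immediately 5' of the right
    MAC-matching segment in the germline, retained once in ``mac_junction``.
    An empty ``m`` (blunt join) is allowed. If no decomposition is
    consistent, the model is returned flagged.
    """
    left_b = mic_left_boundary.upper()
    right_b = mic_right_boundary.upper()
    jxn = mac_junction.upper()
    n = len(jxn)
    for k in range(min(max_mh, n), -1, -1):
        for i in range(0, n - k + 1):
            a, m, b = jxn[:i], jxn[i : i + k], jxn[i + k :]
            if not a or not b:
                continue
            if (a + m) not in left_b or (m + b) not in right_b:
                continue
            # the germline must diverge at the junction: the full somatic
            # junction may not occur on either boundary
            if jxn in left_b or jxn in right_b:
                continue
            return JunctionModel(a, m, b)
    return JunctionModel(jxn, "", "", flagged=True)


def microhomology_bruteforce(
    mic_left_boundary: str, mic_right_boundary: str, mac_junction: str, max_mh: int = DEFAULT_MAX_MH
) -> int:
    """Exhaustive check of the maximal duplicated-string length (test oracle)."""
    left_b, right_b, jxn = (
        mic_left_boundary.upper(),
        mic_right_boundary.upper(),
        mac_junction.upper(),
    )
    if jxn in left_b or jxn in right_b:
        return -1
    best = -1
    for i in range(len(jxn) + 1):
        for k in range(0, min(max_mh, len(jxn) - i) + 1):
            a, m, b = jxn[:i], jxn[i : i + k], jxn[i + k :]
            if a and b and (a + m) in left_b and (m + b) in right_b:
                best = max(best, k)
    return best


@dataclass
class AssemblyResult:
    sequence: str | None
    length: int
    is_exact: bool
    ambiguous: bool = False


def assemble_ies(
    l_exts: Sequence[str],
    r_exts: Sequence[str],
    min_olap: int = 20,
    min_identity: float = 0.95,
) -> AssemblyResult:
    """Join the non-mapping extensions of L and R reads into a full IES core.

    Both inputs are reference-oriented clip sequences: L extensions are
    prefixes of the IES core, R extensions suffixes. If an overlap of at
    least ``min_olap`` bp (>= ``min_identity`` exact) joins the longest L
    extension to the longest R extension, the merged sequence and its exact
    length are returned; a contained extension is also exact. Otherwise the
    longest extension length is returned as a lower bound. Multiple
    incompatible overlaps flag the result as ambiguous with no assembly.
    """
    if not l_exts or not r_exts:
        ext = max(list(l_exts) + list(r_exts), key=len, default="")
        return AssemblyResult(None, len(ext), is_exact=False)
    l = max(l_exts, key=len)
    r = max(r_exts, key=len)
    merged: list[str] = []
    for olap in range(min(len(l), len(r)), min_olap - 1, -1):
        a, b = l[-olap:], r[:olap]
        matches = sum(x == y for x, y in zip(a, b))
        if matches >= min_identity * olap:
            cand = l + r[olap:]
            if cand not in merged:
                merged.append(cand)
    if len(merged) == 1:
        return AssemblyResult(merged[0], len(merged[0]), is_exact=True)
    if len(merged) > 1:
        return AssemblyResult(None, max(len(l), len(r)), is_exact=False, ambiguous=True)
    if r in l:
        return AssemblyResult(l, len(l), is_exact=True)
    if l in r:
        return AssemblyResult(r, len(r), is_exact=True)
    return AssemblyResult(None, max(len(l), len(r)), is_exact=False)


def trim_clip_to_ies(
    clip: str, ref_seq: str, site_l: int, site_r: int, side: str, min_trim: int = 5
) -> str:
    """Remove MAC-destined carry-over from a clip sequence.

    An L clip may run past the IES and re-enter MAC-destined sequence (the
    part of the read beyond the far boundary that was too short to realign);
    that carry-over equals the reference from the R breakpoint onward, so the
    longest matching suffix (>= ``min_trim`` bp, to avoid eroding chance
    matches) is removed. Symmetrically for R clips against the reference
    left of the L breakpoint.
    """
    clip = clip.upper()
    t_best = 0
    if side == "L":
        tail = ref_seq[site_r : site_r + len(clip)]
        for t in range(min(len(clip), len(tail)), min_trim - 1, -1):
            if clip[-t:] == tail[:t]:
                t_best = t
                break
        return clip[: len(clip) - t_best] if t_best else clip
    head = ref_seq[max(0, site_l + 1 - len(clip)) : site_l + 1]
    for t in range(min(len(clip), len(head)), min_trim - 1, -1):
        if clip[:t] == head[-t:]:
            t_best = t
            break
    return clip[t_best:] if t_best else clip


def site_junction_model(ref_seq: str, site, flank: int = 4) -> JunctionModel:
    """Junction model for a called site directly from cluster coordinates.

    For a convergent (win1) site the retained microhomology is exactly the
    overlap of the L- and R-aligned reference intervals; flanks are drawn
    from the reference for rendering.
    """
    l, r = site.l_coord, site.r_coord
    if l is None or r is None:
        ws, we = site.window
        return JunctionModel(
            ref_seq[max(0, ws - flank) : ws], "", ref_seq[we : we + flank], flagged=True
        )
    if l >= r:  # overlapping terminal coordinates: retained microhomology
        mh = ref_seq[r : l + 1]
        left = ref_seq[max(0, r - flank) : r]
        right = ref_seq[l + 1 : l + 1 + flank]
    else:  # blunt or eroded: no retained duplication
        mh = ""
        left = ref_seq[max(0, l + 1 - flank) : l + 1]
        right = ref_seq[r : r + flank]
    return detect_motifs(JunctionModel(left, mh, right))


def compare_junctions(junctions: Sequence[str]) -> tuple[int, int, dict[str, int]]:
    """Group junction strings by length and by exact sequence.

    Returns (number of distinct lengths, number of distinct sequences,
    per-sequence counts). Used to characterise heterogeneous-boundary IES
    whose excision products differ between events or strains.
    """
    if not junctions:
        raise ValueError("at least one junction required")
    norm = [j.upper() for j in junctions]
    counts = dict(Counter(norm))
    return len({len(j) for j in norm}), len(counts), counts
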