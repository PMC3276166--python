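"""Synthetic germline/somatic genome pairs with planted IES, and read simulation.

The generator emulates the data regime of Sanger-era germline (MIC) genome
sequencing of a ciliate: ~75% AT genomes, paired-end reads off ~8 kbp clone
inserts, and two classes of planted internal eliminated sequences (IES):

* ``short_precise`` — <500 bp, with a 3-4 bp boundary microhomology that
  contains TA (the full TTAA piggyBac motif with configurable probability)
  duplicated at both boundaries in the germline and retained once in the
  somatic junction;
* ``long_heterogeneous`` — 1-3 kbp, blunt boundaries, plus a small set of
  alternative cut points modelling junction heterogeneity between excision
  events.

Ground truth records every planted IES so that calling performance
(precision/recall per win category, positional error, microhomology
accuracy) can be measured exactly.

Planted junctions are locally non-extendable: the IES core is resampled at
its ends until no positively scoring gapless extension carries an alignment
across the junction in either genome. Without this constraint the *actual*
maximal microhomology at a junction would occasionally exceed the planted
one (chance base agreement), making the ground-truth labels wrong.

Read placement supports a target junction-coverage fraction ``f``: the
number of fragments is calibrated so that any given junction side is
covered by a qualifying one-end read with probability ``f`` (Poisson
approximation, exact for IES longer than a read). ``f = 1`` switches to a
guarantee mode that plants qualifying reads at every junction side plus
uniform background.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._util import random_dna, revcomp
from .iescall import IesSite
from .refbuild import Contig, ConMacReference
from .sangerprep import SangerRead

SHORT_PRECISE = "short_precise"
LONG_HETEROGENEOUS = "long_heterogeneous"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated sequencing experiment."""

    seed: int = 0
    contig_lens: tuple[int, ...] = (200_000, 150_000, 100_000)
    at_fraction: float = 0.75
    n_ies: int = 30
    short_fraction: float = 0.5
    short_len_range: tuple[int, int] = (100, 500)
    long_len_range: tuple[int, int] = (1000, 3000)
    mh_len_range: tuple[int, int] = (3, 4)
    p_ttaa: float = 0.75
    boundary_heterogeneity: int = 3
    frag_len_mean: float = 8000.0
    frag_len_sd: float = 800.0
    read_len_mean: float = 750.0
    read_len_sd: float = 50.0
    error_rate: float = 0.001
    coverage_fraction: float = 0.25
    #: minimum MAC-bp between planted junctions, and keep-out from contig ends
    min_ies_spacing: int = 2000
    placement_margin: int = 12_000
    #: geometry constants mirrored from the alignment/classification stages:
    #: a qualifying one-end read needs >= min_anchor aligned bp and a clip
    #: strictly longer than min_ext
    min_anchor: int = 40
    min_ext: int = 10
    #: background read coverage used in the f=1 guarantee mode
    background_coverage: float = 1.0
    #: optional multi-mapper mode: plant this many identical copies of a
    #: repeat element in the somatic genome (0 disables)
    n_repeat_copies: int = 0
    repeat_len: int = 2000


@dataclass
class GroundTruthIes:
    """Simulator record of one planted IES."""

    ies_id: str
    contig: str
    #: contig-local MAC coordinate of the junction window start (the retained
    #: microhomology occupies [mac_pos, mac_pos + len(mh)))
    mac_pos: int
    microhomology: str
    core: str  # strictly germline-specific sequence
    cls: str  # SHORT_PRECISE | LONG_HETEROGENEOUS
    alt_boundaries: list[tuple[int, int]] = field(default_factory=list)
    #: germline (MIC contig) coordinates of the core
    mic_core_start: int = 0
    mic_core_end: int = 0

    @property
    def ies_len(self) -> int:
        """Length of eliminated DNA: the core plus one microhomology copy."""
        return len(self.core) + len(self.microhomology)


@dataclass
class SimulatedGenomes:
    mac_contigs: list[Contig]
    mic_contigs: list[Contig]
    truth: list[GroundTruthIes]


@dataclass
class ReadPlacement:
    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    mate: str


@dataclass
class SimulatedReads:
    reads: list[SangerRead]
    placements: list[ReadPlacement]


# -- junction non-extendability ----------------------------------------------

_CHECK_DEPTH = 60


def _max_prefix_score(a: str, b: str, match: int = 1, mismatch: int = -3) -> int:
    best = s = 0
    for x, y in zip(a, b):
        s += match if x == y else mismatch
        best = max(best, s)
        if s < best - 20:
            break
    return best


def _nonextendable(a: str, b: str) -> bool:
    """True iff no gapless local extension of ``a`` vs ``b`` scores > 0."""
    return _max_prefix_score(a[:_CHECK_DEPTH], b[:_CHECK_DEPTH]) <= 0


def _draw_microhomology(rng: np.random.Generator, cfg: SimConfig) -> str:
    lo, hi = cfg.mh_len_range
    k = int(rng.integers(lo, hi + 1))
    if k >= 4 and rng.random() < cfg.p_ttaa:
        return "TTAA"
    while True:
        off = int(rng.integers(0, k - 1))
        rest = random_dna(rng, k - 2, cfg.at_fraction)
        mh = rest[:off] + "TA" + rest[off:]
        if mh != "TTAA":
            return mh


def _draw_core(
    rng: np.random.Generator, cfg: SimConfig, length: int, left_ctx: str, right_ctx: str
) -> str:
    """Random core whose ends cannot extend an alignment across either junction.

    ``left_ctx`` is the somatic sequence immediately right of the junction
    (what an alignment entering from the left would continue into);
    ``right_ctx`` is the reversed somatic sequence immediately left of it.
    """
    for _ in range(500):
        core = random_dna(rng, length, cfg.at_fraction)
        if _nonextendable(core, left_ctx) and _nonextendable(core[::-1], right_ctx):
            return core
    raise RuntimeError("could not draw a non-extendable core")


def simulate_genomes(cfg: SimConfig) -> SimulatedGenomes:
    """Generate somatic contigs, the germline counterpart, and ground truth.

    With ``n_ies == 0`` the germline equals the somatic genome exactly.
    Output is byte-identical across runs for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    mac_seqs = {
        f"contig{i:03d}": list(random_dna(rng, L, cfg.at_fraction))
        for i, L in enumerate(sorted(cfg.contig_lens, reverse=True))
    }
    if cfg.n_repeat_copies > 1:
        _plant_repeats(rng, cfg, mac_seqs)

    # junction positions: stratified-uniform with a guaranteed minimum
    # spacing (one jittered position per equal-width slot), contigs
    # allocated counts proportional to usable length
    names = list(mac_seqs)
    usable = np.array(
        [max(0, len(mac_seqs[n]) - 2 * cfg.placement_margin) for n in names], float
    )
    if cfg.n_ies > 0 and usable.sum() <= 0:
        raise ValueError("contigs too short for the placement margin")
    quota = usable / usable.sum() * cfg.n_ies if cfg.n_ies else usable * 0
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts))[: cfg.n_ies - counts.sum()]:
        counts[i] += 1
    positions: dict[str, list[int]] = {n: [] for n in names}
    for c, n_c in zip(names, counts):
        if n_c == 0:
            continue
        span = len(mac_seqs[c]) - 2 * cfg.placement_margin
        slot = span / n_c
        if slot <= cfg.min_ies_spacing:
            raise RuntimeError(
                f"cannot place {n_c} IES at {cfg.min_ies_spacing} bp spacing "
                f"in contig {c}"
            )
        jitter = slot - cfg.min_ies_spacing
        positions[c] = [
            int(cfg.placement_margin + i * slot + rng.uniform(0, jitter))
            for i in range(n_c)
        ]

    truth: list[GroundTruthIes] = []
    idx = 0
    for c in names:
        for p in sorted(positions[c]):
            is_short = rng.random() < cfg.short_fraction
            if is_short:
                mh = _draw_microhomology(rng, cfg)
                mac_seqs[c][p : p + len(mh)] = list(mh)
                total = int(rng.integers(cfg.short_len_range[0], cfg.short_len_range[1] + 1))
                core_len = max(10, total - len(mh))
                cls = SHORT_PRECISE
                alt: list[tuple[int, int]] = []
            else:
                mh = ""
                core_len = int(rng.integers(cfg.long_len_range[0], cfg.long_len_range[1] + 1))
                cls = LONG_HETEROGENEOUS
                alt = [(0, 0)]
                while len(alt) < max(1, cfg.boundary_heterogeneity):
                    cand = (int(rng.integers(0, 16)), int(rng.integers(0, 16)))
                    if cand != (0, 0) and cand not in alt:
                        alt.append(cand)
            mac = mac_seqs[c]
            left_ctx = "".join(mac[p + len(mh) : p + len(mh) + _CHECK_DEPTH])
            right_ctx = "".join(mac[max(0, p - _CHECK_DEPTH) : p])[::-1]
            core = _draw_core(rng, cfg, core_len, left_ctx, right_ctx)
            truth.append(
                GroundTruthIes(
                    ies_id=f"ies{idx:04d}",
                    contig=c,
                    mac_pos=p,
                    microhomology=mh,
                    core=core,
                    cls=cls,
                    alt_boundaries=alt,
                )
            )
            idx += 1

    mac_contigs: list[Contig] = []
    mic_contigs: list[Contig] = []
    for c in names:
        mac = "".join(mac_seqs[c])
        mac_contigs.append(Contig(name=c, sequence=mac))
        parts: list[str] = []
        prev = 0
        shift = 0
        for t in sorted((t for t in truth if t.contig == c), key=lambda t: t.mac_pos):
            k = len(t.microhomology)
            parts.append(mac[prev : t.mac_pos + k])
            t.mic_core_start = t.mac_pos + k + shift
            t.mic_core_end = t.mic_core_start + len(t.core)
            parts.append(t.core)
            prev = t.mac_pos  # germline repeats the microhomology then continues
            shift += len(t.core) + k
        parts.append(mac[prev:])
        mic_contigs.append(Contig(name=c, sequence="".join(parts)))
    return SimulatedGenomes(mac_contigs, mic_contigs, truth)


def _plant_repeats(rng: np.random.Generator, cfg: SimConfig, mac_seqs: dict[str, list[str]]) -> None:
    """Copy one repeat element to several somatic locations (multi-mapper mode)."""
    element = random_dna(rng, cfg.repeat_len, cfg.at_fraction)
    names = list(mac_seqs)
    for _ in range(cfg.n_repeat_copies):
        c = names[int(rng.integers(len(names)))]
        L = len(mac_seqs[c])
        p = int(rng.integers(cfg.placement_margin, L - cfg.placement_margin - cfg.repeat_len))
        mac_seqs[c][p : p + cfg.repeat_len] = list(element)


# -- read simulation ----------------------------------------------------------


def _qual_profile(rng: np.random.Generator, n: int) -> np.ndarray:
    """Sanger-like quality profile: high plateau, decay over the final 40%."""
    x = np.arange(n) / max(n - 1, 1)
    q = 40.0 - 18.0 * np.clip((x - 0.6) / 0.4, 0.0, 1.0)
    q = q + rng.normal(0.0, 2.0, size=n)
    return np.clip(np.rint(q), 2, 60).astype(np.int32)


def _apply_errors(
    rng: np.random.Generator, bases: str, quals: np.ndarray, error_rate: float
) -> str:
    if error_rate <= 0:
        return bases
    p = 10.0 ** (-quals / 10.0)
    p *= error_rate / p.mean()
    p = np.clip(p, 0.0, 0.75)
    hits = np.nonzero(rng.random(len(bases)) < p)[0]
    if not hits.size:
        return bases
    out = list(bases)
    alphabet = "ACGT"
    for i in hits:
        choices = [b for b in alphabet if b != out[i]]
        out[i] = choices[int(rng.integers(3))]
    return "".join(out)


def _read_len(rng: np.random.Generator, cfg: SimConfig, cap: int) -> int:
    if cfg.read_len_sd <= 0:
        r = cfg.read_len_mean
    else:
        r = rng.normal(cfg.read_len_mean, cfg.read_len_sd)
    return int(np.clip(round(r), 300, cap))


def _frag_len(rng: np.random.Generator, cfg: SimConfig, cap: int) -> int:
    lo = int(2 * cfg.read_len_mean + 100)
    hi = min(cap, int(cfg.frag_len_mean + 4 * cfg.frag_len_sd))
    f = rng.normal(cfg.frag_len_mean, cfg.frag_len_sd) if cfg.frag_len_sd > 0 else cfg.frag_len_mean
    return int(np.clip(round(f), lo, max(lo, hi)))


def _emit_fragment(
    rng: np.random.Generator,
    cfg: SimConfig,
    contig_name: str,
    seq: str,
    start: int,
    frag_len: int,
    frag_id: str,
    reads: list[SangerRead],
    placements: list[ReadPlacement],
    b1_len: int | None = None,
) -> None:
    end = start + frag_len
    r1 = b1_len if b1_len is not None else _read_len(rng, cfg, frag_len // 2)
    r2 = _read_len(rng, cfg, frag_len // 2)
    for mate, s, e, strand in (
        ("b1", start, start + r1, "+"),
        ("g1", end - r2, end, "-"),
    ):
        bases = seq[s:e]
        if strand == "-":
            bases = revcomp(bases)
        quals = _qual_profile(rng, len(bases))
        bases = _apply_errors(rng, bases, quals, cfg.error_rate)
        rid = f"{frag_id}.{mate}"
        reads.append(SangerRead(id=rid, mate_tag=mate, bases=bases, quals=quals))
        placements.append(ReadPlacement(rid, contig_name, s, e, strand, mate))


def qualifying_window(
    t: GroundTruthIes, side: str, read_len: int, cfg: SimConfig
) -> tuple[int, int]:
    """Germline start-coordinate interval [lo, hi] of reads that yield
    one-end evidence for this junction side.

    A qualifying read aligns with at least ``min_anchor`` bp on the somatic
    side of the junction, clips more than ``min_ext`` bp into the core, and
    does not reach far enough across the IES to re-anchor on the other side.
    """
    a, e = cfg.min_anchor, cfg.min_ext
    if side == "L":
        q = t.mic_core_start
        lo = q + e + 1 - read_len
        hi = min(q - a, t.mic_core_end + a - 1 - read_len)
    else:
        q = t.mic_core_end
        lo = max(q + a - read_len, t.mic_core_start - a + 1)
        hi = q - e - 1
    return lo, hi


def fragments_for_coverage(cfg: SimConfig, contig_len: int) -> int:
    """Per-contig fragment count so that a junction side is read-covered
    with probability f.

    Inverts the Poisson approximation ``f = 1 - exp(-lambda)`` with
    ``lambda = 2 * n_frag * w / (L - F)``, where ``w`` is the expected
    qualifying-window width of a read (exact for IES longer than a read;
    short IES present a narrower window and are detected less often).
    """
    f = cfg.coverage_fraction
    if not 0 < f < 1:
        raise ValueError("fragments_for_coverage requires 0 < f < 1")
    lam = -math.log1p(-f)
    w = cfg.read_len_mean - cfg.min_anchor - cfg.min_ext
    span = max(1.0, contig_len - cfg.frag_len_mean)
    return max(1, int(round(lam * span / (2 * w))))


def simulate_reads(genomes: SimulatedGenomes, cfg: SimConfig) -> SimulatedReads:
    """Paired Sanger-like reads from the germline genome.

    With ``coverage_fraction < 1`` fragments are placed uniformly at the
    calibrated density; with ``coverage_fraction >= 1`` every junction side
    additionally receives two guaranteed qualifying reads (full-coverage
    limit) on top of uniform background at ``background_coverage``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    reads: list[SangerRead] = []
    placements: list[ReadPlacement] = []
    mic = {c.name: c.sequence for c in genomes.mic_contigs}
    lens = {n: len(s) for n, s in mic.items()}
    guarantee = cfg.coverage_fraction >= 1.0

    frag_no = 0
    for name, seq in mic.items():
        L = lens[name]
        if L < cfg.frag_len_mean + 1:
            raise ValueError(f"contig {name} shorter than a clone insert")
        if guarantee:
            n_frag = int(
                round(cfg.background_coverage * L / (2 * cfg.read_len_mean))
            )
        else:
            n_frag = fragments_for_coverage(cfg, L)
        for _ in range(n_frag):
            F = _frag_len(rng, cfg, L)
            s = int(rng.integers(0, L - F + 1))
            _emit_fragment(
                rng, cfg, name, seq, s, F, f"{name}_frag{frag_no:06d}", reads, placements
            )
            frag_no += 1

    if guarantee:
        for t in genomes.truth:
            seq = mic[t.contig]
            L = lens[t.contig]
            for side in "LR":
                for _ in range(2):
                    r = _read_len(rng, cfg, int(cfg.frag_len_mean) // 2)
                    lo, hi = qualifying_window(t, side, r, cfg)
                    if hi < lo:
                        continue
                    x = int(rng.integers(lo, hi + 1))
                    F = _frag_len(rng, cfg, L)
                    if x + F <= L:
                        _emit_fragment(
                            rng, cfg, t.contig, seq, x, F,
                            f"{t.contig}_tgt{frag_no:06d}", reads, placements, b1_len=r,
                        )
                    else:
                        # hang the fragment leftward; the g1 read is the
                        # qualifying one and covers [x, x + r)
                        s = x + r - F
                        if s < 0:
                            continue
                        _emit_fragment(
                            rng, cfg, t.contig, seq, s, F,
                            f"{t.contig}_tgt{frag_no:06d}", reads, placements,
                        )
                        # replace the g1 read to end exactly at x + r
                        reads.pop()
                        placements.pop()
                        bases = seq[x : x + r]
                        quals = _qual_profile(rng, r)
                        bases = _apply_errors(rng, revcomp(bases), quals, cfg.error_rate)
                        rid = f"{t.contig}_tgt{frag_no:06d}.g1"
                        reads.append(
                            SangerRead(id=rid, mate_tag="g1", bases=bases, quals=quals)
                        )
                        placements.append(
                            ReadPlacement(rid, t.contig, x, x + r, "-", "g1")
                        )
                    frag_no += 1
    return SimulatedReads(reads=reads, placements=placements)


def expected_detectable(
    genomes: SimulatedGenomes, sim: SimulatedReads, cfg: SimConfig
) -> set[str]:
    """IES ids with at least one qualifying read on each side (given the
    actual read placements) — the set a perfect caller should recover as win1."""
    out: set[str] = set()
    for t in genomes.truth:
        got = {"L": False, "R": False}
        for pl in sim.placements:
            if pl.contig != t.contig:
                continue
            r = pl.end - pl.start
            for side in "LR":
                lo, hi = qualifying_window(t, side, r, cfg)
                if lo <= pl.start <= hi:
                    got[side] = True
        if got["L"] and got["R"]:
            out.add(t.ies_id)
    return out


def variant_junction_strings(
    t: GroundTruthIes, mic_contig: Contig, width: int = 6
) -> list[str]:
    """Somatic junction sequences for each alternative excision boundary.

    Each alternative (dl, dr) cuts the germline locus at ``core_start - dl``
    and ``core_end + dr``; the returned strings are ``width`` bp of somatic
    sequence either side of the resulting join.
    """
    seq = mic_contig.sequence
    assert seq is not None
    out = []
    for dl, dr in t.alt_boundaries or [(0, 0)]:
        cut_l = t.mic_core_start - dl
        cut_r = t.mic_core_end + dr
        out.append(seq[cut_l - width : cut_l] + seq[cut_r : cut_r + width])
    return out


# -- evaluation ---------------------------------------------------------------


@dataclass
class EvalResult:
    n_truth: int
    recall: dict[str, float]  # per win category and 'any'
    precision: dict[str, float | None]  # None when no sites of that category
    positional_errors: list[int]  # signed window-start offsets of win1 matches
    microhomology_accuracy: float | None
    matched_win1: set[str] = field(default_factory=set)

    def as_dict(self) -> dict:
        return {
            "n_truth": self.n_truth,
            "recall": self.recall,
            "precision": self.precision,
            "positional_errors": self.positional_errors,
            "microhomology_accuracy": self.microhomology_accuracy,
        }


def _interval_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    if a[1] <= b[0]:
        return b[0] - a[1] + 1
    if b[1] <= a[0]:
        return a[0] - b[1] + 1
    return 0


def evaluate_calls(
    sites: Sequence[IesSite],
    truth: Sequence[GroundTruthIes],
    ref: ConMacReference,
    tol: int = 9,
    ref_seq: str | None = None,
) -> EvalResult:
    """Score called sites against the ground truth.

    A planted IES is recovered by a site whose window lies within ``tol`` bp
    of its somatic junction window. Microhomology accuracy is assessed on
    win1 matches using the junction model derived from cluster coordinates.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    from .junction import site_junction_model

    truth_windows = {}
    for t in truth:
        start = ref.lift_to_conmac(t.contig, t.mac_pos)
        truth_windows[t.ies_id] = (start, start + max(1, len(t.microhomology)))

    matched_by_cat: dict[str, set[str]] = {"win1": set(), "win2": set(), "win3": set()}
    site_matches: list[bool] = []
    positional: list[int] = []
    mh_ok = 0
    mh_n = 0
    if ref_seq is None and all(c.sequence is not None for c in ref.contigs):
        ref_seq = ref.sequence()
    for site in sites:
        hit = None
        best = None
        for tid, w in truth_windows.items():
            d = _interval_distance(site.window, w)
            if d <= tol and (best is None or d < best):
                hit, best = tid, d
        site_matches.append(hit is not None)
        if hit is None:
            continue
        matched_by_cat[site.category].add(hit)
        if site.category == "win1":
            positional.append(site.window[0] - truth_windows[hit][0])
            if ref_seq is not None and site.l_coord is not None:
                jm = site_junction_model(ref_seq, site)
                t = next(t for t in truth if t.ies_id == hit)
                mh_n += 1
                if jm.microhomology.upper() == t.microhomology.upper():
                    mh_ok += 1

    n_truth = len(truth)
    recall = {
        cat: (len(ids) / n_truth if n_truth else float("nan"))
        for cat, ids in matched_by_cat.items()
    }
    any_matched = set().union(*matched_by_cat.values())
    recall["any"] = len(any_matched) / n_truth if n_truth else float("nan")
    precision: dict[str, float | None] = {}
    for cat in ("win1", "win2", "win3"):
        cat_sites = [m for s, m in zip(sites, site_matches) if s.category == cat]
        precision[cat] = (sum(cat_sites) / len(cat_sites)) if cat_sites else None
    all_n = len(sites)
    precision["any"] = (sum(site_matches) / all_n) if all_n else None
    return EvalResult(
        n_truth=n_truth,
        recall=recall,
        precision=precision,
        positional_errors=positional,
        microhomology_accuracy=(mh_ok / mh_n) if mh_n else None,
        matched_win1=matched_by_cat["win1"],
    )
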