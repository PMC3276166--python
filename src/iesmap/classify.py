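"""Sorting reads into alignment categories.

Every germline read falls into exactly one category after alignment to the
conMAC:

* ``FULL`` — aligned end to end (terminal clips of at most ``min_ext`` bp on
  both sides), no internal discontinuity. These reads argue *against* an
  elimination site anywhere under their span.
* ``ONE_END_L`` / ``ONE_END_R`` — aligned from one end only, with a
  non-mapping terminal extension of more than ``min_ext`` bp (default 10,
  strictly greater) on the other end. The extension is interpreted as the
  read running into micronucleus-specific sequence: an L read aligns on the
  browser-left of a putative IES, an R read on the browser-right.
* ``DISCONTINUOUS`` — clipped on both ends, split into multiple segments, or
  containing an internal break; possibly a cloning artifact, never used as
  elimination evidence.
* ``EDGE_EXCLUDED`` — a one-end read whose breakpoint lies within
  ``edge_margin`` bp of a contig end (or in a spacer); the clip is more
  plausibly an assembly-edge artifact.
* ``UNMAPPED`` — no alignment at all; candidate germline-specific content.

Each category is crossed with a unique/multi-mapper flag taken from the
alignment stage.
"""
from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .align import AlignmentRecord
from .refbuild import ConMacReference

DEFAULT_MIN_EXT = 10
DEFAULT_EDGE_MARGIN = 100


class ReadClass(str, Enum):
    FULL = "FULL"
    ONE_END_L = "ONE_END_L"
    ONE_END_R = "ONE_END_R"
    DISCONTINUOUS = "DISCONTINUOUS"
    EDGE_EXCLUDED = "EDGE_EXCLUDED"
    UNMAPPED = "UNMAPPED"


@dataclass
class Classification:
    read_id: str
    category: ReadClass
    unique: bool = True
    primary: AlignmentRecord | None = None
    #: conMAC coordinate of the terminal MAC-matching base for one-end reads
    #: (L: last aligned base, inclusive; R: first aligned base).
    breakpoint: int | None = None
    #: side of the putative IES the read aligns on ('L'/'R'), one-end reads only
    side: str | None = None


def classify_read(
    records: Sequence[AlignmentRecord],
    read_len: int,
    ref: ConMacReference,
    min_ext: int = DEFAULT_MIN_EXT,
    edge_margin: int = DEFAULT_EDGE_MARGIN,
) -> Classification:
    """Assign one read to its alignment category.

    ``min_ext`` is a strict threshold: a clip of exactly ``min_ext`` bp still
    counts as fully aligned ("more than 10 bp" is strictly greater-than).
    """
    read_id = records[0].read_id if records else ""
    if not records:
        return Classification(read_id=read_id, category=ReadClass.UNMAPPED)
    unique = records[0].is_unique
    primaries = sorted(
        (r for r in records if not r.is_secondary), key=lambda r: r.read_start
    )
    if not primaries:
        primaries = sorted(records, key=lambda r: r.read_start)
    if len(primaries) > 1 or any(r.has_internal_break for r in primaries):
        return Classification(read_id, ReadClass.DISCONTINUOUS, unique, primaries[0])
    p = primaries[0]
    lc, rc = p.left_clip, p.right_clip
    if lc <= min_ext and rc <= min_ext:
        return Classification(read_id, ReadClass.FULL, unique, p)
    if lc > min_ext and rc > min_ext:
        return Classification(read_id, ReadClass.DISCONTINUOUS, unique, p)
    if rc > min_ext:  # aligned by its left end; IES to the right
        side, bp = "L", p.ref_end - 1
    else:  # aligned by its right end; IES to the left
        side, bp = "R", p.ref_start
    if ref.is_near_contig_edge(bp, edge_margin):
        return Classification(read_id, ReadClass.EDGE_EXCLUDED, unique, p, bp, side)
    category = ReadClass.ONE_END_L if side == "L" else ReadClass.ONE_END_R
    return Classification(read_id, category, unique, p, bp, side)


@dataclass
class Tally:
    """Per-category read counts, crossed with uniqueness."""

    counts: dict[tuple[str, str], int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def category(self, cat: ReadClass | str) -> int:
        cat = str(getattr(cat, "value", cat))
        return sum(n for (c, _u), n in self.counts.items() if c == cat)

    @property
    def n_left(self) -> int:
        return self.category(ReadClass.ONE_END_L)

    @property
    def n_right(self) -> int:
        return self.category(ReadClass.ONE_END_R)

    @property
    def n_one_end(self) -> int:
        return self.n_left + self.n_right

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "by_category": {
                f"{cat}:{uni}": n for (cat, uni), n in sorted(self.counts.items())
            },
            "one_end_L": self.n_left,
            "one_end_R": self.n_right,
        }


def tally(classifications: Iterable[Classification]) -> Tally:
    counts: Counter[tuple[str, str]] = Counter()
    for cl in classifications:
        counts[(cl.category.value, "unique" if cl.unique else "multi")] += 1
    return Tally(counts=dict(counts))


def write_tally_json(t: Tally, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(t.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
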