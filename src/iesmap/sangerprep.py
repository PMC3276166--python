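"""Vector and quality trimming of Sanger-style reads.

Reads come from paired-end (b1/g1) sequencing of a large-insert clone
library, so each read may start or end in cloning-vector sequence and the
base quality typically decays toward the read ends. Trimming is two-stage:

1. :func:`trim_vector` removes terminal segments that exactly match vector
   sequence; internal vector hits flag the read as a suspect chimera but do
   not alter it.
2. :func:`quality_trim` keeps the longest contiguous sub-read whose mean
   phred quality reaches a threshold (default Q20), discarding reads whose
   best window is too short to be mappable.

Averaging is done on the phred scale. The "longest window with mean >= Q"
criterion is deterministic, reduces to whole-read behaviour when the whole
read qualifies, and is tie-broken leftmost.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

DEFAULT_MIN_MEAN_Q = 20.0
DEFAULT_MIN_LEN = 50


@dataclass
class SangerRead:
    """One Sanger read with per-base phred qualities.

    ``mate_tag`` records the pairing convention (``"b1"`` = forward read off
    one end of the clone insert, ``"g1"`` = reverse read off the other).
    """

    id: str
    mate_tag: str
    bases: str
    quals: np.ndarray
    vector_flagged: bool = False

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int32)
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.id}: bases/quals length mismatch")
        if len(self.quals) and (self.quals.min() < 0 or self.quals.max() > 93):
            raise ValueError(f"read {self.id}: phred scores outside [0, 93]")

    def __len__(self) -> int:
        return len(self.bases)

    def subread(self, start: int, end: int) -> "SangerRead":
        return replace(self, bases=self.bases[start:end], quals=self.quals[start:end])


def _longest_terminal_vector_match(read_end: str, vector_seqs: Sequence[str], min_match: int) -> int:
    """Length of the longest prefix of ``read_end`` found inside any vector."""
    best = 0
    hi = len(read_end)
    for vec in vector_seqs:
        lo = max(best + 1, min_match)
        for k in range(hi, lo - 1, -1):
            if read_end[:k] in vec:
                best = max(best, k)
                break
    return best


def trim_vector(read: SangerRead, vector_seqs: Sequence[str], min_match: int = 10) -> SangerRead:
    """Remove terminal vector sequence from both read ends.

    The longest terminal segment (>= ``min_match`` bp) exactly matching a
    substring of any vector sequence is removed from each end. A vector hit
    that is internal only leaves the read unchanged but sets
    ``vector_flagged``.
    """
    if min_match < 8:
        raise ValueError("min_match must be >= 8")
    vecs = [v.upper() for v in vector_seqs]
    left = _longest_terminal_vector_match(read.bases.upper(), vecs, min_match)
    rc = read.bases.upper()[::-1]
    vec_rev = [v[::-1] for v in vecs]
    right = _longest_terminal_vector_match(rc, vec_rev, min_match)
    right = min(right, len(read) - left)
    out = read.subread(left, len(read) - right)
    if left == 0 and right == 0:
        core = out.bases.upper()
        for vec in vecs:
            for i in range(len(vec) - min_match + 1):
                if vec[i : i + min_match] in core:
                    out = replace(out, vector_flagged=True)
                    return out
        return out
    if len(out) == 0:
        out = replace(out, vector_flagged=True)
    return out


def quality_trim(
    read: SangerRead,
    min_mean_q: float = DEFAULT_MIN_MEAN_Q,
    min_len: int = DEFAULT_MIN_LEN,
) -> SangerRead | None:
    """Longest contiguous sub-read with mean quality >= ``min_mean_q``.

    Returns ``None`` (read discarded) if the best window is shorter than
    ``min_len``. Ties between equally long windows are broken leftmost.
    """
    n = len(read)
    if n == 0:
        return None
    q = read.quals.astype(np.float64)
    if q.mean() >= min_mean_q:
        return read if n >= min_len else None
    cs = np.concatenate([[0.0], np.cumsum(q - min_mean_q)])
    # longest window with non-negative adjusted sum; scan lengths downward
    for length in range(n - 1, max(min_len, 1) - 1, -1):
        sums = cs[length:] - cs[: n - length + 1]
        idx = np.nonzero(sums >= 0)[0]
        if idx.size:
            start = int(idx[0])
            return read.subread(start, start + length)
    return None


def trim_reads(
    reads: Iterable[SangerRead],
    min_mean_q: float = DEFAULT_MIN_MEAN_Q,
    min_len: int = DEFAULT_MIN_LEN,
    vector_seqs: Sequence[str] = (),
    min_match: int = 10,
) -> tuple[list[SangerRead], list[tuple[str, str]]]:
    """Full trimming pass. Returns (kept reads, [(read id, discard reason)])."""
    kept: list[SangerRead] = []
    discarded: list[tuple[str, str]] = []
    for read in reads:
        if vector_seqs:
            read = trim_vector(read, vector_seqs, min_match=min_match)
            if len(read) == 0:
                discarded.append((read.id, "all_vector"))
                continue
        trimmed = quality_trim(read, min_mean_q=min_mean_q, min_len=min_len)
        if trimmed is None:
            discarded.append((read.id, "low_quality"))
        else:
            kept.append(trimmed)
    if discarded:
        log.info("discarded %d/%d reads during trimming", len(discarded), len(discarded) + len(kept))
    return kept, discarded


# -- FASTQ I/O (Sanger +33 encoding) ----------------------------------------


def _mate_tag_from_id(read_id: str) -> str:
    for tag in ("b1", "g1"):
        if read_id.endswith("." + tag) or read_id.endswith("/" + tag):
            return tag
    return ""


def read_fastq(path: str | Path) -> Iterator[SangerRead]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield SangerRead(
            id=rec.id,
            mate_tag=_mate_tag_from_id(rec.id),
            bases=str(rec.seq).upper(),
            quals=np.array(rec.letter_annotations["phred_quality"], dtype=np.int32),
        )


def write_fastq(reads: Iterable[SangerRead], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.quals]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
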