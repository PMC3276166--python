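"""Concatenated somatic reference ("conMAC") construction and coordinate liftover.

The macronuclear (MAC) assembly of a ciliate consists of many contigs. For
browser-style positional analysis the contigs are joined into one pseudo-
chromosome: contigs ordered by decreasing length (ties broken by name),
separated by fixed-size blocks of N (default 10 kbp) so that no read can
align across a contig boundary. This module builds that reference, maps
coordinates in both directions, and reads/writes the associated files
(multi-FASTA in, single-record FASTA plus a contig offset table out).

All conMAC coordinates are 0-based, half-open internally; 1-based conventions
are applied only at I/O boundaries (SAM, GFF3).
"""
from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

#: Sentinel contig name returned by :meth:`ConMacReference.lift_to_contig`
#: for positions inside an inter-contig N spacer.
SPACER = "<spacer>"

DEFAULT_SPACER_LEN = 10_000


@dataclass(frozen=True)
class Contig:
    """One assembly contig.

    ``sequence`` may be ``None`` for layout-only work (coordinate arithmetic
    on assemblies whose bases are not loaded); in that case ``length`` must
    be given explicitly.
    """

    name: str
    sequence: str | None = None
    length: int = 0

    def __post_init__(self) -> None:
        if self.sequence is not None:
            if self.length and self.length != len(self.sequence):
                raise ValueError(
                    f"contig {self.name}: length {self.length} != sequence "
                    f"length {len(self.sequence)}"
                )
            object.__setattr__(self, "length", len(self.sequence))
        if self.length <= 0:
            raise ValueError(f"contig {self.name}: non-positive length")


@dataclass
class ConMacReference:
    """Ordered contig concatenation with spacers and a bidirectional coordinate map."""

    contigs: list[Contig]
    spacer_len: int = DEFAULT_SPACER_LEN
    offsets: list[int] = field(default_factory=list)
    total_length: int = 0
    name: str = "conMAC"
    _by_name: dict[str, int] = field(default_factory=dict, repr=False)
    _seq_cache: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.offsets:
            off = 0
            for c in self.contigs:
                self.offsets.append(off)
                off += c.length + self.spacer_len
            self.total_length = off - self.spacer_len if self.contigs else 0
        self._by_name = {c.name: i for i, c in enumerate(self.contigs)}

    # -- coordinate liftover -------------------------------------------------

    def lift_to_conmac(self, contig_name: str, pos: int) -> int:
        """Contig-local coordinate -> conMAC coordinate."""
        i = self._by_name[contig_name]
        if not 0 <= pos < self.contigs[i].length:
            raise ValueError(f"position {pos} outside contig {contig_name}")
        return self.offsets[i] + pos

    def lift_to_contig(self, pos: int) -> tuple[str, int]:
        """conMAC coordinate -> (contig name, contig-local coordinate).

        Positions inside an inter-contig spacer return ``(SPACER, offset
        into the spacer)``.
        """
        if not 0 <= pos < self.total_length:
            raise ValueError(f"position {pos} outside conMAC [0, {self.total_length})")
        i = bisect_right(self.offsets, pos) - 1
        local = pos - self.offsets[i]
        if local < self.contigs[i].length:
            return self.contigs[i].name, local
        return SPACER, local - self.contigs[i].length

    def is_near_contig_edge(self, pos: int, margin: int) -> bool:
        """True iff ``pos`` lies within ``margin`` bp of a contig end or in a spacer.

        One-end-mapping reads whose breakpoint falls here are treated as
        assembly-edge artifacts rather than elimination evidence.
        """
        name, local = self.lift_to_contig(pos)
        if name == SPACER:
            return True
        length = self.contigs[self._by_name[name]].length
        return min(local, length - 1 - local) < margin

    # -- sequence access -----------------------------------------------------

    def sequence(self) -> str:
        """The full conMAC sequence (requires contigs with bases loaded)."""
        if self._seq_cache is None:
            if any(c.sequence is None for c in self.contigs):
                raise ValueError("reference was built without contig sequences")
            spacer = "N" * self.spacer_len
            self._seq_cache = spacer.join(c.sequence for c in self.contigs)
        return self._seq_cache

    def contig_intervals(self) -> list[tuple[int, int]]:
        """conMAC [start, end) interval of every contig, in order."""
        return [(off, off + c.length) for off, c in zip(self.offsets, self.contigs)]


def build_conmac(
    contigs: Iterable[Contig],
    spacer_len: int = DEFAULT_SPACER_LEN,
    exclude_names: Iterable[str] = (),
) -> ConMacReference:
    """Assemble the conMAC reference from contigs.

    Contigs named in ``exclude_names`` (e.g. the rDNA minichromosome and the
    mitochondrial chromosome, which carry no elimination signal of interest)
    are dropped before size-ordering. Duplicate names and an empty post-
    exclusion set are hard errors.
    """
    if spacer_len < 0:
        raise ValueError("spacer_len must be >= 0")
    contigs = list(contigs)
    names = [c.name for c in contigs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate contig names: {dupes}")
    excluded = set(exclude_names)
    kept = [c for c in contigs if c.name not in excluded]
    if not kept:
        raise ValueError("no contigs remain after exclusion")
    kept.sort(key=lambda c: (-c.length, c.name))
    return ConMacReference(contigs=kept, spacer_len=spacer_len)


# -- file I/O ----------------------------------------------------------------


def read_contigs_fasta(path: str | Path) -> list[Contig]:
    return [
        Contig(name=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_conmac_fasta(ref: ConMacReference, path: str | Path, wrap: int = 80) -> None:
    seq = ref.sequence()
    with open(path, "w") as fh:
        fh.write(f">{ref.name}\n")
        for i in range(0, len(seq), wrap):
            fh.write(seq[i : i + wrap] + "\n")


def write_offset_table(ref: ConMacReference, path: str | Path) -> None:
    """Tab-separated (contig, conMAC offset, length) table."""
    with open(path, "w") as fh:
        fh.write("contig\toffset\tlength\n")
        for off, c in zip(ref.offsets, ref.contigs):
            fh.write(f"{c.name}\t{off}\t{c.length}\n")


def read_offset_table(path: str | Path, spacer_len: int = DEFAULT_SPACER_LEN) -> ConMacReference:
    """Rebuild a layout-only reference (no bases) from an offset table."""
    contigs: list[Contig] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("contig\t"):
            raise ValueError(f"{path}: not an offset table")
        for line in fh:
            name, _off, length = line.rstrip("\n").split("\t")
            contigs.append(Contig(name=name, length=int(length)))
    return ConMacReference(contigs=contigs, spacer_len=spacer_len)
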