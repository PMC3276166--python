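"""Small shared helpers."""
from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """View a DNA string as a uint8 array for vectorised comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int, at_fraction: float = 0.75) -> str:
    """Random DNA with the given AT fraction (A/T and G/C each split evenly)."""
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    bases = rng.choice(
        np.frombuffer(b"ATGC", dtype=np.uint8), size=n, p=[p_at, p_at, p_gc, p_gc]
    )
    return bases.tobytes().decode("ascii")
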