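"""Low-level nucleotide sequence helpers shared across the package.

Sequences are plain Python strings over {A,C,G,T,N} internally; numpy uint8
views are used where per-site vectorised work pays off.
"""
from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")

# numpy alphabet encoding: A=0 C=1 G=2 T=3 N=4
_A2I = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _A2I[ord(_b)] = _i
_I2A = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement (N self-complements)."""
    return seq.translate(_COMP)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMP)


def seq_to_array(seq: str) -> np.ndarray:
    """Encode to uint8 codes A=0 C=1 G=2 T=3 N=4."""
    return _A2I[np.frombuffer(seq.encode(), dtype=np.uint8)]


def array_to_seq(arr: np.ndarray) -> str:
    return _I2A[arr].tobytes().decode()


def gc_content(seq: str) -> float:
    n = len(seq) - seq.count("N")
    if n == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / n


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """i.i.d. nucleotides with the given GC fraction (AT and GC split evenly)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(4, size=length, p=p).astype(np.uint8)
    return array_to_seq(arr)


def jc69_expected_p(d: float) -> float:
    """Expected proportion of differing sites after divergence d (subs/site)."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def jc69_distance(p: float) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3); raises on saturation."""
    if p >= 0.75:
        raise ValueError(f"saturated: observed difference {p:.4f} >= 0.75")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)
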