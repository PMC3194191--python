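"""Nucleotide encoding helpers shared across the package.

Sequences are held internally as ``numpy.uint8`` arrays with the 2-bit code
A=0, C=1, G=2, T=3; N (or any other IUPAC letter) is code 4 and never matches
anything during search or alignment.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

# any byte -> code; unknown letters collapse to N
_LUT = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lower case

# complement in code space (N stays N)
_COMP = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string into a uint8 code array."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _LUT[np.frombuffer(seq, dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into an upper-case string."""
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space."""
    return _COMP[codes[::-1]]


def revcomp_rows(mat: np.ndarray) -> np.ndarray:
    """Row-wise reverse complement of a (n, l) code matrix."""
    return _COMP[mat][:, ::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def random_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Mismatch count between equal-length code arrays; N mismatches everything."""
    if a.shape != b.shape:
        raise ValueError("hamming() requires equal-length sequences")
    return int(np.count_nonzero((a != b) | (a >= 4) | (b >= 4)))


def write_fasta(path, records, width: int = 60) -> None:
    """Write ``(name, sequence-string)`` records as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` dict."""
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out
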